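"""Density maps, drift correction, enrichment, coverage, compartment sorting."""

import numpy as np
import pandas as pd
import pytest

from synaptrack import (
    MapParams,
    Track,
    correct_drift,
    reconstruct_density_map,
    sort_by_compartment,
    synaptic_coverage,
    synaptic_enrichment,
    upscale_mask,
)
from synaptrack.srmap import DensityMap


def loc_table(x, y, frames=None):
    n = len(x)
    return pd.DataFrame({
        "frame": np.zeros(n, int) if frames is None else np.asarray(frames),
        "x_um": np.asarray(x, float), "y_um": np.asarray(y, float),
        "intensity": 1.0, "precision_um": np.nan, "id": -1,
    })


class TestMapParams:
    def test_zoom5_gives_32nm_pixels(self):
        assert MapParams(zoom=5, source_pixel=0.16).map_pixel == pytest.approx(0.032)

    def test_zoom_must_be_positive_integer(self):
        with pytest.raises(ValueError):
            MapParams(zoom=0)


class TestDensityMap:
    def test_single_localization_lands_in_expected_pixel(self):
        dmap = reconstruct_density_map(loc_table([0.050], [0.050]),
                                       MapParams(), field_shape_px=(4, 4))
        assert dmap.counts[1, 1] == 1          # floor(0.050 / 0.032) == 1
        assert dmap.total == 1

    def test_count_conservation(self, rng):
        n = 500
        locs = loc_table(rng.uniform(0, 4 * 0.16, n), rng.uniform(0, 4 * 0.16, n))
        dmap = reconstruct_density_map(locs, MapParams(), field_shape_px=(4, 4))
        assert dmap.total == n
        assert dmap.n_dropped == 0

    def test_out_of_field_dropped_and_counted(self):
        locs = loc_table([0.05, 99.0], [0.05, 99.0])
        dmap = reconstruct_density_map(locs, MapParams(), field_shape_px=(4, 4))
        assert dmap.total == 1
        assert dmap.n_dropped == 1

    def test_uniform_input_is_chi_square_uniform(self, rng):
        from scipy import stats
        n = 20000
        locs = loc_table(rng.uniform(0, 8 * 0.16, n), rng.uniform(0, 8 * 0.16, n))
        dmap = reconstruct_density_map(locs, MapParams(), field_shape_px=(8, 8))
        counts = dmap.counts.ravel()
        expected = n / counts.size
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, counts.size - 1)
        assert p > 0.001

    def test_map_dimensions_are_source_times_zoom(self):
        dmap = reconstruct_density_map(loc_table([0.1], [0.1]),
                                       MapParams(zoom=5), field_shape_px=(24, 32))
        assert dmap.counts.shape == (120, 160)


class TestDriftCorrection:
    @staticmethod
    def fiducial_table(drift_per_frame, n_frames, n_fids=1, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(n_fids):
            fx, fy = 2.0 + k, 3.0
            for f in range(n_frames):
                rows.append({
                    "frame": f, "id": k,
                    "x_um": fx + drift_per_frame[0] * f + rng.normal(0, noise),
                    "y_um": fy + drift_per_frame[1] * f + rng.normal(0, noise),
                })
        return pd.DataFrame(rows)

    def test_zero_drift_is_identity(self):
        locs = loc_table([1.0, 2.0], [1.0, 2.0], frames=[0, 500])
        fid = self.fiducial_table((0.0, 0.0), 1000)
        out, resid = correct_drift(locs, fid)
        np.testing.assert_allclose(out["x_um"], locs["x_um"])
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_linear_drift_removed_below_10nm(self):
        fid = self.fiducial_table((0.002, 0.001), 1000, noise=0.005, seed=1)
        locs = loc_table(np.full(1000, 1.0) + 0.002 * np.arange(1000),
                         np.full(1000, 1.0) + 0.001 * np.arange(1000),
                         frames=np.arange(1000))
        out, resid = correct_drift(locs, fid)
        assert resid < 0.010
        # the molecule, static apart from drift, is re-pinned near 1.0
        assert out["x_um"].std() < 0.010

    def test_fiducial_sd_reduced_80pct_for_3_map_pixel_drift(self):
        # 3 map pixels = 96 nm of linear drift over the movie
        n = 1000
        total = 3 * 0.032
        fid = self.fiducial_table((total / n, 0.0), n, noise=0.003, seed=2)
        before = np.sqrt(np.mean((fid["x_um"] - fid["x_um"].iloc[0]) ** 2
                                 + (fid["y_um"] - fid["y_um"].iloc[0]) ** 2))
        _, resid = correct_drift(fid[["frame", "x_um", "y_um"]].assign(id=0), fid)
        assert resid <= 0.2 * before

    def test_two_fiducials_halve_estimator_variance(self):
        # Monte-Carlo: variance of the drift estimate with two independent
        # fiducials is ~half the one-fiducial variance
        errs1, errs2 = [], []
        for s in range(40):
            for n_fids, errs in ((1, errs1), (2, errs2)):
                fid = self.fiducial_table((0.0, 0.0), 200, n_fids=n_fids,
                                          noise=0.02, seed=100 + s)
                locs = loc_table([5.0], [5.0], frames=[199])
                out, _ = correct_drift(locs, fid, smooth_window=1)
                errs.append(out["x_um"].iloc[0] - 5.0)
        v1, v2 = np.var(errs1), np.var(errs2)
        assert v2 == pytest.approx(v1 / 2, rel=0.5)

    def test_no_fiducials_passes_through_with_warning(self):
        locs = loc_table([1.0], [1.0])
        with pytest.warns(UserWarning, match="fiducial"):
            out, resid = correct_drift(locs, locs.iloc[0:0])
        np.testing.assert_allclose(out["x_um"], locs["x_um"])
        assert np.isnan(resid)


class TestEnrichment:
    def test_uniform_detections_give_unit_enrichment(self, rng):
        params = MapParams(zoom=1, source_pixel=0.1)
        cell = np.ones((100, 100), bool)
        syn = np.zeros((100, 100), bool)
        syn[40:60, 40:60] = True
        n = 40000
        locs = loc_table(rng.uniform(0, 10.0, n), rng.uniform(0, 10.0, n))
        res = synaptic_enrichment(locs, syn, cell, params)
        assert res.enrichment == pytest.approx(1.0, abs=0.1)

    def test_hand_constructed_ratio(self, rng):
        # 50 detections on 10 µm² of synapse, 100 on 90 µm² outside:
        # E = (50/10) / (100/90) = 4.5
        params = MapParams(zoom=1, source_pixel=0.1)
        cell = np.ones((100, 100), bool)
        syn = np.zeros((100, 100), bool)
        syn[:10, :] = True                        # 1000 px = 10 µm²
        xs = list(rng.uniform(0, 10.0, 50))
        ys = list(rng.uniform(0, 0.999, 50))
        xe = list(rng.uniform(0, 10.0, 100))
        ye = list(rng.uniform(1.001, 9.999, 100))
        res = synaptic_enrichment(loc_table(xs + xe, ys + ye), syn, cell, params)
        assert res.enrichment == pytest.approx(4.5, rel=1e-9)

    def test_zero_extrasynaptic_detections_flagged_infinite(self):
        params = MapParams(zoom=1, source_pixel=0.1)
        cell = np.ones((10, 10), bool)
        syn = np.zeros((10, 10), bool)
        syn[0, 0] = True
        res = synaptic_enrichment(loc_table([0.05], [0.05]), syn, cell, params)
        assert np.isinf(res.enrichment)
        assert res.flagged

    def test_empty_synapse_mask_is_error(self):
        with pytest.raises(ValueError):
            synaptic_enrichment(loc_table([0.1], [0.1]),
                                np.zeros((5, 5), bool), np.ones((5, 5), bool))

    def test_invariant_under_uniform_thinning(self, rng):
        params = MapParams(zoom=1, source_pixel=0.1)
        cell = np.ones((50, 50), bool)
        syn = np.zeros((50, 50), bool)
        syn[10:20, 10:20] = True
        n = 20000
        locs = loc_table(rng.uniform(0, 5.0, n), rng.uniform(0, 5.0, n))
        full = synaptic_enrichment(locs, syn, cell, params)
        thinned = synaptic_enrichment(locs.iloc[::2], syn, cell, params)
        assert thinned.enrichment == pytest.approx(full.enrichment, abs=0.15)


class TestCoverage:
    def test_saturated_synapse_full_coverage(self):
        syn = np.zeros((30, 30), bool)
        syn[5:15, 5:15] = True
        counts = np.zeros((30, 30), int)
        counts[syn] = 3
        res = synaptic_coverage(DensityMap(counts, MapParams()), syn)
        assert res.mean_coverage == 1.0

    def test_compact_blob_gives_exact_fraction(self):
        # 100-pixel synapse, detections in an isolated compact 4x5 blob:
        # closing adds nothing, coverage = 20/100
        syn = np.zeros((30, 30), bool)
        syn[10:20, 10:20] = True
        counts = np.zeros((30, 30), int)
        counts[12:16, 12:17] = 1
        res = synaptic_coverage(DensityMap(counts, MapParams()), syn)
        assert res.mean_coverage == pytest.approx(0.20)

    def test_no_detections_zero_coverage(self):
        syn = np.zeros((20, 20), bool)
        syn[5:10, 5:10] = True
        res = synaptic_coverage(DensityMap(np.zeros((20, 20), int), MapParams()), syn)
        assert res.mean_coverage == 0.0

    def test_per_synapse_values_bounded(self, rng):
        syn = np.zeros((40, 40), bool)
        syn[2:8, 2:8] = True
        syn[20:30, 20:30] = True
        counts = rng.poisson(0.3, size=(40, 40))
        res = synaptic_coverage(DensityMap(counts, MapParams()), syn)
        assert len(res.per_synapse) == 2
        assert ((res.per_synapse >= 0) & (res.per_synapse <= 1)).all()

    def test_coverage_grows_with_acquisition_length(self, rng):
        syn = np.zeros((30, 30), bool)
        syn[5:25, 5:25] = True
        means = []
        for n in (20, 100, 500):
            locs = loc_table(rng.uniform(0.16, 0.8, n), rng.uniform(0.16, 0.8, n))
            dmap = reconstruct_density_map(locs, MapParams(), field_shape_px=(6, 6))
            means.append(synaptic_coverage(dmap, syn).mean_coverage)
        assert means[0] <= means[1] <= means[2]

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            synaptic_coverage(DensityMap(np.zeros((5, 5), int), MapParams()),
                              np.zeros((5, 5), bool))


class TestCompartmentSorting:
    @staticmethod
    def square_mask():
        # synapse covers [0.32, 0.64) µm in both axes at 32 nm map pixels
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True
        return mask

    def test_track_fully_inside_is_synaptic(self):
        t = Track(0, [0, 1, 2], [0.4, 0.45, 0.5], [0.4, 0.45, 0.5])
        _, labels = sort_by_compartment([t], self.square_mask())
        assert labels[0] == "synaptic"

    def test_track_fully_outside_is_extrasynaptic(self):
        t = Track(0, [0, 1], [1.0, 1.05], [1.0, 1.0])
        _, labels = sort_by_compartment([t], self.square_mask())
        assert labels[0] == "extrasynaptic"

    @pytest.mark.parametrize("n_inside,expected", [(6, "synaptic"), (4, "extrasynaptic"),
                                                   (5, "synaptic")])
    def test_majority_rule(self, n_inside, expected):
        xs = [0.4] * n_inside + [1.0] * (10 - n_inside)
        t = Track(0, np.arange(10), xs, [0.4] * n_inside + [1.0] * (10 - n_inside))
        table, labels = sort_by_compartment([t], self.square_mask())
        assert labels[0] == expected
        assert (table["compartment"] == "synaptic").sum() == n_inside


class TestUpscaleMask:
    def test_kron_preserves_area_fraction(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[1, 1] = 1
        up = upscale_mask(mask, 5)
        assert up.shape == (20, 20)
        assert up.sum() == 25
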