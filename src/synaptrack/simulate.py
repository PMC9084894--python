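"""Ground-truth simulator for single-molecule membrane-mobility experiments.

Emulates sparse live-labeling (uPAINT-style) movies of molecules diffusing in
the dendritic membrane: a mobile pool performing 2-D Brownian motion that is
reflected at the dendrite boundary, plus a slowly-mobile/immobile pool anchored
inside post-synaptic discs (the operational "trapped" state).  The simulator
produces full ground truth — per-frame true positions and free/trapped state
labels — so every downstream analysis stage (localization, tracking, diffusion
estimation, density mapping, enrichment/coverage) can be validated by parameter
recovery rather than against microscope data.

Units and conventions
---------------------
All physical positions are in micrometres; time is ``frame_index * frame_interval``.
The image coordinate frame has x rightward and y downward with the origin at the
top-left corner of pixel (0, 0); pixel (i, j) covers the half-open square
``[j*p, (j+1)*p) x [i*p, (i+1)*p)`` µm for pixel size ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "Geometry",
    "SimulationConfig",
    "OpticsConfig",
    "Molecule",
    "GroundTruthSet",
    "simulate_ground_truth",
    "degrade_to_localizations",
    "render_movie",
    "render_reference_channel",
    "scenario",
    "SCENARIOS",
]

LOC_COLUMNS = ["frame", "x_um", "y_um", "intensity", "precision_um", "id"]


# ---------------------------------------------------------------------------
# Geometry and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Dendrite membrane domain with post-synaptic trapping discs.

    ``dendrite_rect`` is ``(x0, y0, width, height)`` in µm; ``synapses`` is a
    sequence of ``(cx, cy, radius)`` discs in µm standing for the Homer1c-
    positive post-synaptic landscape.
    """

    dendrite_rect: tuple[float, float, float, float]
    synapses: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        x0, y0, w, h = self.dendrite_rect
        if w <= 0 or h <= 0:
            raise ValueError("dendrite_rect must have positive width and height")
        object.__setattr__(self, "synapses", tuple(tuple(s) for s in self.synapses))
        syn_area = 0.0
        for cx, cy, r in self.synapses:
            if r <= 0:
                raise ValueError(f"synapse radius must be > 0, got {r}")
            if not (x0 - r < cx < x0 + w + r and y0 - r < cy < y0 + h + r):
                raise ValueError(f"synapse at ({cx}, {cy}) does not intersect the dendrite")
            syn_area += math.pi * r * r
        if syn_area >= 0.5 * w * h:
            raise ValueError("synapse area fraction of the dendrite must be < 0.5")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, y0, w, h = self.dendrite_rect
        return (x >= x0) & (x <= x0 + w) & (y >= y0) & (y <= y0 + h)

    def in_synapse(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points lying inside any synapse disc."""
        x = np.asarray(x, dtype=float)
        inside = np.zeros(np.shape(x), dtype=bool)
        for cx, cy, r in self.synapses:
            inside |= (x - cx) ** 2 + (np.asarray(y) - cy) ** 2 <= r * r
        return inside


@dataclass(frozen=True)
class SimulationConfig:
    """Motion-model parameters.

    Defaults reproduce the early-development (DIV 8) condition: a mobile pool
    with D around 0.30 µm²/s and ~20% slowly mobile molecules, imaged at 20 ms
    per frame for up to 4000 frames.  ``track_length_mean`` is the mean of the
    geometric photobleaching lifetime (frames, minimum 1).  With ``p_trap = 0``
    the immobile pool is a fixed mixture anchored in synapses; with
    ``p_trap > 0`` molecules instead toggle free↔trapped while inside a disc
    (escape rate ``k_off`` in s⁻¹).
    """

    D_free: float = 0.30
    immobile_fraction: float = 0.20
    p_trap: float = 0.0
    k_off: float = 1.0
    frame_interval: float = 0.02
    n_frames: int = 4000
    sigma_loc: float = 0.030
    track_length_mean: float = 50.0
    n_molecules: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if self.D_free < 0:
            raise ValueError("D_free must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.n_frames < 1 or self.n_molecules < 1:
            raise ValueError("n_frames and n_molecules must be >= 1")
        if not 0.0 <= self.p_trap <= 1.0:
            raise ValueError("p_trap must be in [0, 1]")


@dataclass(frozen=True)
class OpticsConfig:
    """Camera/PSF model for rendering movies.

    ``pixel_size`` is the camera pixel in µm (0.16 µm as on an EMCCD with a
    100x objective); ``psf_sigma`` the Gaussian PSF s.d. in µm;
    ``em_gain_noise_factor`` scales the Poisson shot-noise variance (EM excess
    noise); ``fiducials`` are fixed bright markers rendered every frame;
    ``drift_velocity`` is a lateral stage drift applied to everything in the
    image (µm/s, 2-vector).
    """

    pixel_size: float = 0.16
    psf_sigma: float = 0.10
    photons_per_molecule: float = 250.0
    background: float = 50.0
    em_gain_noise_factor: float = 2.0
    fiducials: tuple[tuple[float, float], ...] = ()
    fiducial_photons: float = 5000.0
    drift_velocity: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.photons_per_molecule < 0 or self.background < 0:
            raise ValueError("photon counts must be >= 0")
        object.__setattr__(self, "fiducials", tuple(tuple(f) for f in self.fiducials))
        object.__setattr__(self, "drift_velocity", tuple(self.drift_velocity))


@dataclass
class Molecule:
    """Ground-truth record for one molecule: alive on frames [birth, death]."""

    molecule_id: int
    birth: int
    x: np.ndarray          # µm, one entry per live frame
    y: np.ndarray
    trapped: np.ndarray    # bool per live frame

    @property
    def death(self) -> int:
        return self.birth + len(self.x) - 1

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.birth, self.birth + len(self.x))


@dataclass
class GroundTruthSet:
    """Simulated molecules with their geometry and configuration."""

    molecules: list[Molecule]
    geometry: Geometry
    config: SimulationConfig

    def to_table(self) -> pd.DataFrame:
        """Long-format ground truth: molecule_id, frame, x_um, y_um, state."""
        parts = []
        for m in self.molecules:
            parts.append(pd.DataFrame({
                "molecule_id": m.molecule_id,
                "frame": m.frames,
                "x_um": m.x,
                "y_um": m.y,
                "state": np.where(m.trapped, "trapped", "free"),
            }))
        if not parts:
            return pd.DataFrame(columns=["molecule_id", "frame", "x_um", "y_um", "state"])
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Ground-truth dynamics
# ---------------------------------------------------------------------------

def _reflect(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] by specular reflection."""
    span = hi - lo
    v = np.mod(u - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return lo + v

def _sample_in_synapse(rng: np.random.Generator, geometry: Geometry) -> tuple[float, float]:
    """Uniform point inside a (area-weighted) synapse disc, clipped to the dendrite."""
    x0, y0, w, h = geometry.dendrite_rect
    areas = np.array([r * r for _, _, r in geometry.synapses])
    probs = areas / areas.sum()
    for _ in range(10000):
        cx, cy, r = geometry.synapses[rng.choice(len(geometry.synapses), p=probs)]
        rho = r * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        x, y = cx + rho * math.cos(phi), cy + rho * math.sin(phi)
        if x0 <= x <= x0 + w and y0 <= y <= y0 + h:
            return x, y
    raise RuntimeError("could not place an anchored molecule inside the dendrite")


def simulate_ground_truth(config: SimulationConfig, geometry: Geometry) -> GroundTruthSet:
    """Simulate molecule trajectories on the dendrite with synaptic trapping.

    Free molecules take Gaussian steps with per-axis variance
    ``2 * D_free * frame_interval`` and reflect at the dendrite rectangle.
    A fraction ``immobile_fraction`` of molecules is immobile for its whole
    lifetime, anchored inside a synapse disc (true position frozen; apparent
    motion downstream comes only from localization noise).  If ``p_trap > 0``,
    mobile molecules additionally toggle free→trapped with probability
    ``p_trap`` per frame while inside a disc and escape at rate ``k_off``.

    Lifetimes are geometric with mean ``track_length_mean`` (photobleaching),
    truncated at the end of the movie; birth frames are uniform over the movie.
    Reproducible: one master seed, one deterministic substream per molecule.
    """
    if config.immobile_fraction > 0 and not geometry.synapses:
        raise ValueError(
            "immobile_fraction > 0 requires at least one synapse disc to anchor molecules"
        )
    x0, y0, w, h = geometry.dendrite_rect
    dt = config.frame_interval
    step_sd = math.sqrt(2.0 * config.D_free * dt)
    p_bleach = 1.0 / max(config.track_length_mean, 1.0)
    p_escape = 1.0 - math.exp(-config.k_off * dt)

    master = np.random.SeedSequence(config.seed)
    substreams = master.spawn(config.n_molecules)

    molecules: list[Molecule] = []
    for mid, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        birth = int(rng.integers(0, config.n_frames))
        lifetime = int(rng.geometric(p_bleach))  # >= 1
        lifetime = min(lifetime, config.n_frames - birth)
        immobile = rng.uniform() < config.immobile_fraction

        if immobile:
            px, py = _sample_in_synapse(rng, geometry)
            x = np.full(lifetime, px)
            y = np.full(lifetime, py)
            trapped = np.ones(lifetime, dtype=bool)
        elif config.p_trap == 0.0:
            steps = rng.normal(0.0, step_sd, size=(lifetime - 1, 2)) if lifetime > 1 else np.empty((0, 2))
            start = np.array([rng.uniform(x0, x0 + w), rng.uniform(y0, y0 + h)])
            path = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            x = _reflect(path[:, 0], x0, x0 + w)
            y = _reflect(path[:, 1], y0, y0 + h)
            trapped = np.zeros(lifetime, dtype=bool)
        else:
            # Frame-by-frame kinetic mode: trapping inside discs, k_off escape.
            x = np.empty(lifetime)
            y = np.empty(lifetime)
            trapped = np.zeros(lifetime, dtype=bool)
            x[0] = rng.uniform(x0, x0 + w)
            y[0] = rng.uniform(y0, y0 + h)
            trapped[0] = False
            for t in range(1, lifetime):
                if trapped[t - 1]:
                    if rng.uniform() < p_escape:
                        trapped[t] = False
                        x[t] = _reflect(x[t - 1] + rng.normal(0.0, step_sd), x0, x0 + w)
                        y[t] = _reflect(y[t - 1] + rng.normal(0.0, step_sd), y0, y0 + h)
                    else:
                        trapped[t] = True
                        x[t], y[t] = x[t - 1], y[t - 1]
                else:
                    x[t] = _reflect(x[t - 1] + rng.normal(0.0, step_sd), x0, x0 + w)
                    y[t] = _reflect(y[t - 1] + rng.normal(0.0, step_sd), y0, y0 + h)
                    if geometry.in_synapse(x[t], y[t]) and rng.uniform() < config.p_trap:
                        trapped[t] = True
        molecules.append(Molecule(mid, birth, x, y, trapped))
    return GroundTruthSet(molecules, geometry, config)


# ---------------------------------------------------------------------------
# Degradation to localization tables (rendering bypass)
# ---------------------------------------------------------------------------

def degrade_to_localizations(
    truth: GroundTruthSet,
    sigma_loc: float | None = None,
    detection_rate: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn ground truth into a localization table without image rendering.

    True positions are perturbed by isotropic Gaussian noise of s.d.
    ``sigma_loc`` (default: the simulation's configured value) and thinned per
    frame with probability ``detection_rate``.  The molecule identity is kept
    in the ``id`` column as the ground-truth link for recovery tests.
    """
    if sigma_loc is None:
        sigma_loc = truth.config.sigma_loc
    if sigma_loc < 0:
        raise ValueError("sigma_loc must be >= 0")
    if not 0.0 < detection_rate <= 1.0:
        raise ValueError("detection_rate must be in (0, 1]")

    rng = np.random.default_rng(seed)
    table = truth.to_table()
    n = len(table)
    if n == 0:
        return pd.DataFrame(columns=LOC_COLUMNS)
    keep = rng.uniform(size=n) < detection_rate if detection_rate < 1.0 else np.ones(n, bool)
    noise = rng.normal(0.0, sigma_loc, size=(n, 2)) if sigma_loc > 0 else np.zeros((n, 2))
    out = pd.DataFrame({
        "frame": table["frame"].to_numpy(),
        "x_um": table["x_um"].to_numpy() + noise[:, 0],
        "y_um": table["y_um"].to_numpy() + noise[:, 1],
        "intensity": 1.0,
        "precision_um": sigma_loc,
        "id": table["molecule_id"].to_numpy(),
    })
    out = out[keep].sort_values(["frame", "x_um"], kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Camera rendering
# ---------------------------------------------------------------------------

def _field_shape(geometry: Geometry, pixel_size: float, margin_um: float = 0.5) -> tuple[int, int]:
    """Camera frame (ny, nx) covering the dendrite with a margin."""
    x0, y0, w, h = geometry.dendrite_rect
    nx = int(math.ceil((x0 + w + margin_um) / pixel_size))
    ny = int(math.ceil((y0 + h + margin_um) / pixel_size))
    return ny, nx


def _integrated_gaussian(shape: tuple[int, int], x_um: np.ndarray, y_um: np.ndarray,
                         photons: np.ndarray, psf_sigma: float, pixel_size: float) -> np.ndarray:
    """Sum of pixel-integrated 2-D Gaussians (erf differences per axis)."""
    ny, nx = shape
    img = np.zeros(shape)
    s = psf_sigma
    for xc, yc, ph in zip(x_um, y_um, photons):
        # 4-sigma support window
        j0 = max(int((xc - 4 * s) / pixel_size), 0)
        j1 = min(int((xc + 4 * s) / pixel_size) + 1, nx)
        i0 = max(int((yc - 4 * s) / pixel_size), 0)
        i1 = min(int((yc + 4 * s) / pixel_size) + 1, ny)
        if j0 >= j1 or i0 >= i1:
            continue
        xe = np.arange(j0, j1 + 1) * pixel_size
        ye = np.arange(i0, i1 + 1) * pixel_size
        fx = 0.5 * np.diff(special.erf((xe - xc) / (s * math.sqrt(2.0))))
        fy = 0.5 * np.diff(special.erf((ye - yc) / (s * math.sqrt(2.0))))
        img[i0:i1, j0:j1] += ph * np.outer(fy, fx)
    return img


def render_movie(
    truth: GroundTruthSet,
    optics: OpticsConfig,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render ground truth into a 16-bit camera movie.

    Each live molecule contributes a pixel-integrated 2-D Gaussian of width
    ``psf_sigma`` at its true position plus the cumulative drift offset;
    fiducials are rendered in every frame.  Counts are Poisson with mean
    ``signal + background``; if ``em_gain_noise_factor > 1`` the shot-noise
    variance is inflated by that factor (EM-register excess noise) while the
    mean is preserved.  Molecules that drift outside the field are silently
    clipped.  Deterministic under a fixed seed.
    """
    if shape is None:
        shape = _field_shape(truth.geometry, optics.pixel_size)
    ny, nx = shape
    rng = np.random.default_rng(seed)
    n_frames = truth.config.n_frames
    dt = truth.config.frame_interval
    vx, vy = optics.drift_velocity

    # index molecules by frame once
    per_frame: list[list[tuple[float, float]]] = [[] for _ in range(n_frames)]
    for m in truth.molecules:
        for k, f in enumerate(m.frames):
            per_frame[f].append((m.x[k], m.y[k]))

    fid = np.asarray(optics.fiducials, dtype=float).reshape(-1, 2)
    stack = np.empty((n_frames, ny, nx), dtype=np.uint16)
    g = optics.em_gain_noise_factor
    for f in range(n_frames):
        dx, dy = vx * f * dt, vy * f * dt
        pts = np.asarray(per_frame[f], dtype=float).reshape(-1, 2)
        xs = np.concatenate([pts[:, 0] + dx, fid[:, 0] + dx]) if len(fid) else pts[:, 0] + dx
        ys = np.concatenate([pts[:, 1] + dy, fid[:, 1] + dy]) if len(fid) else pts[:, 1] + dy
        ph = np.concatenate([
            np.full(len(pts), optics.photons_per_molecule),
            np.full(len(fid), optics.fiducial_photons),
        ]) if len(fid) else np.full(len(pts), optics.photons_per_molecule)
        mean = _integrated_gaussian(shape, xs, ys, ph, optics.psf_sigma, optics.pixel_size)
        mean += optics.background
        if g > 1.0:
            counts = g * rng.poisson(mean / g)
        elif np.any(mean > 0):
            counts = rng.poisson(mean)
        else:
            counts = mean.astype(np.int64)
        stack[f] = np.clip(counts, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return stack


def render_reference_channel(
    geometry: Geometry,
    optics: OpticsConfig,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    synapse_intensity: float = 2000.0,
    dendrite_intensity: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a Homer1c-like reference image of the synapse landscape.

    Synapse discs are bright plateaus and the dendrite a dimmer fill, both
    blurred by the PSF, with Poisson noise on top.  Returns ``(image, mask)``
    where ``mask`` is the noise-free rasterized ground-truth disc mask
    (uint8, 1 inside a disc) at camera resolution.
    """
    from scipy import ndimage

    if shape is None:
        shape = _field_shape(geometry, optics.pixel_size)
    ny, nx = shape
    p = optics.pixel_size
    # pixel-center coordinates in µm
    xc = (np.arange(nx) + 0.5) * p
    yc = (np.arange(ny) + 0.5) * p
    X, Y = np.meshgrid(xc, yc)

    x0, y0, w, h = geometry.dendrite_rect
    dendrite = ((X >= x0) & (X <= x0 + w) & (Y >= y0) & (Y <= y0 + h)).astype(float)
    mask = geometry.in_synapse(X, Y)

    clean = dendrite_intensity * dendrite + (synapse_intensity - dendrite_intensity) * mask
    clean = ndimage.gaussian_filter(clean, sigma=optics.psf_sigma / p)
    clean += optics.background
    rng = np.random.default_rng(seed)
    image = rng.poisson(clean).astype(np.uint16) if np.any(clean > 0) else clean.astype(np.uint16)
    return image, mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

def _default_geometry() -> Geometry:
    """A 40 x 3.2 µm dendritic segment with 14 synapses of 0.3 µm radius."""
    rng = np.random.default_rng(12345)
    synapses = []
    for k in range(14):
        cx = 1.5 + k * 2.7 + rng.uniform(-0.5, 0.5)
        cy = rng.uniform(0.6, 2.6)
        synapses.append((cx, cy, 0.3))
    return Geometry(dendrite_rect=(0.0, 0.0, 40.0, 3.2), synapses=tuple(synapses))


#: Built-in study conditions: "DIV8" is the early-development condition
#: (mobile peak 0.30 µm²/s, 20% immobile); "uniform-GPI" emulates the freely
#: diffusing GPI-anchored control with a negligible immobile pool.
SCENARIOS: dict[str, SimulationConfig] = {
    "DIV8": SimulationConfig(D_free=0.30, immobile_fraction=0.20),
    "uniform-GPI": SimulationConfig(D_free=0.30, immobile_fraction=0.05),
}


def scenario(name: str, **overrides) -> tuple[SimulationConfig, Geometry]:
    """Return ``(config, geometry)`` for a built-in scenario, with overrides."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    cfg = SCENARIOS[name]
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg, _default_geometry()
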