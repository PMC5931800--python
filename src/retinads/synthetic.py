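"""Ground-truth synthetic data emulating direction-selectivity experiments.

Every analysis stage in this package is validated against data generated
here, with known parameters:

* **Spike responses** — populations of direction-selective (DS) and non-DS
  ganglion cells responding to a bright bar moved in 12 equally spaced
  directions.  Each cell fires two temporal response lobes (ON at the bar's
  leading edge, OFF at the trailing edge), with per-trial spike counts drawn
  from a Poisson law whose mean follows a von Mises direction profile
  (normalized to 1 at the preferred direction μ, concentration κ) scaled by a
  saturating contrast function, with a floor for null-direction spiking.
* **Mosaics** — 2-D soma arrays of controlled regularity: jittered hexagonal
  lattice (regular), hard-core random placement (random with soma-sized
  exclusion), or pure Poisson scatter.
* **IPL profiles** — sums of Gaussian fluorescence bands across IPL depth,
  plus noise.
* **Plexus images and contact volumes** — binary arbor images with punched
  holes at a controlled coverage fraction, and 3-D tip/target fixtures with
  an exact number of tips placed on the target.

All randomness flows from a single explicit seed through named
:class:`numpy.random.Generator` instances; identical parameters and seed give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import disk

from retinads.mosaic import MosaicPattern
from retinads.anatomy import ContactVolume, IntensityProfile
from retinads.tuning import SpikeResponseSet

__all__ = [
    "StimulusProtocol",
    "SyntheticCellParams",
    "SyntheticTruth",
    "MosaicPackingError",
    "generate_population",
    "expected_count",
    "generate_mosaic",
    "generate_ipl_profile",
    "generate_plexus_image",
    "generate_contact_volume",
]


class MosaicPackingError(RuntimeError):
    """Raised when a hard-core mosaic cannot be packed at the requested density."""


# ---------------------------------------------------------------------------
# stimulus and cell parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Moving-bar stimulus protocol.

    Defaults follow the standard paradigm: a positive-contrast bar 1200 µm
    wide moving at 400 µm/s in one of 12 equally spaced directions, shown at
    Weber contrasts of 5-300%, 8 trials per condition.
    """

    directions_deg: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 30))
    contrasts_pct: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0, 150.0, 300.0)
    n_trials: int = 8
    bar_speed_um_s: float = 400.0
    bar_width_um: float = 1200.0
    trial_duration_s: float = 3.0

    def __post_init__(self) -> None:
        d = np.sort(np.asarray(self.directions_deg, dtype=float))
        if np.any(d < 0) or np.any(d >= 360):
            raise ValueError("directions must lie in [0, 360)")
        steps = np.diff(np.concatenate([d, [d[0] + 360.0]]))
        if not np.allclose(steps, 360.0 / len(d)):
            raise ValueError("directions must be equally spaced over [0, 360)")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if any(c <= 0 for c in self.contrasts_pct):
            raise ValueError("contrasts must be positive")


@dataclass
class SyntheticCellParams:
    """Ground-truth response parameters for one synthetic cell.

    ``gain`` is the mean spike count per trial in the ON lobe for motion in
    the preferred direction at the reference (highest) contrast;
    ``off_gain`` defaults to the same value.  ``null_rate`` is the mean count
    per trial per lobe for null-direction motion.  ``kappa_on/off`` are the
    von Mises concentrations (0 = untuned).  Temporal lobes are Gaussians of
    width ``lobe_sigma_s`` centered at the ON/OFF peak times (ON precedes OFF
    for a bright bar).  Contrast response saturates with semisaturation
    constant ``contrast_semisaturation`` (Weber %).
    """

    cell_id: str
    is_ds: bool = True
    mu_on_deg: float = 0.0
    mu_off_deg: float = 0.0
    kappa_on: float = 2.0
    kappa_off: float = 2.0
    gain: float = 30.0
    null_rate: float = 0.5
    off_gain: float | None = None
    on_peak_time_s: float = 0.75
    off_peak_time_s: float = 2.25
    lobe_sigma_s: float = 0.1
    baseline_rate_hz: float = 0.0
    contrast_semisaturation: float = 20.0

    def __post_init__(self) -> None:
        if self.off_gain is None:
            self.off_gain = self.gain
        if self.kappa_on < 0 or self.kappa_off < 0:
            raise ValueError("kappa must be >= 0")
        if not (self.gain >= self.null_rate >= 0):
            raise ValueError("need gain >= null_rate >= 0")
        if self.off_peak_time_s <= self.on_peak_time_s:
            raise ValueError("OFF lobe must follow the ON lobe in time")


@dataclass
class SyntheticTruth:
    """A synthetic population: per-cell parameters, protocol and master seed."""

    cells: list[SyntheticCellParams]
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    seed: int = 0


# ---------------------------------------------------------------------------
# spike-response generation
# ---------------------------------------------------------------------------

def _direction_profile(theta_deg: np.ndarray | float, mu_deg: float, kappa: float) -> np.ndarray | float:
    """von Mises direction profile normalized to 1 at μ: exp(κ(cos(θ−μ)−1))."""
    delta = np.deg2rad(np.asarray(theta_deg, dtype=float) - mu_deg)
    if np.isinf(kappa):
        return np.where(np.isclose(np.cos(delta), 1.0), 1.0, 0.0)
    return np.exp(kappa * (np.cos(delta) - 1.0))


def _contrast_gain(contrast_pct: float, c50: float, c_ref: float) -> float:
    """Saturating (Naka-Rushton) contrast response, normalized to 1 at c_ref."""
    return (contrast_pct * (c50 + c_ref)) / (c_ref * (c50 + contrast_pct))


def expected_count(
    params: SyntheticCellParams,
    direction_deg: float,
    contrast_pct: float,
    protocol: StimulusProtocol,
    lobe: str = "ON",
) -> float:
    """Analytic mean spike count per trial for one lobe — the generator's rate law."""
    if lobe == "ON":
        mu, kappa, gain = params.mu_on_deg, params.kappa_on, params.gain
    elif lobe == "OFF":
        mu, kappa, gain = params.mu_off_deg, params.kappa_off, params.off_gain
    else:
        raise ValueError("lobe must be 'ON' or 'OFF'")
    if not params.is_ds:
        kappa = 0.0
    g = _direction_profile(direction_deg, mu, kappa)
    s = _contrast_gain(contrast_pct, params.contrast_semisaturation, max(protocol.contrasts_pct))
    return float(params.null_rate + (gain - params.null_rate) * g * s)


def generate_population(truth: SyntheticTruth) -> SpikeResponseSet:
    """Draw a full synthetic spike-response data set from ground truth.

    Per cell, condition and trial, an inhomogeneous-Poisson spike train: the
    ON- and OFF-lobe counts are Poisson with the analytic means of
    :func:`expected_count`, spike times are Gaussian around the lobe peak
    times, and an optional homogeneous baseline adds uniform spikes over the
    trial window.  Reproducible: same truth (including seed) gives identical
    output.
    """
    rng = np.random.default_rng(truth.seed)
    proto = truth.protocol
    rs = SpikeResponseSet(proto.trial_duration_s, proto.bar_speed_um_s, protocol=proto)
    dur = proto.trial_duration_s
    for params in truth.cells:
        for direction in proto.directions_deg:
            for contrast in proto.contrasts_pct:
                lam_on = expected_count(params, direction, contrast, proto, "ON")
                lam_off = expected_count(params, direction, contrast, proto, "OFF")
                n_on = rng.poisson(lam_on, proto.n_trials)
                n_off = rng.poisson(lam_off, proto.n_trials)
                n_base = rng.poisson(params.baseline_rate_hz * dur, proto.n_trials)
                trials = []
                for k in range(proto.n_trials):
                    t = np.concatenate([
                        rng.normal(params.on_peak_time_s, params.lobe_sigma_s, n_on[k]),
                        rng.normal(params.off_peak_time_s, params.lobe_sigma_s, n_off[k]),
                        rng.uniform(0.0, dur, n_base[k]),
                    ])
                    trials.append(np.sort(np.clip(t, 0.0, dur)))
                rs.add(params.cell_id, direction, contrast, trials)
    return rs


# ---------------------------------------------------------------------------
# mosaic generation
# ---------------------------------------------------------------------------

def generate_mosaic(
    process: str,
    density_cells_mm2: float,
    bounds: tuple[float, float, float, float],
    d_min_um: float = 8.0,
    jitter_sd_um: float = 2.0,
    seed: int | None = None,
    soma_radius_um: float = 4.0,
    max_tries_per_cell: int = 1000,
) -> MosaicPattern:
    """Generate a 2-D soma mosaic of controlled regularity.

    ``process`` is one of:

    * ``'lattice_jitter'`` — hexagonal lattice at the target density with
      isotropic Gaussian positional jitter of SD ``jitter_sd_um`` (clipped to
      the field); the regular extreme;
    * ``'hardcore'`` — sequential random placement rejecting candidates
      closer than ``d_min_um`` (about a soma diameter) to any accepted point;
      the density-matched random null;
    * ``'poisson'`` — uniform random placement with no exclusion.

    Raises :class:`MosaicPackingError` if hard-core packing fails within
    ``max_tries_per_cell`` attempts per cell.
    """
    xmin, ymin, xmax, ymax = bounds
    w, h = xmax - xmin, ymax - ymin
    area_mm2 = w * h / 1e6
    n = int(round(density_cells_mm2 * area_mm2))
    if n < 10:
        raise ValueError("density x area must give at least 10 cells")
    rng = np.random.default_rng(seed)

    if process == "poisson":
        pts = np.column_stack([rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])
    elif process == "hardcore":
        if d_min_um < 0:
            raise ValueError("d_min must be >= 0")
        pts_list: list[np.ndarray] = []
        tries = 0
        budget = max_tries_per_cell * n
        while len(pts_list) < n:
            if tries >= budget:
                raise MosaicPackingError(
                    f"placed {len(pts_list)}/{n} cells after {tries} tries; packing too dense"
                )
            cand = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
            tries += 1
            if pts_list:
                d2 = np.sum((np.asarray(pts_list) - cand) ** 2, axis=1)
                if np.min(d2) < d_min_um**2:
                    continue
            pts_list.append(cand)
        pts = np.asarray(pts_list)
    elif process == "lattice_jitter":
        # hexagonal lattice constant for the target areal density
        a = np.sqrt(2.0 / (np.sqrt(3.0) * density_cells_mm2 / 1e6))
        row_h = a * np.sqrt(3.0) / 2.0
        rows = []
        i = 0
        y = ymin + row_h / 2.0
        while y < ymax:
            x0 = xmin + (a / 2.0 if i % 2 else a / 4.0)
            xs = np.arange(x0, xmax, a)
            rows.append(np.column_stack([xs, np.full(xs.size, y)]))
            y += row_h
            i += 1
        pts = np.vstack(rows)
        if jitter_sd_um > 0:
            pts = pts + rng.normal(0.0, jitter_sd_um, pts.shape)
        eps = 1e-9 * max(w, h)
        pts[:, 0] = np.clip(pts[:, 0], xmin, xmax - eps)
        pts[:, 1] = np.clip(pts[:, 1], ymin, ymax - eps)
    else:
        raise ValueError(f"unknown mosaic process {process!r}")

    return MosaicPattern(pts, bounds, soma_radius_um)


# ---------------------------------------------------------------------------
# anatomy fixtures
# ---------------------------------------------------------------------------

def generate_ipl_profile(
    bands: Sequence[tuple[float, float, float]],
    noise_sd: float = 0.0,
    n_samples: int = 201,
    seed: int | None = None,
    roi_width_um: float = 12.5,
) -> IntensityProfile:
    """Sum-of-Gaussian-bands fluorescence profile across IPL depth.

    ``bands`` is a sequence of ``(center_pct, width_pct, amplitude)`` tuples;
    Gaussian noise of SD ``noise_sd`` is added before normalization.  Sampled
    on a uniform grid of ``n_samples`` points over 0-100% depth.
    """
    for center, width, _amp in bands:
        if not 0.0 <= center <= 100.0:
            raise ValueError("band centers must lie in [0, 100]% depth")
        if width <= 0:
            raise ValueError("band widths must be positive")
    depth = np.linspace(0.0, 100.0, n_samples)
    raw = np.zeros_like(depth)
    for center, width, amp in bands:
        raw += amp * np.exp(-((depth - center) ** 2) / (2.0 * width**2))
    if noise_sd > 0:
        raw = raw + np.random.default_rng(seed).normal(0.0, noise_sd, raw.shape)
    return IntensityProfile.from_raw(depth, raw, roi_width_um)


def generate_plexus_image(
    coverage_target: float,
    hole_density: float = 0.0,
    hole_radius_px: float = 5.0,
    size_px: tuple[int, int] = (256, 256),
    seed: int | None = None,
) -> np.ndarray:
    """Binary arbor-plexus image with punched holes at a set coverage fraction.

    Starts from full foreground, punches ``hole_density`` circular holes per
    100×100-pixel patch at random centers, then trims or restores randomly
    chosen pixels so the realized foreground fraction equals
    ``round(coverage_target · n_pixels)`` exactly.
    """
    if not 0.0 < coverage_target < 1.0:
        raise ValueError("coverage_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    img = np.ones(size_px, dtype=bool)
    n_px = img.size
    n_holes = int(round(hole_density * n_px / 1e4))
    for _ in range(n_holes):
        center = (rng.uniform(0, size_px[0]), rng.uniform(0, size_px[1]))
        rr, cc = disk(center, hole_radius_px, shape=size_px)
        img[rr, cc] = False
    target_fg = int(round(coverage_target * n_px))
    flat = img.ravel()
    n_fg = int(flat.sum())
    if n_fg > target_fg:
        on = np.flatnonzero(flat)
        flat[rng.choice(on, n_fg - target_fg, replace=False)] = False
    elif n_fg < target_fg:
        off = np.flatnonzero(~flat)
        flat[rng.choice(off, target_fg - n_fg, replace=False)] = True
    return img


def generate_contact_volume(
    n_tips: int,
    target_geometry: np.ndarray | tuple[int, int, int] = (8, 64, 64),
    hit_fraction: float = 0.5,
    seed: int | None = None,
    voxel_size_um: float = 1.0,
) -> ContactVolume:
    """Tip/target fixture with an exact number of tips on the target.

    ``target_geometry`` is either a 3-D boolean mask used directly, or a
    volume shape for which an off-center box occupying one in-plane quadrant
    (asymmetric under in-plane flips, so the flip control differs from the
    observed rate) is used.  Exactly ``round(hit_fraction · n_tips)`` tips are
    placed on random target voxels; the remainder on non-target voxels.
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValueError("hit_fraction must lie in [0, 1]")
    if isinstance(target_geometry, np.ndarray):
        mask = target_geometry.astype(bool)
    else:
        nz, ny, nx = target_geometry
        mask = np.zeros((nz, ny, nx), dtype=bool)
        mask[:, : ny // 2, : nx // 2] = True
    rng = np.random.default_rng(seed)
    n_hit = int(round(hit_fraction * n_tips))
    inside = np.argwhere(mask)
    outside = np.argwhere(~mask)
    if n_hit > 0 and len(inside) == 0:
        raise ValueError("target mask is empty but hits were requested")
    if n_tips - n_hit > 0 and len(outside) == 0:
        raise ValueError("target mask fills the volume but misses were requested")
    tips = []
    if n_hit:
        tips.append(inside[rng.choice(len(inside), n_hit, replace=True)])
    if n_tips - n_hit:
        tips.append(outside[rng.choice(len(outside), n_tips - n_hit, replace=True)])
    return ContactVolume(np.vstack(tips), mask, voxel_size_um)
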