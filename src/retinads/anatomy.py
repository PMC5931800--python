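"""Anatomical quantifications for developing retinal interneuron circuits.

Covers the image- and tracing-derived measurements used to characterize
starburst amacrine cell (SAC) development:

* orientation of primary dendrites relative to the inner plexiform layer
  (IPL), classified as IPL-directed, tangential, or directed away toward the
  outer neuroblast layer (ONBL);
* fluorescence intensity profiles across IPL depth (0% at the INL border,
  100% at the GCL border) with peak calls and inter-band distances;
* dendritic-arbor territory areas from traced tip polygons;
* fractional retinal coverage of an arbor plexus from thresholded images;
* homotypic contact rates of dendritic tips onto a labeled target population,
  with a channel-flip chance control;
* frequency tables of categorical projection phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

__all__ = [
    "IntensityProfile",
    "ContactVolume",
    "ContactRateResult",
    "ProjectionRecord",
    "classify_dendrite_angle",
    "orientation_summary",
    "ipl_profile",
    "find_profile_peaks",
    "band_distance",
    "stratification_call",
    "arbor_territory_area",
    "plexus_coverage",
    "contact_rate",
    "flipped_control",
    "projection_frequency_table",
    "percent_decrease",
]


# ---------------------------------------------------------------------------
# dendrite orientation
# ---------------------------------------------------------------------------

def classify_dendrite_angle(
    angle_deg: float, low_cut: float = 45.0, high_cut: float = 135.0
) -> str:
    """Classify a primary-dendrite angle as ``IPL``, ``TANGENTIAL`` or ``ONBL``.

    Angles are absolute values in [0, 180] measured against a plumb line to
    the IPL, so 0° points exactly at the IPL and 180° exactly away from it.
    The quadrant cuts default to 45°/135°.
    """
    a = float(angle_deg)
    if not 0.0 <= a <= 180.0:
        raise ValueError(f"angle {a} outside [0, 180]")
    if a < low_cut:
        return "IPL"
    if a <= high_cut:
        return "TANGENTIAL"
    return "ONBL"


def orientation_summary(
    angles_deg: Sequence[float],
    low_cut: float = 45.0,
    high_cut: float = 135.0,
    bin_width_deg: float = 15.0,
) -> tuple[dict[str, float], np.ndarray, np.ndarray]:
    """Per-category dendrite-orientation fractions plus a polar histogram.

    Returns ``(fractions, bin_edges, counts)``; fractions over the categories
    IPL / TANGENTIAL / ONBL sum to 1.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("no angles given")
    labels = [classify_dendrite_angle(a, low_cut, high_cut) for a in angles]
    n = len(labels)
    fractions = {cat: labels.count(cat) / n for cat in ("IPL", "TANGENTIAL", "ONBL")}
    edges = np.arange(0.0, 180.0 + bin_width_deg / 2, bin_width_deg)
    counts, _ = np.histogram(angles, bins=edges)
    return fractions, edges, counts


# ---------------------------------------------------------------------------
# IPL stratification profiles
# ---------------------------------------------------------------------------

@dataclass
class IntensityProfile:
    """Normalized fluorescence vs % IPL depth (0 = INL border, 100 = GCL)."""

    depth_pct: np.ndarray
    intensity: np.ndarray  # background-subtracted, max-normalized to [0, 1]
    roi_width_um: float = 12.5

    def __post_init__(self) -> None:
        self.depth_pct = np.asarray(self.depth_pct, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.depth_pct.shape != self.intensity.shape:
            raise ValueError("depth and intensity must align")
        if not (np.isclose(self.intensity.max(), 1.0) and np.isclose(self.intensity.min(), 0.0)):
            raise ValueError("profile must be min-subtracted and max-normalized")

    @classmethod
    def from_raw(
        cls, depth_pct: np.ndarray, raw: np.ndarray, roi_width_um: float = 12.5
    ) -> "IntensityProfile":
        """Background-subtract (minimum) and normalize (maximum) a raw profile."""
        raw = np.asarray(raw, dtype=float)
        lo, hi = float(raw.min()), float(raw.max())
        if hi <= lo:
            raise ValueError("flat profile: cannot normalize")
        return cls(np.asarray(depth_pct, dtype=float), (raw - lo) / (hi - lo), roi_width_um)


def ipl_profile(
    image: np.ndarray,
    roi: tuple[slice, slice] | None = None,
    depth_axis: int = 0,
    roi_width_um: float = 12.5,
) -> IntensityProfile:
    """Width-averaged, normalized intensity profile across the IPL.

    Emulates drawing a vertical ROI perpendicular to the IPL strata: intensity
    at each depth is the mean across the ROI width, the background (minimum)
    is subtracted, and the result is normalized to its maximum.  ``depth_axis``
    selects which image axis runs from the INL border (index 0 → 0% depth) to
    the GCL border (last index → 100%).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if roi is not None:
        img = img[roi]
    raw = img.mean(axis=1 - depth_axis)
    depth = np.linspace(0.0, 100.0, raw.size)
    return IntensityProfile.from_raw(depth, raw, roi_width_um)


def find_profile_peaks(p: IntensityProfile, prominence: float = 0.1) -> np.ndarray:
    """Depths (% IPL) of profile peaks above a prominence floor.

    A run of equal-intensity samples forming a flat maximum (plateau) is
    reported at its center.  Returns an empty array when nothing exceeds the
    floor.
    """
    peaks, props = signal.find_peaks(p.intensity, prominence=prominence, plateau_size=1)
    if len(peaks) == 0:
        return np.empty(0)
    centers = (props["left_edges"] + props["right_edges"]) / 2.0
    idx = np.arange(p.depth_pct.size)
    return np.interp(centers, idx, p.depth_pct)


def _primary_peak(p: IntensityProfile, prominence: float) -> float:
    depths = find_profile_peaks(p, prominence=prominence)
    if depths.size == 0:
        raise ValueError("profile has no peak above the prominence floor")
    heights = np.interp(depths, p.depth_pct, p.intensity)
    return float(depths[int(np.argmax(heights))])


def band_distance(p_a: IntensityProfile, p_b: IntensityProfile, prominence: float = 0.1) -> float:
    """Distance between the primary fluorescent bands of two profiles, in % IPL."""
    return abs(_primary_peak(p_a, prominence) - _primary_peak(p_b, prominence))


def stratification_call(
    p: IntensityProfile,
    reference_depth_pct: float,
    window_pct: float = 10.0,
    min_signal_fraction: float = 0.6,
    prominence: float = 0.1,
) -> bool:
    """Whether an arbor profile is stratified at a reference IPL band.

    A formalization of a laminar-ramification judgement: the profile's
    primary peak must fall within ``window_pct`` of the reference depth, and
    at least ``min_signal_fraction`` of the (normalized) arbor signal must
    lie inside that window.  Both knobs are reconstructions of a qualitative
    criterion and should be reported alongside results.
    """
    try:
        peak = _primary_peak(p, prominence)
    except ValueError:
        return False
    if abs(peak - reference_depth_pct) > window_pct:
        return False
    inside = np.abs(p.depth_pct - reference_depth_pct) <= window_pct
    total = float(p.intensity.sum())
    return total > 0 and float(p.intensity[inside].sum()) / total >= min_signal_fraction


# ---------------------------------------------------------------------------
# arbor territory and plexus coverage
# ---------------------------------------------------------------------------

def arbor_territory_area(tips_um: np.ndarray) -> float:
    """Area (µm²) of the polygon traced through a cell's dendritic tips.

    Tips are ordered by polar angle about their centroid — a formalization of
    tracing the dendritic field tip-to-tip — and the simple-polygon area is
    taken by the shoelace formula.  Requires at least three non-collinear
    tips.
    """
    tips = np.atleast_2d(np.asarray(tips_um, dtype=float))
    if tips.shape[0] < 3 or tips.shape[1] != 2:
        raise ValueError("need at least 3 planar tips")
    centered = tips - tips.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("collinear tips enclose no area")
    order = np.argsort(np.arctan2(centered[:, 1], centered[:, 0]), kind="stable")
    v = tips[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def plexus_coverage(image: np.ndarray, threshold: float | None = None) -> float:
    """Percent of the field of view covered by labeled arbors.

    Boolean images are taken as already-thresholded masks.  Grayscale images
    are binarized at ``threshold`` if given, otherwise by Otsu's method; a
    constant image cannot be thresholded and raises.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.dtype == bool:
        return float(img.mean() * 100.0)
    if float(img.max()) == float(img.min()):
        raise ValueError("constant image: coverage undefined")
    thr = threshold_otsu(img) if threshold is None else threshold
    return float((img > thr).mean() * 100.0)


# ---------------------------------------------------------------------------
# homotypic contact rate
# ---------------------------------------------------------------------------

@dataclass
class ContactVolume:
    """Scored dendritic-tip coordinates and a 3-D target mask."""

    tip_points: np.ndarray  # (n, 3) integer voxel coordinates (z, y, x)
    target_mask: np.ndarray  # 3-D boolean
    voxel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.tip_points = np.atleast_2d(np.asarray(self.tip_points, dtype=int))
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if self.target_mask.ndim != 3 or self.tip_points.shape[1] != 3:
            raise ValueError("expected 3-D mask and (n, 3) tip coordinates")
        if np.any(self.tip_points < 0) or np.any(self.tip_points >= self.target_mask.shape):
            raise ValueError("tips outside volume bounds")


@dataclass
class ContactRateResult:
    percent: float
    n_contacting: int
    n_tips: int


def contact_rate(cv: ContactVolume, dilation_voxels: int = 0) -> ContactRateResult:
    """Fraction of dendritic tips terminating on the target population.

    A tip counts as contacting if its voxel lies in the target mask; an
    optional 1-voxel dilation emulates confocal resolution limits.
    """
    if cv.tip_points.shape[0] == 0:
        raise ValueError("no tips scored")
    mask = cv.target_mask
    if dilation_voxels > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilation_voxels)
    z, y, x = cv.tip_points.T
    hits = int(np.sum(mask[z, y, x]))
    n = cv.tip_points.shape[0]
    return ContactRateResult(100.0 * hits / n, hits, n)


def flipped_control(cv: ContactVolume, dilation_voxels: int = 0) -> ContactRateResult:
    """Chance contact rate after flipping the target channel in-plane.

    The target mask is mirrored about both in-plane (horizontal and vertical)
    axes, destroying true tip-target correspondence while preserving arbor
    density and geometry; the contact rate of the flipped volume estimates
    how often the two labels interact by chance.
    """
    flipped = cv.target_mask[:, ::-1, ::-1]
    return contact_rate(
        ContactVolume(cv.tip_points, flipped, cv.voxel_size_um), dilation_voxels=dilation_voxels
    )


# ---------------------------------------------------------------------------
# projection phenotype tables
# ---------------------------------------------------------------------------

@dataclass
class ProjectionRecord:
    """Categorical projection phenotype of one traced cell."""

    cell_id: str
    age: str
    genotype: str
    innervates_ipl: bool
    stratified: bool
    soma_layer_projection: bool

    def __post_init__(self) -> None:
        if self.stratified and not self.innervates_ipl:
            raise ValueError("a stratified cell must innervate the IPL")


_BOOL_FIELDS = ("innervates_ipl", "stratified", "soma_layer_projection")


def projection_frequency_table(
    records: Iterable[ProjectionRecord] | pd.DataFrame,
    group_by: Sequence[str] = ("genotype", "age"),
) -> pd.DataFrame:
    """Per-group phenotype frequencies with binomial standard errors.

    For each group (by default genotype × age) and each boolean phenotype
    field, reports the fraction of positive cells as a percentage, the
    binomial standard error ``100·sqrt(p(1−p)/n)``, and the group size.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        raise ValueError("no records")
    rows = []
    for key, grp in df.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        row: dict[str, object] = dict(zip(group_by, key))
        row["n_cells"] = n
        for f in _BOOL_FIELDS:
            if f not in grp:
                continue
            p = float(grp[f].mean())
            row[f"{f}_pct"] = 100.0 * p
            row[f"{f}_se_pct"] = 100.0 * float(np.sqrt(p * (1 - p) / n))
        rows.append(row)
    return pd.DataFrame(rows)


def percent_decrease(control: float, test: float) -> float:
    """Decrease of ``test`` relative to ``control``, as a percentage of control."""
    if control == 0:
        raise ValueError("control value must be nonzero")
    return 100.0 * (control - test) / control
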