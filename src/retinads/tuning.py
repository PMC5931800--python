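"""Direction-tuning statistics for retinal ganglion cell spike trains.

The quantities computed here are the standard single-cell descriptors of
direction selectivity measured with a bar moving in ``n`` equally spaced
directions:

* **DSI** — direction selectivity index, the magnitude of the spike-count
  weighted vector sum over directions normalized by the total spike count,
  ``DSI = |Σ n_i u(θ_i)| / Σ n_i`` with ``u`` the unit vector.  0 for an
  untuned cell, 1 when all spikes occur for a single direction.
* **Tuning width** — the circular standard deviation of the count-weighted
  direction distribution, ``σ_circ = sqrt(−2 ln R̄)`` where ``R̄`` is the
  mean resultant length.  A nonparametric width estimate: no fit required.
* **von Mises fit** — least-squares fit of
  ``A·exp(κ cos(θ−μ)) / (2π I0(κ))`` to the tuning curve, for display and
  parametric summaries (μ = preferred direction, κ = concentration).
* **Tuning strength** — ``(P − N)/(P + N)`` where the preferred response P
  (null response N) is a cosine-weighted sum of the two sampled directions
  nearest the preferred (null) axis; accounts for preferred directions that
  fall between the sampled 30° grid.
* **ON/OFF segmentation** — ON-OFF DS cells respond twice to a bright bar
  (leading and trailing edge); the two response lobes are separated at the
  midpoint between the two peaks of the pooled PSTH, and per-phase tuning
  curves give the ON/OFF preferred-direction difference Δϕ.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, special
from scipy.ndimage import gaussian_filter1d

if TYPE_CHECKING:  # pragma: no cover
    from retinads.synthetic import StimulusProtocol

__all__ = [
    "SpikeResponseSet",
    "TuningCurve",
    "TuningMetrics",
    "OnOffSplit",
    "OnOffSeparationError",
    "VonMisesFit",
    "compute_tuning_curve",
    "compute_dsi",
    "circular_stats",
    "fit_von_mises",
    "tuning_strength",
    "split_on_off",
    "delta_phi",
    "compute_metrics",
    "ang_diff_deg",
    "circular_mean_deg",
]


class OnOffSeparationError(ValueError):
    """Raised when a cell's pooled PSTH does not show two separable peaks."""


# ---------------------------------------------------------------------------
# circular helpers
# ---------------------------------------------------------------------------

def ang_diff_deg(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    """Minimal absolute angular difference between directions, in [0, 180]."""
    d = np.abs((np.asarray(a, dtype=float) - b) % 360.0)
    return np.where(d > 180.0, 360.0 - d, d)[()] if np.ndim(d) else min(d, 360.0 - d)


def circular_mean_deg(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean direction in degrees, in [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    return float(np.rad2deg(np.arctan2(np.sum(w * np.sin(a)), np.sum(w * np.cos(a)))) % 360.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class SpikeResponseSet:
    """Per-cell, per-condition, per-trial spike times with stimulus metadata.

    Internally a mapping ``(cell_id, direction_deg, contrast_pct) -> list of
    per-trial spike-time arrays`` (seconds from trial onset).  Every cell is
    expected to carry every condition, possibly with empty trials.
    """

    def __init__(
        self,
        trial_duration_s: float,
        speed_um_s: float = 400.0,
        protocol: "StimulusProtocol | None" = None,
    ) -> None:
        self.trial_duration_s = float(trial_duration_s)
        self.speed_um_s = float(speed_um_s)
        self.protocol = protocol
        self._trials: dict[tuple[str, float, float], list[np.ndarray]] = {}

    # -- construction ------------------------------------------------------
    def add(
        self,
        cell_id: str,
        direction_deg: float,
        contrast_pct: float,
        trials: Sequence[np.ndarray],
    ) -> None:
        key = (str(cell_id), float(direction_deg), float(contrast_pct))
        self._trials[key] = [np.asarray(t, dtype=float) for t in trials]

    # -- views -------------------------------------------------------------
    @property
    def cells(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, _, _ in self._trials:
            seen.setdefault(c)
        return list(seen)

    @property
    def directions(self) -> np.ndarray:
        return np.array(sorted({d for _, d, _ in self._trials}))

    @property
    def contrasts(self) -> np.ndarray:
        return np.array(sorted({c for _, _, c in self._trials}))

    def trials(self, cell_id: str, direction_deg: float, contrast_pct: float) -> list[np.ndarray]:
        key = (str(cell_id), float(direction_deg), float(contrast_pct))
        if key not in self._trials:
            raise KeyError(f"no recorded condition {key}")
        return self._trials[key]

    def pooled_spikes(self, cell_id: str, contrasts: Iterable[float] | None = None) -> np.ndarray:
        """All spike times of one cell pooled over directions (and contrasts)."""
        sel = set(float(c) for c in contrasts) if contrasts is not None else None
        chunks = [
            t
            for (c, _, con), trials in self._trials.items()
            if c == cell_id and (sel is None or con in sel)
            for t in trials
        ]
        return np.sort(np.concatenate(chunks)) if chunks else np.empty(0)

    def global_spike_train(self, cell_id: str) -> tuple[np.ndarray, float]:
        """One cell's spikes on a continuous timeline, trials laid end to end.

        Conditions are visited in sorted order so the layout is deterministic.
        Returns ``(times, total_duration)`` — the form expected by
        spike-sorting quality filters, where inter-spike intervals are only
        meaningful within a trial.
        """
        dur = self.trial_duration_s
        chunks: list[np.ndarray] = []
        slot = 0
        for key in sorted(k for k in self._trials if k[0] == cell_id):
            for t in self._trials[key]:
                chunks.append(t + slot * dur)
                slot += 1
        times = np.concatenate(chunks) if chunks else np.empty(0)
        return np.sort(times), slot * dur

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per spike (empty trials carried by metadata)."""
        rows = []
        for (cell, direc, con), trials in self._trials.items():
            for trial_idx, t in enumerate(trials):
                for s in t:
                    rows.append((cell, direc, con, self.speed_um_s, trial_idx, s))
        return pd.DataFrame(
            rows,
            columns=["cell_id", "direction_deg", "contrast_pct", "speed_um_s", "trial", "spike_time_s"],
        )

    def write(self, table_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        table_path = Path(table_path)
        self.to_frame().to_csv(table_path, index=False)
        meta = {
            "trial_duration_s": self.trial_duration_s,
            "speed_um_s": self.speed_um_s,
            "conditions": [
                {"cell_id": c, "direction_deg": d, "contrast_pct": con, "n_trials": len(tr)}
                for (c, d, con), tr in self._trials.items()
            ],
        }
        sidecar = Path(sidecar_path) if sidecar_path else table_path.with_suffix(".json")
        sidecar.write_text(json.dumps(meta))

    @classmethod
    def read(cls, table_path: str | Path, sidecar_path: str | Path | None = None) -> "SpikeResponseSet":
        table_path = Path(table_path)
        sidecar = Path(sidecar_path) if sidecar_path else table_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        rs = cls(meta["trial_duration_s"], meta["speed_um_s"])
        df = pd.read_csv(table_path)
        grouped: dict[tuple, dict[int, list[float]]] = {}
        for row in df.itertuples(index=False):
            key = (str(row.cell_id), float(row.direction_deg), float(row.contrast_pct))
            grouped.setdefault(key, {}).setdefault(int(row.trial), []).append(float(row.spike_time_s))
        for cond in meta["conditions"]:
            key = (str(cond["cell_id"]), float(cond["direction_deg"]), float(cond["contrast_pct"]))
            per_trial = grouped.get(key, {})
            rs._trials[key] = [
                np.sort(np.array(per_trial.get(i, []), dtype=float)) for i in range(cond["n_trials"])
            ]
        return rs


@dataclass
class TuningCurve:
    """Spike counts per motion direction for one cell at one contrast."""

    directions_deg: np.ndarray
    counts: np.ndarray
    contrast_pct: float | None = None
    phase: str = "ALL"  # ALL | ON | OFF

    def __post_init__(self) -> None:
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.directions_deg.shape != self.counts.shape:
            raise ValueError("directions and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def total(self) -> float:
        return float(np.sum(self.counts))


@dataclass
class VonMisesFit:
    mu_deg: float
    kappa: float
    amplitude: float
    converged: bool


@dataclass
class TuningMetrics:
    """Summary tuning statistics for one cell at one contrast."""

    dsi: float
    pref_dir_deg: float
    null_dir_deg: float
    width_rad: float
    strength: float
    r_bar: float
    vm_mu_deg: float = np.nan
    vm_kappa: float = np.nan

    @property
    def width_deg(self) -> float:
        return float(np.rad2deg(self.width_rad))


@dataclass
class OnOffSplit:
    """ON/OFF temporal segmentation of a bar response and per-phase tuning."""

    boundary_time_s: float
    on_peak_time_s: float
    off_peak_time_s: float
    on_curve: TuningCurve
    off_curve: TuningCurve
    peak_ratio: float  # smaller / larger smoothed PSTH peak height
    delta_phi_deg: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_tuning_curve(
    rs: SpikeResponseSet,
    cell_id: str,
    contrast_pct: float,
    phase: str = "ALL",
    boundary_time_s: float | None = None,
) -> TuningCurve:
    """Total spike count across trials for each direction of bar movement.

    ``phase='ON'`` keeps spikes before ``boundary_time_s``, ``'OFF'`` keeps
    spikes at or after it (the boundary comes from :func:`split_on_off`).
    """
    if phase not in ("ALL", "ON", "OFF"):
        raise ValueError(f"unknown phase {phase!r}")
    if phase != "ALL" and boundary_time_s is None:
        raise ValueError("ON/OFF phase requires a boundary time")
    directions = rs.directions
    counts = np.zeros(len(directions))
    for i, d in enumerate(directions):
        for t in rs.trials(cell_id, d, contrast_pct):
            if phase == "ALL":
                counts[i] += t.size
            elif phase == "ON":
                counts[i] += int(np.sum(t < boundary_time_s))
            else:
                counts[i] += int(np.sum(t >= boundary_time_s))
    return TuningCurve(directions, counts, contrast_pct=contrast_pct, phase=phase)


def compute_dsi(tc: TuningCurve) -> float:
    """Direction selectivity index ``|Σ n_i v_i| / Σ n_i``, in [0, 1].

    ``v_i`` is the unit vector along direction ``θ_i``.  An all-zero curve has
    no defined DSI and returns NaN with a warning.
    """
    total = tc.total
    if total == 0:
        warnings.warn("all-zero tuning curve: DSI undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    rad = np.deg2rad(tc.directions_deg)
    vx = float(np.sum(tc.counts * np.cos(rad)))
    vy = float(np.sum(tc.counts * np.sin(rad)))
    return float(np.hypot(vx, vy) / total)


def circular_stats(tc: TuningCurve) -> tuple[float, float, float]:
    """Mean resultant length, circular mean and circular SD of a tuning curve.

    Returns ``(R_bar, circ_mean_deg, sigma_circ_rad)`` with
    ``sigma_circ = sqrt(−2 ln R_bar)``.  ``R_bar = 0`` (perfectly uniform)
    maps to ``sigma_circ = +inf``; ``R_bar = 1`` to 0.
    """
    total = tc.total
    if total == 0:
        raise ValueError("all-zero tuning curve: circular statistics undefined")
    rad = np.deg2rad(tc.directions_deg)
    cx = float(np.sum(tc.counts * np.cos(rad)) / total)
    sx = float(np.sum(tc.counts * np.sin(rad)) / total)
    r_bar = float(np.hypot(cx, sx))
    mean_deg = float(np.rad2deg(np.arctan2(sx, cx)) % 360.0)
    # snap the degenerate ends: float cancellation leaves R within ~1e-16 of
    # the exact 0 (uniform) or 1 (point mass) cases
    if r_bar <= 1e-12:
        sigma = float("inf")
    elif r_bar >= 1.0 - 1e-12:
        sigma = 0.0
    else:
        sigma = float(np.sqrt(-2.0 * np.log(r_bar)))
    return r_bar, mean_deg, sigma


def kappa_from_rbar(r_bar: float) -> float:
    """Invert the Bessel-function ratio ``R̄ = I1(κ)/I0(κ)`` (Best-Fisher)."""
    r = float(np.clip(r_bar, 0.0, 1.0 - 1e-12))
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def _vm_model(theta_rad: np.ndarray, amplitude: float, kappa: float, mu_rad: float) -> np.ndarray:
    return amplitude * np.exp(kappa * np.cos(theta_rad - mu_rad)) / (2 * np.pi * special.i0(kappa))


def fit_von_mises(tc: TuningCurve) -> VonMisesFit:
    """Nonlinear least-squares von Mises fit ``A·e^{κcos(θ−μ)} / (2π I0(κ))``.

    Initialized at μ = circular mean and κ from inverting the Bessel ratio.
    On non-convergence the initialization values are returned, flagged as a
    fallback.  Requires at least three nonzero directions.
    """
    if tc.total == 0:
        raise ValueError("all-zero tuning curve: cannot fit")
    if int(np.sum(tc.counts > 0)) < 3:
        raise ValueError("von Mises fit needs >= 3 nonzero directions")
    r_bar, mean_deg, _ = circular_stats(tc)
    kappa0 = max(kappa_from_rbar(r_bar), 1e-3)
    mu0 = np.deg2rad(mean_deg)
    amp0 = float(np.max(tc.counts)) * 2 * np.pi * special.i0(kappa0) * np.exp(-kappa0)
    theta = np.deg2rad(tc.directions_deg)
    try:
        popt, _ = optimize.curve_fit(
            _vm_model,
            theta,
            tc.counts,
            p0=[max(amp0, 1e-6), kappa0, mu0],
            bounds=([1e-9, 0.0, mu0 - np.pi], [np.inf, 500.0, mu0 + np.pi]),
            maxfev=5000,
        )
        amp, kappa, mu = popt
        return VonMisesFit(float(np.rad2deg(mu) % 360.0), float(kappa), float(amp), True)
    except (RuntimeError, ValueError):
        return VonMisesFit(mean_deg, kappa0, float(amp0), False)


def tuning_strength(tc: TuningCurve) -> float:
    """Preferred-minus-null response contrast ``(P − N)/(P + N)``.

    The preferred direction is the resultant-vector angle (continuous, not an
    argmax bin); because tuning curves are sampled on a 30° grid, P is the sum
    of the two sampled responses nearest the preferred axis, each weighted by
    the cosine of its angular offset from that axis; N analogously for the
    null axis (preferred + 180°).  Returns NaN with a warning when P + N = 0.
    """
    if tc.total == 0:
        warnings.warn("all-zero tuning curve: strength undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    _, pref, _ = circular_stats(tc)
    null = (pref + 180.0) % 360.0

    def lobe(target: float) -> float:
        offsets = np.asarray(ang_diff_deg(tc.directions_deg, target), dtype=float)
        nearest = np.argsort(offsets, kind="stable")[:2]
        return float(np.sum(tc.counts[nearest] * np.cos(np.deg2rad(offsets[nearest]))))

    p, n = lobe(pref), lobe(null)
    if p + n == 0:
        warnings.warn("zero preferred+null response: strength undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return (p - n) / (p + n)


def split_on_off(
    rs: SpikeResponseSet,
    cell_id: str,
    high_contrasts: Sequence[float] | None = None,
    curve_contrast: float | None = None,
    bin_ms: float = 1.0,
    smooth_sigma_ms: float = 25.0,
    min_peak_height_frac: float = 0.05,
) -> OnOffSplit:
    """Separate ON and OFF response lobes of a bar response.

    The PSTH pooled over all directions at high contrast (default: the two
    highest contrasts present) is binned at 1 ms, smoothed with a Gaussian
    kernel, and the two tallest temporal peaks identified; the ON/OFF boundary
    is the midpoint between their times.  Per-phase tuning curves are then
    computed at ``curve_contrast`` (default: the highest contrast).  The same
    boundary is intended to be reused across contrasts.

    Raises :class:`OnOffSeparationError` if fewer than two separable peaks are
    found (the cell is then not an ON-OFF DS cell).
    """
    contrasts = rs.contrasts
    if high_contrasts is None:
        high_contrasts = contrasts[-2:] if len(contrasts) >= 2 else contrasts
    spikes = rs.pooled_spikes(cell_id, contrasts=high_contrasts)
    if spikes.size == 0:
        raise OnOffSeparationError(f"cell {cell_id}: no spikes at high contrast")
    n_bins = max(2, int(round(rs.trial_duration_s * 1000.0 / bin_ms)))
    hist, edges = np.histogram(spikes, bins=n_bins, range=(0.0, rs.trial_duration_s))
    smoothed = gaussian_filter1d(hist.astype(float), sigma=smooth_sigma_ms / bin_ms)
    peaks, props = signal.find_peaks(smoothed, height=min_peak_height_frac * smoothed.max())
    if len(peaks) < 2:
        raise OnOffSeparationError(f"cell {cell_id}: fewer than two temporal response peaks")
    top2 = peaks[np.argsort(props["peak_heights"], kind="stable")[-2:]]
    top2 = np.sort(top2)
    centers = (edges[:-1] + edges[1:]) / 2.0
    t_on, t_off = float(centers[top2[0]]), float(centers[top2[1]])
    heights = smoothed[top2]
    ratio = float(np.min(heights) / np.max(heights))
    boundary = 0.5 * (t_on + t_off)
    if curve_contrast is None:
        curve_contrast = float(contrasts[-1])
    on_curve = compute_tuning_curve(rs, cell_id, curve_contrast, phase="ON", boundary_time_s=boundary)
    off_curve = compute_tuning_curve(rs, cell_id, curve_contrast, phase="OFF", boundary_time_s=boundary)
    out = OnOffSplit(boundary, t_on, t_off, on_curve, off_curve, ratio)
    out.delta_phi_deg = delta_phi(out)
    return out


def delta_phi(split: OnOffSplit) -> float:
    """Angular difference between ON and OFF preferred directions, in [0, 180].

    Preferred directions are the resultant-vector angles of the per-phase
    tuning curves.  NaN with a warning if either phase curve is all zero.
    """
    if split.on_curve.total == 0 or split.off_curve.total == 0:
        warnings.warn("empty ON or OFF phase curve: delta-phi undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    _, on_dir, _ = circular_stats(split.on_curve)
    _, off_dir, _ = circular_stats(split.off_curve)
    return float(ang_diff_deg(on_dir, off_dir))


def compute_metrics(tc: TuningCurve, fit: bool = False) -> TuningMetrics:
    """Bundle DSI, preferred/null direction, width, strength for one curve."""
    dsi = compute_dsi(tc)
    r_bar, pref, sigma = circular_stats(tc)
    strength = tuning_strength(tc)
    m = TuningMetrics(
        dsi=dsi,
        pref_dir_deg=pref,
        null_dir_deg=(pref + 180.0) % 360.0,
        width_rad=sigma,
        strength=strength,
        r_bar=r_bar,
    )
    if fit and int(np.sum(tc.counts > 0)) >= 3:
        vm = fit_von_mises(tc)
        m.vm_mu_deg, m.vm_kappa = vm.mu_deg, vm.kappa
    return m
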