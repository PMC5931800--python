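"""Population gating and classification of direction-selective ganglion cells.

A recorded retinal ganglion cell population is filtered and classified in
stages: spike-sorting quality control (refractory-period contamination and
minimum firing rate), DSGC gating on the bimodal DSI histogram with a
two-Gaussian mixture model, isolation of ON-OFF DS cells by their two
temporal response lobes, circular K-means assignment of the four
cardinal-direction subtypes, and two-sample Kolmogorov-Smirnov comparison of
tuning-metric distributions between genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from retinads.tuning import (
    OnOffSeparationError,
    OnOffSplit,
    SpikeResponseSet,
    ang_diff_deg,
    circular_mean_deg,
    split_on_off,
)

__all__ = [
    "DsiMixture",
    "CellLabel",
    "qc_filter",
    "gate_dsgc",
    "isolate_oods",
    "assign_subtypes",
    "compare_populations",
]


@dataclass
class DsiMixture:
    """Two-Gaussian mixture fit to a DSI histogram and the derived threshold."""

    weights: np.ndarray
    means: np.ndarray  # ordered low, high
    sds: np.ndarray
    crossing_threshold: float  # DSI separating the two components (the one used)
    fallback_threshold: float = 0.25
    used_fallback: bool = False


@dataclass
class CellLabel:
    cell_id: str
    is_ds: bool = False
    is_oods: bool = False
    subtype: int | None = None
    qc_pass: bool = True
    qc_reason: str | None = None


def qc_filter(
    spike_times_s: np.ndarray,
    recording_duration_s: float,
    refractory_ms: float = 1.5,
    contamination_max: float = 0.10,
    min_rate_hz: float = 1.0,
) -> tuple[bool, str | None]:
    """Spike-sorting quality filter.

    Contamination is estimated as the fraction of inter-spike intervals
    shorter than the refractory period (default 1.5 ms); clusters with more
    than 10% contamination, or mean firing rates below 1 Hz, fail.
    Returns ``(passed, reason)`` with reason ``'contamination'`` or ``'rate'``.
    """
    if recording_duration_s <= 0:
        raise ValueError("recording duration must be positive")
    t = np.sort(np.asarray(spike_times_s, dtype=float))
    if t.size >= 2:
        isi = np.diff(t)
        contamination = float(np.mean(isi < refractory_ms / 1000.0))
        if contamination > contamination_max:
            return False, "contamination"
    rate = t.size / recording_duration_s
    if rate < min_rate_hz:
        return False, "rate"
    return True, None


def _mixture_crossing(mix: GaussianMixture) -> float | None:
    """DSI where the two weighted component densities cross, between the means."""
    order = np.argsort(mix.means_.ravel())
    w = mix.weights_[order]
    mu = mix.means_.ravel()[order]
    sd = np.sqrt(mix.covariances_.ravel()[order])

    def diff(x: float) -> float:
        return w[0] * stats.norm.pdf(x, mu[0], sd[0]) - w[1] * stats.norm.pdf(x, mu[1], sd[1])

    grid = np.linspace(mu[0], mu[1], 512)
    vals = diff(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    return float(optimize.brentq(diff, grid[i], grid[i + 1]))


def gate_dsgc(
    dsi_values: np.ndarray,
    fallback_threshold: float = 0.25,
    random_state: int = 0,
) -> tuple[DsiMixture, np.ndarray]:
    """Separate DS from non-DS cells on the bimodal DSI histogram.

    A two-component 1-D Gaussian mixture is fit to the DSI values; the gating
    threshold is the density-crossing point between the two components, and
    cells above it are labeled DS.  If the fit is not convincingly bimodal
    (component means closer than the pooled SD), or with fewer than 20 cells,
    a fixed threshold (default 0.25) is used instead.
    """
    dsi = np.asarray(dsi_values, dtype=float)
    finite = dsi[np.isfinite(dsi)]

    def fallback(msg: str) -> tuple[DsiMixture, np.ndarray]:
        warnings.warn(f"DSI gating fell back to fixed threshold: {msg}", RuntimeWarning, stacklevel=3)
        mixture = DsiMixture(
            weights=np.array([np.nan, np.nan]),
            means=np.array([np.nan, np.nan]),
            sds=np.array([np.nan, np.nan]),
            crossing_threshold=fallback_threshold,
            fallback_threshold=fallback_threshold,
            used_fallback=True,
        )
        return mixture, dsi > fallback_threshold

    if finite.size < 20:
        return fallback("fewer than 20 cells")
    if np.allclose(finite, finite[0]):
        return fallback("degenerate (constant) DSI sample")
    gm = GaussianMixture(n_components=2, n_init=10, random_state=random_state)
    gm.fit(finite.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    mu = gm.means_.ravel()[order]
    var = gm.covariances_.ravel()[order]
    sd = np.sqrt(var)
    pooled_sd = float(np.sqrt(w @ var))
    if (mu[1] - mu[0]) <= pooled_sd:
        return fallback("mixture not bimodal (means closer than pooled SD)")
    crossing = _mixture_crossing(gm)
    if crossing is None:
        return fallback("no density crossing between component means")
    mixture = DsiMixture(w, mu, sd, crossing, fallback_threshold, used_fallback=False)
    return mixture, dsi > crossing


def isolate_oods(
    rs: SpikeResponseSet,
    ds_cells: Sequence[str],
    min_lobe_ratio: float = 0.2,
    **split_kwargs,
) -> tuple[dict[str, bool], dict[str, OnOffSplit]]:
    """Isolate ON-OFF DS cells among gated DSGCs.

    A DS cell is an ooDSGC if its pooled high-contrast PSTH shows two
    separable temporal peaks (responses to the bar entering and exiting the
    receptive field) whose smaller peak is at least ``min_lobe_ratio`` of the
    larger.  Returns the per-cell verdicts and the ON/OFF splits of cells
    where two peaks were found.
    """
    labels: dict[str, bool] = {}
    splits: dict[str, OnOffSplit] = {}
    for cell in ds_cells:
        try:
            split = split_on_off(rs, cell, **split_kwargs)
        except OnOffSeparationError:
            labels[cell] = False
            continue
        splits[cell] = split
        labels[cell] = split.peak_ratio >= min_lobe_ratio
    return labels, splits


def assign_subtypes(
    pref_dirs_deg: np.ndarray,
    seeds_deg: Sequence[float] = (0.0, 90.0, 180.0, 270.0),
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster preferred directions into cardinal subtypes by circular K-means.

    Cluster centers start at the four cardinal directions; each cell joins
    the cluster with the minimum angular difference to its center; centers
    update to the circular mean of their members; empty clusters retain their
    seed.  Iterates to convergence.  Returns ``(labels, centers_deg)``.
    """
    dirs = np.asarray(pref_dirs_deg, dtype=float) % 360.0
    if dirs.size < 4:
        raise ValueError("need at least 4 cells for subtype clustering")
    centers = np.asarray(seeds_deg, dtype=float) % 360.0
    labels = np.zeros(dirs.size, dtype=int)
    for _ in range(max_iter):
        dist = np.stack([np.asarray(ang_diff_deg(dirs, c)) for c in centers])
        new_labels = np.argmin(dist, axis=0)
        new_centers = centers.copy()
        for k in range(len(centers)):
            members = dirs[new_labels == k]
            if members.size:
                new_centers[k] = circular_mean_deg(members)
        if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
            break
        labels, centers = new_labels, new_centers
    return labels, centers


def compare_populations(metric_a: np.ndarray, metric_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of metric distributions.

    Used to compare cumulative distributions of tuning width, strength or Δϕ
    between genotype populations.  NaNs are dropped.  Returns
    ``(ks_statistic, p_value)``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
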