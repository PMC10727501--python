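"""Regression-based selection and functional clustering of ROI traces.

Candidate stimulus-coding ROIs are those whose trace correlates at >= 0.25
with any of the six stimulus regressors; of these, only ROIs whose trace
correlates at >= 0.3 with at least five ROIs imaged in *other* fish are
kept, discarding responses idiosyncratic to single animals.  The surviving
traces are clustered by affinity propagation on the Pearson correlation
matrix (damping 0.9, preference -9); the emerging exemplars are ordered by
a complete-linkage correlation-distance tree and named by a two-part
taxonomy — adaptation profile (from the late/early flash-locked response
ratio) and response shape (onset latency and duration of the flash-locked
mean).  Finally every ROI (including those dropped by the filters) is
re-scanned against the cluster mean traces and assigned to its
best-correlated cluster when that correlation reaches 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import AffinityPropagation

from .protocol import DarkFlashProtocol, RegressorSet

__all__ = [
    "ClusterModel",
    "correlate_rois",
    "filter_stimulus_tuned",
    "cross_fish_filter",
    "affinity_propagation_cluster",
    "order_and_name_clusters",
    "reassign_all_rois",
    "motor_correlation_by_cluster",
    "cluster_proportions_by_treatment",
    "build_motion_regressor",
]

#: Late/early flash-response-ratio boundaries of the adaptation taxonomy.
ADAPTATION_BINS = {"Pot": 1.1, "noA": 0.8, "weakD": 0.5, "medD": 0.2}
#: Half-maximum response-duration boundaries (s) separating S / M / L shapes.
SHAPE_DURATION_BOUNDS = (4.0, 8.5)


def _zscore_rows(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    zero = sd == 0
    safe = np.where(zero, 1.0, sd)
    z = (x - x.mean(axis=1, keepdims=True)) / safe[:, None]
    z[zero] = 0.0
    return z, zero


def correlate_rois(traces: np.ndarray,
                   regressors: RegressorSet | np.ndarray,
                   regressor_names: Sequence[str] | None = None
                   ) -> pd.DataFrame:
    """Pearson correlation of every ROI trace with every regressor.

    Regressors sampled on a different grid are linearly resampled to the
    trace length.  Zero-variance traces get correlation 0 with a warning.
    """
    traces = np.asarray(traces, dtype=float)
    if isinstance(regressors, RegressorSet):
        reg = regressors.as_matrix()
        names = regressors.names
    else:
        reg = np.asarray(regressors, dtype=float)
        if reg.ndim == 1:
            reg = reg[None, :]
        names = list(regressor_names) if regressor_names is not None \
            else [f"reg{i}" for i in range(reg.shape[0])]
    n_frames = traces.shape[1]
    if reg.shape[1] != n_frames:
        if abs(reg.shape[1] - n_frames) / n_frames > 0.05:
            raise ValueError(
                f"regressor length {reg.shape[1]} incompatible with trace "
                f"length {n_frames}")
        old = np.linspace(0.0, 1.0, reg.shape[1])
        new = np.linspace(0.0, 1.0, n_frames)
        reg = np.array([np.interp(new, old, r) for r in reg])
    tz, tzero = _zscore_rows(traces)
    rz, rzero = _zscore_rows(reg)
    if tzero.any():
        warnings.warn(f"{int(tzero.sum())} zero-variance traces; their "
                      "correlations are 0", stacklevel=2)
    if rzero.any():
        raise ValueError("zero-variance regressor")
    corr = tz @ rz.T / n_frames
    return pd.DataFrame(corr, columns=names)


def filter_stimulus_tuned(corr: pd.DataFrame,
                          threshold: float = 0.25) -> np.ndarray:
    """Keep ROIs whose best stimulus-regressor correlation is >= threshold
    (inclusive).  Returns a boolean mask."""
    return corr.max(axis=1).to_numpy() >= threshold


def cross_fish_filter(traces: np.ndarray, fish_ids: np.ndarray,
                      corr_thresh: float = 0.3,
                      min_matches: int = 5) -> np.ndarray:
    """Keep ROIs reproducible across animals.

    An ROI survives when at least ``min_matches`` ROIs recorded in *other*
    fish (pooled over all other fish) correlate with it at
    >= ``corr_thresh``.  Returns a boolean mask.
    """
    fish_ids = np.asarray(fish_ids)
    if len(np.unique(fish_ids)) < 2:
        raise ValueError("cross-fish filtering needs at least two fish")
    z, _ = _zscore_rows(traces)
    corr = z @ z.T / z.shape[1]
    other = fish_ids[:, None] != fish_ids[None, :]
    n_matches = ((corr >= corr_thresh) & other).sum(axis=1)
    return n_matches >= min_matches


def affinity_propagation_cluster(traces: np.ndarray, damping: float = 0.9,
                                 preference: float = -9.0,
                                 max_iter: int = 1000,
                                 convergence_iter: int = 15,
                                 random_state: int = 0
                                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Affinity propagation on the Pearson correlation matrix.

    Returns (labels, exemplar row indices).  The cluster count is not set a
    priori; it emerges from the preference (the self-similarity assigned to
    every point).  Raises on non-convergence with iteration diagnostics.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.shape[0] < 2:
        raise ValueError("need at least two ROIs to cluster")
    sim = np.corrcoef(traces)
    with warnings.catch_warnings():
        warnings.simplefilter("error",
                              category=__import__("sklearn").exceptions
                              .ConvergenceWarning)
        try:
            ap = AffinityPropagation(
                affinity="precomputed", damping=damping,
                preference=preference, max_iter=max_iter,
                convergence_iter=convergence_iter,
                random_state=random_state).fit(sim)
        except Exception as err:  # ConvergenceWarning escalated
            raise RuntimeError(
                f"affinity propagation did not converge within {max_iter} "
                f"iterations (damping={damping}, preference={preference})"
            ) from err
    if len(ap.cluster_centers_indices_) == 0:
        raise RuntimeError("affinity propagation produced no exemplars "
                           f"after {ap.n_iter_} iterations")
    return ap.labels_, ap.cluster_centers_indices_


@dataclass
class ClusterModel:
    """Ordered, named functional clusters with z-scored mean traces."""

    mean_traces: np.ndarray          # (K, n_frames), z-scored
    names: list                      # e.g. "4LstrgD", ordered 1..K
    adaptation: list
    shape: list
    linkage: np.ndarray = field(repr=False, default=None)  # type: ignore
    sample_rate: float = 1.98

    @property
    def n_clusters(self) -> int:
        return self.mean_traces.shape[0]


def _flash_segments(trace: np.ndarray, onsets_s: np.ndarray, rate: float,
                    window_s: float = 30.0) -> np.ndarray:
    win = int(round(window_s * rate))
    segs = []
    for onset in onsets_s:
        i0 = int(round(onset * rate))
        seg = trace[i0:i0 + win]
        if len(seg) < win:
            seg = np.pad(seg, (0, win - len(seg)), constant_values=seg[-1])
        base = trace[i0 - 1] if i0 > 0 else 0.0
        segs.append(seg - base)
    return np.array(segs)


def classify_cluster(mean_trace: np.ndarray, protocol: DarkFlashProtocol,
                     rate: float,
                     n_edge: int = 3,
                     onset_frac: float = 0.15,
                     duration_bounds: Tuple[float, float]
                     = SHAPE_DURATION_BOUNDS) -> Tuple[str, str]:
    """Adaptation and shape labels of one cluster mean trace.

    Adaptation: ratio of mean flash-locked peak response over the last
    ``n_edge`` flashes to the first ``n_edge``, binned per
    ``ADAPTATION_BINS``.  Shape: On when the naive flash-locked response
    first rises (to ``onset_frac`` of peak) only after the lights-off
    period; otherwise S / M / L by the time the response stays above half
    maximum, split at ``duration_bounds`` seconds.
    """
    onsets = protocol.flash_onsets[:protocol.flashes_per_block]
    segs = _flash_segments(mean_trace, onsets, rate)
    peaks = segs.max(axis=1)
    early = peaks[:n_edge].mean()
    late = peaks[-n_edge:].mean()
    if early <= 1e-12:
        ratio = np.inf if late > 1e-12 else 1.0
    else:
        ratio = late / early
    if ratio > ADAPTATION_BINS["Pot"]:
        adapt = "Pot"
    elif ratio > ADAPTATION_BINS["noA"]:
        adapt = "noA"
    elif ratio > ADAPTATION_BINS["weakD"]:
        adapt = "weakD"
    elif ratio > ADAPTATION_BINS["medD"]:
        adapt = "medD"
    else:
        adapt = "strgD"

    naive = segs[:n_edge].mean(axis=0)
    naive = naive - naive[0]
    peak = naive.max()
    if peak <= 0:
        return adapt, "S"
    j = int(np.argmax(naive >= onset_frac * peak))
    # frame-centre convention: subtract half a frame from the crossing time
    onset_s = max(0.0, j / rate - 0.5 / rate)
    if onset_s > protocol.off_duration:
        shape = "On"
    else:
        dur = float((naive >= 0.5 * peak).sum()) / rate
        lo, hi = duration_bounds
        shape = "S" if dur <= lo else ("M" if dur <= hi else "L")
    return adapt, shape


def order_and_name_clusters(traces: np.ndarray, labels: np.ndarray,
                            protocol: DarkFlashProtocol,
                            rate: float | None = None,
                            duration_bounds: Tuple[float, float]
                            = SHAPE_DURATION_BOUNDS) -> ClusterModel:
    """Order clusters on a complete-linkage correlation tree and name them.

    Cluster ids (1..K) follow the dendrogram leaf order; each name combines
    the id with the shape and adaptation labels, e.g. ``4LstrgD``.
    """
    rate = rate or protocol.sample_rate
    ids = np.unique(labels[labels >= 0])
    if len(ids) < 2:
        raise ValueError("need at least two clusters to order")
    z, _ = _zscore_rows(np.asarray(traces, dtype=float))
    means = np.array([z[labels == k].mean(axis=0) for k in ids])
    means, _ = _zscore_rows(means)
    corr = np.corrcoef(means)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="complete")
    order = hierarchy.leaves_list(link)
    means = means[order]
    names, adapts, shapes = [], [], []
    for i, m in enumerate(means):
        adapt, shape = classify_cluster(m, protocol, rate,
                                        duration_bounds=duration_bounds)
        adapts.append(adapt)
        shapes.append(shape)
        names.append(f"{i + 1}{shape}{adapt}")
    return ClusterModel(mean_traces=means, names=names, adaptation=adapts,
                        shape=shapes, linkage=link, sample_rate=rate)


def reassign_all_rois(traces: np.ndarray, cluster_means: np.ndarray,
                      threshold: float = 0.3) -> pd.DataFrame:
    """Assign every ROI to its best-correlated cluster mean.

    Assignment requires the maximum correlation to reach ``threshold``
    (inclusive); otherwise the ROI stays unassigned (cluster -1).  Ties go
    to the lowest cluster id.  Returns a frame with 0-based ``cluster`` and
    ``corr`` columns.
    """
    tz, _ = _zscore_rows(traces)
    mz, _ = _zscore_rows(cluster_means)
    corr = tz @ mz.T / tz.shape[1]
    best = corr.argmax(axis=1)          # argmax takes the first maximum
    best_corr = corr[np.arange(len(best)), best]
    cluster = np.where(best_corr >= threshold, best, -1)
    return pd.DataFrame({"cluster": cluster, "corr": best_corr})


def build_motion_regressor(response_flags: Sequence[bool] | np.ndarray,
                           protocol: DarkFlashProtocol,
                           kernel: np.ndarray, rate: float,
                           event_times: np.ndarray | None = None,
                           latency: float = 0.3) -> np.ndarray:
    """Convolve inferred movement events with the indicator kernel.

    Either explicit ``event_times`` (s) or per-flash response flags (events
    placed ``latency`` s after each responded flash).
    """
    n = int(round(protocol.duration * rate))
    x = np.zeros(n)
    if event_times is None:
        onsets = protocol.flash_onsets[:protocol.flashes_per_block]
        event_times = onsets[np.asarray(response_flags, dtype=bool)] + latency
    for t in np.asarray(event_times, dtype=float):
        idx = int(round(t * rate))
        if 0 <= idx < n:
            x[idx] += 1.0
    return np.convolve(x, kernel)[:n]


def motor_correlation_by_cluster(assignments: pd.DataFrame,
                                 traces: np.ndarray,
                                 motion_regressor: np.ndarray,
                                 ci_level: float = 99.99999,
                                 n_boot: int = 100_000,
                                 seed: int = 0) -> pd.DataFrame:
    """Per-cluster motor-correlation distributions with a bootstrap CI of
    the median.

    Returns one row per cluster: n, median, ci_lo, ci_hi (NaN CI and a
    ``reliable=False`` flag for clusters with fewer than two ROIs).
    """
    corr = correlate_rois(traces, np.asarray(motion_regressor)[None, :],
                          ["motor"])["motor"].to_numpy()
    rng = np.random.default_rng(seed)
    alpha = (100.0 - ci_level) / 2.0
    rows = []
    for k in sorted(set(assignments["cluster"]) - {-1}):
        vals = corr[assignments["cluster"].to_numpy() == k]
        if len(vals) < 2:
            rows.append({"cluster": k, "n": len(vals),
                         "median": float(np.median(vals)) if len(vals)
                         else np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan,
                         "reliable": False})
            continue
        boot = np.median(
            vals[rng.integers(0, len(vals), (n_boot, len(vals)))], axis=1)
        lo, hi = np.percentile(boot, [alpha, 100.0 - alpha])
        rows.append({"cluster": k, "n": len(vals),
                     "median": float(np.median(vals)),
                     "ci_lo": float(lo), "ci_hi": float(hi),
                     "reliable": True})
    return pd.DataFrame(rows).set_index("cluster")


def cluster_proportions_by_treatment(assignments: pd.DataFrame,
                                     treatments: Sequence,
                                     n_boot: int = 5000,
                                     seed: int = 0) -> Dict[str, Dict]:
    """Fraction of assigned ROIs per cluster per treatment group, with
    bootstrap-over-ROIs distributions (5000 replicates by default)."""
    treatments = np.asarray(treatments)
    groups = np.unique(treatments)
    if len(groups) < 2:
        raise ValueError("need at least two treatment groups")
    clusters = np.array(sorted(set(assignments["cluster"]) - {-1}))
    labels = assignments["cluster"].to_numpy()
    rng = np.random.default_rng(seed)
    out: Dict[str, Dict] = {}
    for g in groups:
        lab = labels[(treatments == g) & (labels >= 0)]
        n = len(lab)
        idx = np.searchsorted(clusters, lab)
        props = np.bincount(idx, minlength=len(clusters)) / n if n else \
            np.full(len(clusters), np.nan)
        boot = np.empty((n_boot, len(clusters)))
        for b in range(n_boot):
            if n:
                res = idx[rng.integers(0, n, n)]
                boot[b] = np.bincount(res, minlength=len(clusters)) / n
            else:
                boot[b] = np.nan
        out[str(g)] = {"clusters": clusters.tolist(),
                       "proportion": props.tolist(),
                       "bootstrap": boot, "n": int(n)}
    return out
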