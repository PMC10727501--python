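"""GABAergic classification from two-channel ratios and cluster enrichment.

ROIs imaged in double-transgenic fish carrying a red GABAergic reporter
(gad1b promoter) alongside the green calcium indicator are classified as
gad1b-positive when their red/green intensity ratio is strictly above 0.25.
Per functional cluster, enrichment (or depletion) of positives against the
overall positive fraction is tested with a 2x2 chi-square (cluster vs rest,
positive vs negative), Bonferroni-corrected over clusters, with bootstrap
distributions of the per-cluster proportion for display.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["classify_positive", "enrichment_test"]


def classify_positive(red: np.ndarray, green: np.ndarray,
                      threshold: float = 0.25,
                      green_floor: float | None = None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Flag ROIs with red/green strictly above ``threshold``.

    ROIs whose green intensity is at or below ``green_floor`` (default: the
    5th percentile of green) have undefined ratios and are excluded.
    Returns (positive flags, excluded flags).
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if np.any(red < 0) or np.any(green < 0):
        raise ValueError("intensities must be non-negative")
    if green_floor is None:
        green_floor = float(np.percentile(green, 5))
    excluded = green <= green_floor
    ratio = np.divide(red, green, out=np.zeros_like(red), where=~excluded)
    positive = (~excluded) & (ratio > threshold)
    return positive, excluded


def enrichment_test(cluster_assignments: Sequence, positive: np.ndarray,
                    n_boot: int = 5000, alpha: float = 0.05,
                    seed: int = 0) -> Tuple[pd.DataFrame, np.ndarray]:
    """Per-cluster positive-fraction enrichment against the pooled rate.

    For each cluster a 2x2 contingency table (in cluster vs rest x positive
    vs negative) is tested by chi-square without continuity correction;
    p-values are Bonferroni-corrected by the number of clusters tested.
    Clusters where any expected cell count falls below 1 are flagged
    unreliable.  Also returns the (n_boot x K) bootstrap matrix of
    per-cluster positive proportions (resampling ROIs within cluster).
    """
    labels = np.asarray(cluster_assignments)
    pos = np.asarray(positive, dtype=bool)
    keep = labels != -1
    labels, pos = labels[keep], pos[keep]
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters with assigned ROIs")
    expected = pos.mean()
    rng = np.random.default_rng(seed)
    rows = []
    boot = np.empty((n_boot, len(clusters)))
    for j, k in enumerate(clusters):
        in_k = labels == k
        n_k = int(in_k.sum())
        tbl = np.array([[pos[in_k].sum(), (~pos[in_k]).sum()],
                        [pos[~in_k].sum(), (~pos[~in_k]).sum()]],
                       dtype=float)
        if tbl[0].sum() == 0 or min(tbl.sum(0)) == 0:
            p = 1.0
            exp_min = 0.0
        else:
            stat, p, _, exp = chi2_contingency(tbl, correction=False)
            exp_min = exp.min()
        p_bonf = min(p * len(clusters), 1.0)
        obs = pos[in_k].mean() if n_k else np.nan
        rows.append({"cluster": k, "n": n_k, "observed": obs,
                     "expected": expected, "p": p, "p_bonferroni": p_bonf,
                     "significant": p_bonf < alpha,
                     "enriched": obs > expected,
                     "reliable": exp_min >= 1.0})
        kpos = pos[in_k]
        draws = kpos[rng.integers(0, n_k, (n_boot, n_k))] if n_k else \
            np.full((n_boot, 1), np.nan)
        boot[:, j] = draws.mean(axis=1)
    return pd.DataFrame(rows).set_index("cluster"), boot
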