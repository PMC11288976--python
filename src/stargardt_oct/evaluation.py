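"""Scoring and cohort summaries for atrophy predictions.

Predictions (ensemble probability maps, binarized masks, and per-component
sigmoid activation maps) are graded against ground truth with the Dice
coefficient

    D = 2*sum(p*g) / (sum(g^2) + sum(p^2))

and pixel accuracy.  Cohorts are summarized by medians per region and
configuration, and paired configurations are compared with the two-sided
Wilcoxon signed-rank test (zero differences dropped, average ranks on ties,
exact tail probabilities up to n = 25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_model import PredictionResult

__all__ = ["EyeScore", "dice", "pixel_accuracy", "grade_components",
           "summarize", "summary_table", "wilcoxon_paired"]


@dataclass
class EyeScore:
    """Dice and pixel accuracy for one eye under one configuration."""

    eye_id: str
    region: str
    configuration: str     # "ensemble", "component:<feature>", model label, ...
    dice: float
    pixel_accuracy: float
    horizon: str = "6mo"

    def __post_init__(self):
        for v in (self.dice, self.pixel_accuracy):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"metrics must lie in [0, 1], got {v}")


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap of a (possibly soft) prediction against a binary mask.

    Both-empty inputs score 1.0 (agreement on absence); exactly one empty
    scores 0.0.
    """
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not np.isin(np.unique(g), (0, 1)).all():
        raise ValueError("ground truth must be binary (0/1)")
    den = (g ** 2).sum() + (p ** 2).sum()
    if den == 0.0:
        return 1.0
    return float(2.0 * (p * g).sum() / den)


def pixel_accuracy(pred: np.ndarray, gt: np.ndarray) -> float:
    """Fraction of pixels whose predicted binary label matches ground truth."""
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    for m in (p, g):
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValueError("pixel accuracy requires binary (0/1) masks")
    return float((p == g).mean())


def grade_components(result: PredictionResult, gt: np.ndarray, eye_id: str = "",
                     region: str = "", horizon: str = "6mo",
                     soft_ensemble: bool = False) -> List[EyeScore]:
    """Ensemble score plus one score per component feature.

    The ensemble row uses the binarized (argmax) map by default (soft
    probability map with ``soft_ensemble=True``); each component row grades
    the component's sigmoid activation map with the soft Dice and the pixel
    accuracy of its 0.5-threshold binarization.
    """
    gt = np.asarray(gt)
    ens_pred = result.probabilities[1] if soft_ensemble else result.mask
    scores = [EyeScore(eye_id, region, "ensemble",
                       dice(ens_pred, gt), pixel_accuracy(result.mask, gt), horizon)]
    for feat, sig in zip(result.features, result.component_sigmoids):
        hard = (sig > 0.5).astype(np.uint8)
        scores.append(EyeScore(eye_id, region, f"component:{feat}",
                               dice(sig, gt), pixel_accuracy(hard, gt), horizon))
    return scores


def summarize(scores: Sequence[EyeScore]) -> pd.DataFrame:
    """Median Dice / pixel accuracy per (region, configuration, horizon) cell."""
    if not scores:
        raise ValueError("no scores to summarize")
    df = pd.DataFrame([vars(s) for s in scores])
    out = (df.groupby(["region", "configuration", "horizon"], sort=False)
             .agg(median_dice=("dice", "median"),
                  median_pixel_accuracy=("pixel_accuracy", "median"),
                  n_eyes=("dice", "size"))
             .reset_index())
    return out


def summary_table(scores: Sequence[EyeScore], metric: str = "median_dice") -> pd.DataFrame:
    """Pivot a cohort summary: regions as columns, ensemble + features as rows."""
    summary = summarize(scores)
    table = summary.pivot_table(index="configuration", columns="region",
                                values=metric, aggfunc="first")
    order = ["ensemble"] + sorted(c for c in table.index if c != "ensemble")
    return table.reindex([c for c in order if c in table.index])


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments (average ranks allowed).

    Average ranks may be half-integers, so the DP runs over doubled ranks.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r]
    w2 = int(np.rint(2.0 * w_plus))
    denom = 2.0 ** len(ranks)
    cdf = counts[:w2 + 1].sum() / denom
    sf = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_paired(a: Sequence[float], b: Sequence[float],
                    exact_threshold: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired scores.

    Zero differences are dropped (Wilcoxon's rule), tied absolute differences
    receive average ranks; the exact null distribution is enumerated for
    n <= ``exact_threshold``, the tie-corrected normal approximation is used
    above.  Degenerate input (all differences zero) returns p = 1.0 with a
    warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D paired score vectors")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; returning p = 1.0")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        return _exact_signed_rank_p(ranks, w_plus)
    # tie-corrected normal approximation
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
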