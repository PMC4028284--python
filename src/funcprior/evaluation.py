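"""Predictive-accuracy diagnostics: ROC/AUC, PPV, class histograms, and
score-stratified QQ statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PPV_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_MIN_POSITIVES = 11


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC.

    AUC is the probability that a random hit outscores a random non-hit,
    with ties credited 1/2 (the Mann–Whitney form).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_y = y[order]
    # one curve point per distinct threshold
    distinct = np.r_[np.where(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    tp = np.cumsum(sorted_y)[distinct]
    fp = np.cumsum(1 - sorted_y)[distinct]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    sens = np.r_[0.0, tp / n1]
    spec = np.r_[1.0, 1.0 - fp / n0]
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def ppv_at_thresholds(
    scores,
    labels,
    thresholds=DEFAULT_PPV_THRESHOLDS,
    min_positives: int = DEFAULT_MIN_POSITIVES,
) -> pd.DataFrame:
    """Positive predictive value at each score threshold.

    A threshold's PPV is reported only when at least ``min_positives``
    hits score above it; otherwise the row is marked insufficient and the
    PPV is NaN.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    rows = []
    for t in thresholds:
        if not 0.0 < t < 1.0:
            raise ValueError("thresholds must be in (0, 1)")
        above = scores > t
        n_above = int(above.sum())
        n_hits_above = int(y[above].sum())
        sufficient = n_hits_above >= min_positives
        rows.append(
            {
                "threshold": t,
                "n_above": n_above,
                "n_hits_above": n_hits_above,
                "ppv": n_hits_above / n_above if (sufficient and n_above) else np.nan,
                "sufficient": sufficient,
            }
        )
    return pd.DataFrame(rows)


def score_histograms(scores, labels, n_bins: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class counts over equal-width bins on [0, 1] plus class
    summaries (mean, sd, median)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = {}
    summaries = []
    for cls, name in ((1.0, "hits"), (0.0, "nonhits")):
        s = scores[y == cls]
        counts[name], _ = np.histogram(s, bins=edges)
        summaries.append(
            {
                "class": name,
                "n": len(s),
                "mean": float(s.mean()) if len(s) else np.nan,
                "sd": float(s.std(ddof=1)) if len(s) > 1 else np.nan,
                "median": float(np.median(s)) if len(s) else np.nan,
            }
        )
    hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], **counts})
    return hist, pd.DataFrame(summaries)


@dataclass
class QQStratum:
    label: str
    expected: np.ndarray  # -log10 of uniform order-statistic quantiles, ascending
    observed: np.ndarray  # sorted observed -log10 p, ascending (aligned to expected)
    n: int
    lambda_gc: float


def _lambda_gc(p: np.ndarray) -> float:
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def stratified_qq(p_values, scores, bin_edges=None, n_bins: int = 5) -> list[QQStratum]:
    """QQ statistics of -log10 p within predicted-score bins.

    Default bins are score quantile (equal-frequency) bins.  Expected
    quantiles use the (i - 0.5)/n plotting position.  Empty bins are
    omitted with a warning.  Each stratum also carries a genomic-
    inflation-style summary (median observed chi-square over median
    expected).
    """
    p = np.asarray(p_values, dtype=float)
    s = np.asarray(scores, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    if len(p) != len(s):
        raise ValueError("p-values and scores must align")
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(s, qs))
        bin_edges[0], bin_edges[-1] = -np.inf, np.inf
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
    strata = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (s >= lo) & (s < hi) if hi != bin_edges[-1] else (s >= lo)
        n = int(mask.sum())
        if n == 0:
            logger.warning("stratified_qq: empty score bin [%g, %g) omitted", lo, hi)
            continue
        obs = np.sort(-np.log10(p[mask]))
        i = np.arange(1, n + 1)
        expected = np.sort(-np.log10((i - 0.5) / n))
        strata.append(
            QQStratum(
                label=f"[{lo:g}, {hi:g})",
                expected=expected,
                observed=obs,
                n=n,
                lambda_gc=_lambda_gc(p[mask]),
            )
        )
    return strata


def qq_table(strata: list[QQStratum]) -> pd.DataFrame:
    """Flatten QQ strata into a long table (one row per order statistic)."""
    frames = []
    for st in strata:
        frames.append(
            pd.DataFrame(
                {
                    "bin": st.label,
                    "expected": st.expected,
                    "observed": st.observed,
                    "n": st.n,
                    "lambda_gc": st.lambda_gc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["bin", "expected", "observed", "n", "lambda_gc"]
    )
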