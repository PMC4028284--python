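"""Per-feature enrichment of annotations in hits versus non-hits."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from funcprior.annotation import AnnotationMatrix, HitLabeling, ProxyMap, Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = hits with feature, b = hits without,
    c = non-hits with feature, d = non-hits without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n_hits(self) -> int:
        return self.a + self.b

    @property
    def n_nonhits(self) -> int:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def dichotomize_quantitative(values) -> np.ndarray:
    """Map a non-negative score vector to presence indicators (score > 0)."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("quantitative scores must be non-negative")
    return (values > 0).astype(float)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (probability-mass rule: sum of
    hypergeometric probabilities of tables with fixed margins whose
    probability does not exceed the observed table's).

    A zero margin makes the table degenerate; p = 1 with a warning.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("fisher_exact: zero margin, p-value set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def odds_ratio_ci(table: ContingencyTable, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio ad/bc with a Woolf log-OR normal confidence interval.

    If any cell is zero the Haldane–Anscombe +0.5 correction is applied to
    all four cells before both the OR and the interval are computed.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return or_, float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se))


def contingency_from_feature(values_hits, values_nonhits) -> ContingencyTable:
    """Build the 2x2 table from binary feature vectors of each class."""
    vh = np.asarray(values_hits, dtype=float)
    vn = np.asarray(values_nonhits, dtype=float)
    return ContingencyTable(
        a=int((vh > 0).sum()),
        b=int((vh <= 0).sum()),
        c=int((vn > 0).sum()),
        d=int((vn <= 0).sum()),
    )


def enrichment_table(matrix: AnnotationMatrix, labels: HitLabeling, level: float = 0.95) -> pd.DataFrame:
    """One enrichment row per feature, in input feature order.

    Quantitative features are dichotomized (score > 0) first.  Columns:
    feature, freq_hits, freq_nonhits, p_value, odds_ratio, ci_low,
    ci_high, corrected (True when the Haldane correction was applied).
    """
    hit_ids = sorted(labels.hit_ids)
    nonhit_ids = sorted(labels.nonhit_ids)
    missing = (set(hit_ids) | set(nonhit_ids)) - set(matrix.data.index)
    if missing:
        raise KeyError(f"labelled ids not in matrix: {sorted(missing)[:5]}")
    rows = []
    for f in matrix.features:
        vh = matrix.data.loc[hit_ids, f.name].to_numpy()
        vn = matrix.data.loc[nonhit_ids, f.name].to_numpy()
        if f.mode == "quantitative":
            vh = dichotomize_quantitative(vh)
            vn = dichotomize_quantitative(vn)
        t = contingency_from_feature(vh, vn)
        if t.a + t.c == 0:
            logger.warning("enrichment_table: feature %s absent in all variants", f.name)
        or_, lo, hi = odds_ratio_ci(t, level=level)
        rows.append(
            {
                "feature": f.name,
                "freq_hits": t.a / t.n_hits if t.n_hits else np.nan,
                "freq_nonhits": t.c / t.n_nonhits if t.n_nonhits else np.nan,
                "p_value": fisher_exact(t),
                "odds_ratio": or_,
                "ci_low": lo,
                "ci_high": hi,
                "corrected": min(t.a, t.b, t.c, t.d) == 0,
            }
        )
    return pd.DataFrame(rows)


def feature_correlation(matrix: AnnotationMatrix) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the feature columns.

    Constant columns have undefined correlation; their off-diagonal
    entries are reported as 0 (logged), the diagonal stays 1.
    """
    data = matrix.data
    if len(data) < 2:
        raise ValueError("need at least 2 variants for correlations")
    arr = data.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "feature_correlation: constant columns reported as 0 correlation: %s",
            [n for n, c in zip(matrix.feature_names, constant) if c],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.feature_names, columns=matrix.feature_names)


def mean_annotation_score(matrix: AnnotationMatrix, ids) -> float:
    """Mean over ``ids`` of the per-variant count of present features
    (quantitative features count as present when score > 0)."""
    ids = list(ids)
    if not ids:
        raise ValueError("empty id set")
    missing = set(ids) - set(matrix.data.index)
    if missing:
        raise KeyError(f"ids not in matrix: {sorted(missing)[:5]}")
    sub = matrix.data.loc[ids]
    total = np.zeros(len(ids))
    for f in matrix.features:
        col = sub[f.name].to_numpy()
        total += dichotomize_quantitative(col) if f.mode == "quantitative" else col
    return float(total.mean())


def ld_prune(variants: list[Variant], proxies: ProxyMap, r2_threshold: float = 0.8) -> list[Variant]:
    """Greedy LD pruning: scan variants in (chrom, pos) order, keep a
    variant unless it is in LD (r² >= threshold) with one already kept."""
    order = sorted(variants, key=lambda v: (v.chrom, v.pos, v.id))
    kept: list[Variant] = []
    kept_ids: set[str] = set()
    for v in order:
        partners = proxies.proxies_of(v.id, r2_threshold)
        if kept_ids.isdisjoint(partners):
            kept.append(v)
            kept_ids.add(v.id)
    return kept
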