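"""Synthetic universes with known ground truth.

Correlated binary annotations come from thresholding a block-correlated
latent Gaussian; hit labels are drawn from a logistic model on the
features; summary statistics carry real effects at hits; LD proxies form
a symmetric map with r-squared in a configured high-LD range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from funcprior.annotation import AnnotationMatrix, FeatureDef, ProxyMap, Variant


@dataclass
class SimConfig:
    n_variants: int = 10_000
    n_features: int = 14
    feature_freqs: tuple[float, ...] | float = 0.2
    correlation_blocks: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    quantitative: tuple[int, ...] = ()
    true_intercept: float | None = -3.0
    true_coefficients: tuple[float, ...] | None = None
    hit_fraction_target: float | None = None
    effect_sd_hits: float = 0.5
    n_eff: int = 10_000
    proxy_mean: float = 0.0
    proxy_r2_range: tuple[float, float] = (0.8, 1.0)
    seed: int = 0

    def freqs(self) -> np.ndarray:
        f = np.asarray(
            self.feature_freqs if not np.isscalar(self.feature_freqs) else [self.feature_freqs] * self.n_features,
            dtype=float,
        )
        if len(f) != self.n_features:
            raise ValueError("feature_freqs length must equal n_features")
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("feature frequencies must be in (0, 1)")
        return f

    def coefficients(self) -> np.ndarray:
        if self.true_coefficients is None:
            return np.zeros(self.n_features)
        b = np.asarray(self.true_coefficients, dtype=float)
        if len(b) != self.n_features:
            raise ValueError("true_coefficients length must equal n_features")
        return b

    def validate(self) -> None:
        if self.n_variants < 1 or self.n_features < 1:
            raise ValueError("n_variants and n_features must be positive")
        self.freqs()
        self.coefficients()
        seen: set[int] = set()
        for idx, rho in self.correlation_blocks:
            if not 0.0 <= rho < 1.0:
                raise ValueError("block correlation must be in [0, 1)")
            for j in idx:
                if not 0 <= j < self.n_features:
                    raise ValueError(f"block feature index {j} out of range")
                if j in seen:
                    raise ValueError(f"feature {j} appears in more than one block")
                seen.add(j)
        if self.hit_fraction_target is not None and not 0.0 < self.hit_fraction_target < 0.5:
            raise ValueError("hit_fraction_target must be in (0, 0.5)")
        if self.hit_fraction_target is None and self.true_intercept is None:
            raise ValueError("need true_intercept or hit_fraction_target")
        lo, hi = self.proxy_r2_range
        if not (0.8 <= lo <= hi <= 1.0):
            raise ValueError("proxy_r2_range must lie within [0.8, 1.0]")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_variants(n: int, prefix: str = "v") -> list[Variant]:
    """Placeholder variants with synthetic coordinates on the autosomes."""
    width = len(str(n))
    out = []
    for i in range(n):
        chrom = str(i % 22 + 1)
        out.append(Variant(id=f"{prefix}{i:0{width}d}", chrom=chrom, pos=1000 + (i // 22 + 1) * 100))
    return out


def _latent_gaussian(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((cfg.n_variants, cfg.n_features))
    for idx, rho in cfg.correlation_blocks:
        if rho == 0.0 or len(idx) < 2:
            continue
        common = rng.standard_normal(cfg.n_variants)
        for j in idx:
            z[:, j] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * z[:, j]
    return z


def _solve_intercept(X: np.ndarray, beta: np.ndarray, target: float) -> float:
    eta = X @ beta

    def gap(c: float) -> float:
        return float(_sigmoid(c + eta).mean() - target)

    return brentq(gap, -40.0, 40.0, xtol=1e-10)


def simulate_annotations(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotationMatrix, pd.DataFrame]:
    """Annotation matrix plus a truth table (id, prob, label, intercept).

    Binary features threshold the latent Gaussian at the quantile giving
    the requested marginal frequency; quantitative features are the
    latent excess over that threshold truncated at zero (positive with the
    same frequency).  Labels are Bernoulli draws from
    logistic(intercept + X @ beta).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    freqs = cfg.freqs()
    beta = cfg.coefficients()
    z = _latent_gaussian(cfg, rng)
    thresholds = stats.norm.isf(freqs)
    X = np.empty_like(z)
    defs = []
    width = len(str(cfg.n_features))
    for j in range(cfg.n_features):
        name = f"f{j:0{width}d}"
        if j in cfg.quantitative:
            X[:, j] = np.maximum(z[:, j] - thresholds[j], 0.0)
            defs.append(FeatureDef(name, "quantitative"))
        else:
            X[:, j] = (z[:, j] > thresholds[j]).astype(float)
            defs.append(FeatureDef(name, "binary"))

    if cfg.hit_fraction_target is not None:
        intercept = _solve_intercept(X, beta, cfg.hit_fraction_target)
    else:
        intercept = float(cfg.true_intercept)
    prob = _sigmoid(intercept + X @ beta)
    label = (rng.random(cfg.n_variants) < prob).astype(int)

    ids = [v.id for v in make_variants(cfg.n_variants)]
    frame = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=[d.name for d in defs])
    truth = pd.DataFrame({"id": ids, "prob": prob, "label": label})
    truth.attrs["intercept"] = intercept
    return AnnotationMatrix(frame, defs), truth


def simulate_gwas_summary(truth: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Summary statistics (id, beta, se, z, p).

    Non-hits: z ~ N(0,1) null draws, beta = z * se.  Hits: a true effect
    ~ N(0, effect_sd_hits^2), observed beta ~ N(effect, se^2).  The
    standard error is 1/sqrt(n_eff) throughout.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = len(truth)
    se = 1.0 / np.sqrt(cfg.n_eff)
    is_hit = truth["label"].to_numpy() == 1
    beta = np.empty(n)
    beta[~is_hit] = rng.standard_normal((~is_hit).sum()) * se
    effects = rng.normal(0.0, cfg.effect_sd_hits, is_hit.sum())
    beta[is_hit] = effects + rng.standard_normal(is_hit.sum()) * se
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"id": truth["id"], "beta": beta, "se": se, "z": z, "p": p})


def simulate_ld_proxies(
    cfg: SimConfig, variants: list[Variant] | list[str], rng: np.random.Generator | None = None
) -> ProxyMap:
    """Poisson-many synthetic proxies per variant with r-squared uniform in
    the configured high-LD range; the map is symmetric."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    lo, hi = cfg.proxy_r2_range
    pm = ProxyMap(r2_threshold=0.8)
    for v in variants:
        vid = v.id if isinstance(v, Variant) else str(v)
        k = rng.poisson(cfg.proxy_mean)
        for i in range(k):
            r2 = float(rng.uniform(lo, hi))
            pm.add(vid, f"{vid}_px{i}", r2)
    return pm


def simulate_dataset(cfg: SimConfig) -> dict[str, object]:
    """One coherent synthetic universe: matrix, truth, summary stats,
    proxies, and the variant list, all from a single seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    matrix, truth = simulate_annotations(cfg, rng)
    sumstats = simulate_gwas_summary(truth, cfg, rng)
    variants = make_variants(cfg.n_variants)
    proxies = simulate_ld_proxies(cfg, variants, rng)
    return {
        "matrix": matrix,
        "truth": truth,
        "sumstats": sumstats,
        "variants": variants,
        "proxies": proxies,
    }
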