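"""Class-weighted elastic-net logistic regression.

The fitted objective is

    sum_i w_i * nll_i(b0, b)  +  lambda * [ alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2 ]

with the intercept unpenalized and w_i the class weight of observation i.
Hits and non-hits are weighted to equal total mass, so the fitted odds of
a variant double as its annotation Bayes factor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from funcprior.annotation import AnnotationMatrix, HitLabeling

logger = logging.getLogger(__name__)

#: coordinate-descent convergence: stop when max coefficient change < this
CD_TOL = 1e-7
_MAX_OUTER = 200
_MAX_INNER = 500


@dataclass(frozen=True)
class ClassWeights:
    """Per-observation weights equalizing total hit and non-hit mass."""

    w_hit: float
    w_nonhit: float

    def sample_weights(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.where(y == 1, self.w_hit, self.w_nonhit)


def compute_class_weights(n_hits: int, n_nonhits: int) -> ClassWeights:
    """w_hit = (N_h + N_n) / (2 N_h), w_nonhit = (N_h + N_n) / (2 N_n)."""
    if n_hits < 1 or n_nonhits < 1:
        raise ValueError("both classes must be non-empty")
    total = n_hits + n_nonhits
    return ClassWeights(w_hit=total / (2 * n_hits), w_nonhit=total / (2 * n_nonhits))


@dataclass(frozen=True)
class ElasticNetConfig:
    alpha: float = 0.5
    lambda_: float = 1.0
    n_folds: int = 10
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FitResult:
    intercept: float
    coefficients: dict[str, float]
    config: ElasticNetConfig
    weights: ClassWeights
    cv_deviance_path: pd.DataFrame | None = None
    constant_features: list[str] = field(default_factory=list)

    def coef_vector(self, feature_names=None) -> np.ndarray:
        names = list(self.coefficients if feature_names is None else feature_names)
        return np.array([self.coefficients[n] for n in names])


@dataclass(frozen=True)
class Split:
    train_ids: frozenset[str]
    test_ids: frozenset[str]
    tune_ids: frozenset[str] | None
    scheme: str
    seed: int


def _stratified_cut(ids: list[str], fractions: list[float], rng: np.random.Generator) -> list[list[str]]:
    ids = sorted(ids)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    cuts = np.cumsum([int(round(f * len(ids))) for f in fractions[:-1]])
    parts, prev = [], 0
    for c in list(cuts) + [len(ids)]:
        parts.append(shuffled[prev:c])
        prev = c
    return parts


def split_data(labels: HitLabeling, scheme: str, seed: int, n_folds: int = 10) -> Split:
    """Stratified random split of the labelled universe.

    ``simple_60_40``: 60% train / 40% test.
    ``nested_70_30``: 30% held-out test; the remaining 70% is split
    60/40 into coefficient-training and tuning sets (42/28/30 overall).
    """
    if scheme not in ("simple_60_40", "nested_70_30"):
        raise ValueError(f"unknown scheme {scheme!r}")
    for name, ids in (("hits", labels.hit_ids), ("non-hits", labels.nonhit_ids)):
        if len(ids) < n_folds:
            raise ValueError(f"class {name} has {len(ids)} members, fewer than n_folds={n_folds}")
    rng = np.random.default_rng(seed)
    train, test, tune = [], [], []
    for ids in (labels.hit_ids, labels.nonhit_ids):
        if scheme == "simple_60_40":
            tr, te = _stratified_cut(list(ids), [0.6, 0.4], rng)
            train += tr
            test += te
        else:
            dev, te = _stratified_cut(list(ids), [0.7, 0.3], rng)
            tr, tu = _stratified_cut(dev, [0.6, 0.4], rng)
            train += tr
            tune += tu
            test += te
    return Split(
        train_ids=frozenset(train),
        test_ids=frozenset(test),
        tune_ids=frozenset(tune) if scheme == "nested_70_30" else None,
        scheme=scheme,
        seed=seed,
    )


def design_from_labels(matrix: AnnotationMatrix, labels: HitLabeling, ids=None) -> tuple[pd.DataFrame, pd.Series]:
    """Feature frame and 0/1 response for the labelled variants.

    ``ids`` restricts rows (e.g. to a split's training ids); ordering is
    deterministic (sorted hits first, then sorted non-hits).
    """
    hit_ids = sorted(labels.hit_ids if ids is None else labels.hit_ids & set(ids))
    nonhit_ids = sorted(labels.nonhit_ids if ids is None else labels.nonhit_ids & set(ids))
    ordered = hit_ids + nonhit_ids
    X = matrix.data.loc[ordered]
    y = pd.Series(np.r_[np.ones(len(hit_ids)), np.zeros(len(nonhit_ids))], index=ordered, name="label")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, mean, sd, keep


def _coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = CD_TOL,
) -> tuple[float, np.ndarray]:
    """Penalized weighted logistic fit by IRLS with inner coordinate descent
    (soft-thresholding for the L1 part); the intercept is unpenalized."""
    n, p = X.shape
    b0 = 0.0
    beta = np.zeros(p)
    xsq = X**2
    for _ in range(_MAX_OUTER):
        eta = b0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        prob = np.clip(prob, 1e-9, 1.0 - 1e-9)
        v = w * prob * (1.0 - prob)
        r = (y - prob) / (prob * (1.0 - prob))  # working residual z - eta
        b0_prev, beta_prev = b0, beta.copy()
        vsum = v.sum()
        vx2 = v @ xsq
        for _ in range(_MAX_INNER):
            delta = 0.0
            d0 = (v @ r) / vsum
            b0 += d0
            r -= d0
            delta = abs(d0)
            for j in range(p):
                xj = X[:, j]
                old = beta[j]
                grad = v @ (xj * r) + old * vx2[j]
                new = np.sign(grad) * max(abs(grad) - lam * alpha, 0.0) / (vx2[j] + lam * (1.0 - alpha))
                if new != old:
                    r += xj * (old - new)
                    beta[j] = new
                    delta = max(delta, abs(new - old))
            if delta < tol:
                break
        if max(abs(b0 - b0_prev), float(np.abs(beta - beta_prev).max(initial=0.0))) < tol:
            break
    return b0, beta


def fit_elastic_net(
    X: pd.DataFrame,
    y,
    config: ElasticNetConfig,
    weights: ClassWeights | None = None,
) -> FitResult:
    """Fit the penalized weighted logistic model.

    With ``config.standardize`` the penalty acts on standardized predictors
    and coefficients are reported back on the original feature scale.
    Constant columns are excluded from the fit (coefficient 0, flagged).
    """
    feature_names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    if not np.isfinite(Xa).all():
        raise ValueError("design matrix contains non-finite values")
    if not np.isin(ya, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if weights is None:
        weights = compute_class_weights(int(ya.sum()), int((1 - ya).sum()))
    sw = weights.sample_weights(ya)

    if config.standardize:
        Xs, mean, sd, keep = _standardize(Xa)
    else:
        Xs, mean, sd = Xa.copy(), np.zeros(Xa.shape[1]), np.ones(Xa.shape[1])
        keep = Xa.std(axis=0) > 0
        Xs[:, ~keep] = 0.0
    constant = [n for n, k in zip(feature_names, keep) if not k]
    if constant:
        logger.warning("fit_elastic_net: constant features forced to 0: %s", constant)

    intercept_std, beta_keep = _coordinate_descent(Xs[:, keep], ya, sw, config.lambda_, config.alpha)
    beta_std = np.zeros(Xa.shape[1])
    beta_std[keep] = beta_keep

    # back-transform to the original feature scale
    beta = np.zeros_like(beta_std)
    beta[keep] = beta_std[keep] / sd[keep] if config.standardize else beta_std[keep]
    intercept = intercept_std - float(beta[keep] @ mean[keep]) if config.standardize else intercept_std

    return FitResult(
        intercept=intercept,
        coefficients=dict(zip(feature_names, beta)),
        config=config,
        weights=weights,
        constant_features=constant,
    )


def predict_probability(fit: FitResult, X: pd.DataFrame | AnnotationMatrix) -> pd.Series:
    """logistic(intercept + X @ beta) per variant."""
    frame = X.data if isinstance(X, AnnotationMatrix) else X
    missing = set(fit.coefficients) - set(frame.columns)
    if missing:
        raise KeyError(f"matrix missing model features: {sorted(missing)}")
    names = list(fit.coefficients)
    eta = fit.intercept + frame[names].to_numpy(dtype=float) @ fit.coef_vector(names)
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(p, index=frame.index, name="score")


def weighted_deviance(y, p, sample_weights) -> float:
    """Mean weighted binomial deviance, -2 * sum(w * loglik) / sum(w)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-15, 1 - 1e-15)
    w = np.asarray(sample_weights, dtype=float)
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


def make_lambda_grid(
    X: pd.DataFrame,
    y,
    weights: ClassWeights | None = None,
    alpha: float = 0.5,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced lambda grid from lambda_max (the smallest penalty that
    zeroes every coefficient of the standardized problem) downward."""
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    if weights is None:
        weights = compute_class_weights(int(ya.sum()), int((1 - ya).sum()))
    sw = weights.sample_weights(ya)
    Xs, _, _, keep = _standardize(Xa)
    p0 = np.sum(sw * ya) / np.sum(sw)
    grad = Xs[:, keep].T @ (sw * (ya - p0))
    lam_max = np.abs(grad).max() / max(alpha, 1e-3)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def tune_hyperparameters(
    X: pd.DataFrame,
    y,
    weights: ClassWeights,
    alpha_grid,
    lambda_grid,
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """Pick (alpha, lambda) minimizing mean weighted binomial deviance
    over stratified cross-validation folds.

    Ties favour the largest lambda (sparser model).  Grid points with a
    non-finite fold deviance are disqualified and logged.  Returns the
    winning pair and the full CV path.
    """
    alpha_grid = sorted(set(float(a) for a in alpha_grid))
    lambda_grid = sorted(set(float(l) for l in lambda_grid), reverse=True)
    if not alpha_grid or not lambda_grid:
        raise ValueError("grids must be non-empty")
    ya = np.asarray(y, dtype=float)
    sw_all = weights.sample_weights(ya)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(ya)), ya))

    records = []
    best = None  # (deviance, alpha, lambda)
    for lam, alpha in itertools.product(lambda_grid, alpha_grid):
        devs = []
        for tr, va in folds:
            cfg = ElasticNetConfig(alpha=alpha, lambda_=lam, n_folds=n_folds, seed=seed, standardize=standardize)
            fit = fit_elastic_net(X.iloc[tr], ya[tr], cfg, weights)
            p = predict_probability(fit, X.iloc[va])
            devs.append(weighted_deviance(ya[va], p, sw_all[va]))
        mean_dev = float(np.mean(devs))
        records.append({"alpha": alpha, "lambda": lam, "cv_deviance": mean_dev})
        if not np.isfinite(mean_dev):
            logger.warning("tune_hyperparameters: non-finite deviance at alpha=%g lambda=%g", alpha, lam)
            continue
        if best is None or mean_dev < best[0]:
            best = (mean_dev, alpha, lam)
    if best is None:
        raise RuntimeError("all grid points produced non-finite deviance")
    path = pd.DataFrame(records)
    return best[1], best[2], path


def fit_with_tuning(
    matrix: AnnotationMatrix,
    labels: HitLabeling,
    scheme: str = "simple_60_40",
    alpha_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_lambda: int = 20,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[FitResult, Split]:
    """End-to-end training: split, tune on the appropriate subset, and fit
    on the training ids with weights recomputed on those ids."""
    split = split_data(labels, scheme, seed, n_folds=n_folds)
    tune_ids = split.tune_ids if split.tune_ids is not None else split.train_ids
    Xt, yt = design_from_labels(matrix, labels, tune_ids)
    w_t = compute_class_weights(int(yt.sum()), int((1 - yt).sum()))
    lam_grid = make_lambda_grid(Xt, yt, w_t, alpha=max(max(alpha_grid), 0.5), n_lambda=n_lambda)
    alpha, lam, path = tune_hyperparameters(Xt, yt, w_t, alpha_grid, lam_grid, n_folds=n_folds, seed=seed)

    Xf, yf = design_from_labels(matrix, labels, split.train_ids)
    w_f = compute_class_weights(int(yf.sum()), int((1 - yf).sum()))
    cfg = ElasticNetConfig(alpha=alpha, lambda_=lam, n_folds=n_folds, seed=seed)
    fit = fit_elastic_net(Xf, yf, cfg, w_f)
    fit.cv_deviance_path = path
    return fit, split
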