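"""Bayes factors for annotation and association, and rank evaluation.

Both factors point in the same direction — evidence FOR causality /
association — so the combined factor is a plain product and larger is
better.  (Wakefield's original approximate BF is null-over-alternative;
this module uses its reciprocal.)
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from funcprior.annotation import ProxyMap

logger = logging.getLogger(__name__)

DEFAULT_PRIOR_SD = 0.2


def bf_annot_from_score(score):
    """Annotation Bayes factor = fitted odds score / (1 - score)."""
    s = np.asarray(score, dtype=float)
    if ((s <= 0) | (s >= 1)).any():
        raise ValueError("scores must lie strictly inside (0, 1)")
    out = s / (1.0 - s)
    return float(out) if np.isscalar(score) or out.ndim == 0 else out


def wakefield_log_bf_assoc(beta_hat, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Natural log of the approximate association Bayes factor
    (alternative over null):

        log BF = 0.5 * log(V / (V + W)) + z^2 W / (2 (V + W))

    with V = se^2, W = prior_sd^2, z = beta_hat / se.  Working in log
    space keeps very large z finite.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    se_arr = np.asarray(se, dtype=float)
    if (se_arr <= 0).any():
        raise ValueError("standard errors must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    V = se_arr**2
    W = prior_sd**2
    z = beta_hat / se_arr
    out = 0.5 * np.log(V / (V + W)) + z**2 * W / (2.0 * (V + W))
    return float(out) if out.ndim == 0 else out


def wakefield_bf_assoc(beta_hat, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Approximate association Bayes factor (alternative over null):

        sqrt(V / (V + W)) * exp(z^2 W / (2 (V + W)))

    This equals the ratio of Normal(0, V+W) to Normal(0, V) densities at
    beta_hat.  Overflows to inf for extreme z; use
    :func:`wakefield_log_bf_assoc` when ranking.
    """
    with np.errstate(over="ignore"):
        out = np.exp(wakefield_log_bf_assoc(beta_hat, se, prior_sd))
    return float(out) if np.ndim(out) == 0 else out


def combine_evidence(bf_assoc, bf_annot, o_prior: float | None = None):
    """bf_combined = bf_assoc * bf_annot; posterior odds if a prior odds
    is supplied."""
    a = np.asarray(bf_assoc, dtype=float)
    b = np.asarray(bf_annot, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("Bayes factors must be positive")
    combined = a * b
    if combined.ndim == 0:
        combined = float(combined)
    if o_prior is None:
        return combined, None
    if o_prior <= 0:
        raise ValueError("prior odds must be positive")
    return combined, o_prior * combined


def rank_variants(bfs) -> np.ndarray:
    """Descending ranks: the largest BF gets rank 1; ties share the
    average of their rank span."""
    bfs = np.asarray(bfs, dtype=float)
    if not np.isfinite(bfs).all():
        raise ValueError("Bayes factors must be finite")
    return stats.rankdata(-bfs, method="average")


def recover_z_and_se(beta_hat, se=None, p_value=None) -> tuple[np.ndarray, np.ndarray]:
    """Return (z, se); when se is missing, recover z from the two-sided
    p-value with the sign of beta_hat and back out se = beta_hat / z."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    if se is not None:
        se_arr = np.asarray(se, dtype=float)
        if (se_arr <= 0).any():
            raise ValueError("standard errors must be positive")
        return beta_hat / se_arr, se_arr
    if p_value is None:
        raise ValueError("need either se or p_value alongside beta_hat")
    p = np.asarray(p_value, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p-values must lie strictly inside (0, 1) to recover z")
    if (beta_hat == 0).any():
        raise ValueError("cannot recover se from p when beta_hat is 0")
    z = np.sign(beta_hat) * stats.norm.isf(p / 2.0)
    return z, np.abs(beta_hat / z)


def compute_bfsets(
    scores: pd.DataFrame,
    sumstats: pd.DataFrame,
    prior_sd: float = DEFAULT_PRIOR_SD,
    o_prior: float | None = None,
) -> pd.DataFrame:
    """Join prediction scores with summary statistics and produce per-variant
    BF_annot, BF_assoc, their product, and both rankings.

    ``scores``: columns id, score.  ``sumstats``: columns id, beta and
    se and/or p.  Only the intersection of ids is scored.
    """
    sc = scores[["id", "score"]]
    ss = sumstats.copy()
    merged = sc.merge(ss, on="id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping ids between scores and summary statistics")
    se = merged["se"].to_numpy() if "se" in merged.columns and merged["se"].notna().all() else None
    p = merged["p"].to_numpy() if "p" in merged.columns else None
    z, se_eff = recover_z_and_se(merged["beta"].to_numpy(), se, p)
    log_bf_assoc = wakefield_log_bf_assoc(merged["beta"].to_numpy(), se_eff, prior_sd)
    bf_annot = bf_annot_from_score(merged["score"].to_numpy())
    with np.errstate(over="ignore"):
        bf_assoc = np.exp(log_bf_assoc)
        bf_combined = bf_assoc * bf_annot
    # rank on logs so astronomically large factors stay ordered
    log_bf_combined = log_bf_assoc + np.log(bf_annot)
    out = pd.DataFrame(
        {
            "id": merged["id"],
            "score": merged["score"],
            "bf_annot": bf_annot,
            "bf_assoc": bf_assoc,
            "bf_combined": bf_combined,
            "log10_bf_assoc": log_bf_assoc / np.log(10.0),
            "log10_bf_combined": log_bf_combined / np.log(10.0),
            "rank_assoc": rank_variants(log_bf_assoc),
            "rank_combined": rank_variants(log_bf_combined),
        }
    )
    if o_prior is not None:
        if o_prior <= 0:
            raise ValueError("prior odds must be positive")
        out["o_post"] = o_prior * out["bf_combined"]
    return out


def rank_improvement(hit_ids, bfsets: pd.DataFrame) -> tuple[int, float]:
    """How the combined ranking treats the hits relative to the
    association-only ranking.

    Returns (number of hits whose rank improved, sum of assoc ranks minus
    sum of combined ranks over hits); positive delta means the combined
    ranking placed the hits better overall.
    """
    hit_ids = set(hit_ids)
    missing = hit_ids - set(bfsets["id"])
    if missing:
        raise KeyError(f"hit ids missing from BF table: {sorted(missing)[:5]}")
    sub = bfsets[bfsets["id"].isin(hit_ids)]
    n_improved = int((sub["rank_combined"] < sub["rank_assoc"]).sum())
    delta = float(sub["rank_assoc"].sum() - sub["rank_combined"].sum())
    return n_improved, delta


def _halfdecade_bin(p: np.ndarray) -> np.ndarray:
    # bin index of -log10 p in half-decade steps
    return np.floor(2.0 * -np.log10(p)).astype(int)


def sample_matched_controls(
    hit_ids,
    pool: pd.DataFrame,
    proxies: ProxyMap,
    n_sets: int,
    set_size: int | None = None,
    seed: int = 0,
    r2_threshold: float = 0.8,
    max_widen: int = 20,
) -> list[list[str]]:
    """Random control sets matched to the hits' p-values.

    ``pool``: columns id, p.  Each control (i) is not a hit, (ii) is not
    in LD (r² >= threshold) with any hit, (iii) has -log10 p in the same
    half-decade bin as its matched hit (the tolerance widens by
    half-decades, with a warning, if a bin runs dry), and (iv) appears at
    most once per set.  Deterministic for a fixed seed.
    """
    hit_ids = sorted(set(hit_ids))
    if not hit_ids:
        raise ValueError("empty hit set")
    if set_size is None:
        set_size = len(hit_ids)
    rng = np.random.default_rng(seed)

    ld_excluded: set[str] = set()
    for h in hit_ids:
        ld_excluded.update(proxies.proxies_of(h, r2_threshold))
    eligible = pool[~pool["id"].isin(set(hit_ids) | ld_excluded)].reset_index(drop=True)
    if eligible.empty:
        raise ValueError("no eligible control variants in pool")
    pool_ids = eligible["id"].to_numpy()
    pool_bins = _halfdecade_bin(eligible["p"].to_numpy(dtype=float))
    by_bin: dict[int, np.ndarray] = {
        int(b): np.flatnonzero(pool_bins == b) for b in np.unique(pool_bins)
    }

    hits_in_pool = pool[pool["id"].isin(hit_ids)].set_index("id")["p"]
    missing = set(hit_ids) - set(hits_in_pool.index)
    if missing:
        raise KeyError(f"hit ids missing from pool (need their p-values): {sorted(missing)[:5]}")
    hit_bins = {h: int(_halfdecade_bin(np.array([hits_in_pool[h]]))[0]) for h in hit_ids}

    # targets for one set: cycle through hits to reach set_size
    targets = [hit_ids[i % len(hit_ids)] for i in range(set_size)]

    sets: list[list[str]] = []
    for _ in range(n_sets):
        chosen_idx: set[int] = set()
        chosen: list[str] = []
        for target in targets:
            pick = None
            for tol in range(max_widen + 1):
                if tol > 0:
                    warnings.warn(
                        f"sample_matched_controls: widening p-value tolerance to ±{tol} half-decades for {target}",
                        stacklevel=2,
                    )
                bins = (
                    [hit_bins[target]]
                    if tol == 0
                    else [hit_bins[target] - tol, hit_bins[target] + tol]
                )
                candidates = [
                    i for b in bins for i in by_bin.get(b, ()) if i not in chosen_idx
                ]
                if candidates:
                    pick = candidates[rng.integers(len(candidates))]
                    break
            if pick is None:
                raise ValueError(
                    f"insufficient matched controls for hit {target} even after widening {max_widen} half-decades"
                )
            chosen_idx.add(pick)
            chosen.append(str(pool_ids[pick]))
        sets.append(chosen)
    return sets
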