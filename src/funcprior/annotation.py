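"""Variant universe construction, hit labelling, and the annotation matrix.

Coordinates are 1-based inclusive internally.  BED input (0-based,
half-open) is converted on read, so a BED interval ``[s, e)`` covers the
1-based positions ``s+1 .. e``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Significance thresholds defining the two hit tiers.
TIER_THRESHOLDS = {"weak": 1e-5, "strong": 5e-8}

#: Chromosome names accepted after normalisation.
AUTOSOMES = {str(i) for i in range(1, 23)}
SEX_CHROMS = {"X", "Y"}
VALID_CHROMS = AUTOSOMES | SEX_CHROMS | {"MT", "M"}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and upper-case sex chromosomes."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in {"x", "y", "mt", "m"}:
        c = c.upper()
    return c


@dataclass(frozen=True)
class Variant:
    """A point variant on a declared genome build (1-based position)."""

    id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.chrom}:{self.start}-{self.end}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and self.start <= pos <= self.end


#: The MHC region on build 37, excluded for its atypical LD and gene density.
MHC_REGION = Region("6", 29624809, 33160245)


class ProxyMap:
    """Symmetric map from variant id to its LD proxies with r-squared values.

    The relation implicitly contains each id as its own proxy with r²=1;
    stored pairs are symmetrized on construction.  Every stored r² must be
    at or above ``r2_threshold``.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = (), r2_threshold: float = 0.8):
        if not 0.0 <= r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        self.r2_threshold = float(r2_threshold)
        self._map: dict[str, dict[str, float]] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 for pair ({a}, {b}) must be in [0, 1], got {r2}")
        if a == b:
            return
        if r2 < self.r2_threshold:
            return
        # keep the larger r2 if the pair is seen twice
        self._map.setdefault(a, {})
        self._map.setdefault(b, {})
        self._map[a][b] = max(self._map[a].get(b, 0.0), r2)
        self._map[b][a] = max(self._map[b].get(a, 0.0), r2)

    def proxies_of(self, vid: str, r2_threshold: float | None = None) -> dict[str, float]:
        """Proxies of ``vid`` (excluding itself) at or above the threshold."""
        thr = self.r2_threshold if r2_threshold is None else r2_threshold
        return {p: r for p, r in self._map.get(vid, {}).items() if r >= thr}

    def ids(self) -> set[str]:
        return set(self._map)

    def __contains__(self, vid: str) -> bool:
        return vid in self._map

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True)
class FeatureDef:
    """Definition of one annotation feature column."""

    name: str
    mode: str = "binary"  # "binary" or "quantitative"
    clump_group: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "quantitative"):
            raise ValueError(f"feature {self.name}: mode must be binary or quantitative")
        if self.clump_group is not None and self.mode != "binary":
            raise ValueError(f"feature {self.name}: only binary features may be clumped")


@dataclass(frozen=True)
class HitLabeling:
    """Hit / non-hit assignment at a significance tier.

    Variants that are neither (LD-excluded neighbours of hits) appear in
    neither set.
    """

    hit_ids: frozenset[str]
    nonhit_ids: frozenset[str]
    tier: str = "strong"
    phenotype: str = "all"

    def __post_init__(self) -> None:
        if self.hit_ids & self.nonhit_ids:
            raise ValueError("hit and non-hit sets overlap")
        if self.tier not in TIER_THRESHOLDS:
            raise ValueError(f"unknown tier {self.tier!r}")


class AnnotationMatrix:
    """Variants x features matrix of annotation values.

    Absence is encoded as 0 (no missing cells); quantitative columns are
    non-negative.  Backed by a :class:`pandas.DataFrame` indexed by variant
    id with one column per feature.
    """

    def __init__(self, data: pd.DataFrame, features: Sequence[FeatureDef]):
        names = [f.name for f in features]
        if list(data.columns) != names:
            raise ValueError("matrix columns do not match feature definitions")
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        if data.index.has_duplicates:
            raise ValueError("duplicate variant ids in matrix")
        if data.isna().any().any():
            raise ValueError("annotation matrix has missing cells; encode absence as 0")
        arr = data.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("annotation values must be non-negative")
        for f in features:
            if f.mode == "binary":
                col = data[f.name].to_numpy(dtype=float)
                if not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(f"binary feature {f.name} has values outside {{0,1}}")
        self.data = data.astype(float)
        self.features = list(features)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def variant_ids(self) -> pd.Index:
        return self.data.index

    def feature(self, name: str) -> FeatureDef:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subset(self, ids: Iterable[str]) -> "AnnotationMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"ids not in matrix: {sorted(missing)[:5]}")
        return AnnotationMatrix(self.data.loc[ids], self.features)

    def __repr__(self) -> str:
        return f"AnnotationMatrix({self.data.shape[0]} variants x {self.data.shape[1]} features)"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def exclude_regions(
    variants: Sequence[Variant],
    regions: Sequence[Region],
    drop_sex: bool = True,
) -> list[Variant]:
    """Remove variants inside any of ``regions`` (inclusive bounds) and,
    if ``drop_sex``, variants on the sex chromosomes.

    Raises ``ValueError`` naming the offending record on an unknown
    chromosome name.
    """
    kept = []
    for v in variants:
        chrom = normalize_chrom(v.chrom)
        if chrom not in VALID_CHROMS:
            raise ValueError(f"unknown chromosome {v.chrom!r} for variant {v.id}")
        if drop_sex and chrom in SEX_CHROMS:
            continue
        if any(r.contains(chrom, v.pos) for r in regions):
            continue
        kept.append(v)
    return kept


def label_hits(
    catalog: pd.DataFrame,
    universe: Sequence[Variant] | Iterable[str],
    tier: str = "strong",
    phenotype: str = "all",
) -> set[str]:
    """Ids of catalog SNPs present in the universe at the tier's p-value.

    ``catalog`` needs columns ``id`` and ``p_value`` (optionally
    ``phenotype``).  Duplicate entries for one SNP keep the minimum
    p-value.  Rows with malformed p-values are dropped with a logged
    warning count.
    """
    if tier not in TIER_THRESHOLDS:
        raise ValueError(f"tier must be one of {sorted(TIER_THRESHOLDS)}")
    threshold = TIER_THRESHOLDS[tier]
    universe_ids = {v.id if isinstance(v, Variant) else str(v) for v in universe}

    cat = catalog.copy()
    if phenotype != "all":
        if "phenotype" not in cat.columns:
            raise ValueError("catalog has no phenotype column")
        cat = cat[cat["phenotype"] == phenotype]
    pvals = pd.to_numeric(cat["p_value"], errors="coerce")
    bad = pvals.isna() | (pvals < 0) | (pvals > 1)
    if bad.any():
        logger.warning("label_hits: dropped %d catalog rows with malformed p-values", int(bad.sum()))
    cat = cat.loc[~bad].assign(p_value=pvals[~bad])
    best = cat.groupby("id")["p_value"].min()
    hits = set(best.index[best < threshold]) & universe_ids
    return hits


def define_nonhits(
    universe: Sequence[Variant] | Iterable[str],
    hits: set[str],
    proxies: ProxyMap,
    r2_threshold: float = 0.8,
) -> set[str]:
    """Universe minus hits minus every variant in LD (r² >= threshold)
    with any hit."""
    universe_ids = {v.id if isinstance(v, Variant) else str(v) for v in universe}
    ld_excluded: set[str] = set()
    for h in hits:
        ld_excluded.update(proxies.proxies_of(h, r2_threshold))
    return universe_ids - set(hits) - ld_excluded


def propagate_annotations(
    matrix: AnnotationMatrix,
    proxies: ProxyMap,
    index_ids: Iterable[str] | None = None,
) -> AnnotationMatrix:
    """Assign each index variant the maximum value of each feature across
    itself and all its LD proxies.

    ``index_ids`` restricts the output rows (default: all matrix rows).
    Proxy ids absent from the matrix contribute all-zero rows (logged).
    """
    if index_ids is None:
        index_ids = list(matrix.data.index)
    else:
        index_ids = list(index_ids)
        missing = set(index_ids) - set(matrix.data.index)
        if missing:
            raise KeyError(f"index ids not in matrix: {sorted(missing)[:5]}")

    values = matrix.data.to_numpy(dtype=float)
    row_of = {vid: i for i, vid in enumerate(matrix.data.index)}
    out = np.empty((len(index_ids), values.shape[1]))
    n_missing = 0
    for i, vid in enumerate(index_ids):
        acc = values[row_of[vid]].copy()
        for p in proxies.proxies_of(vid):
            j = row_of.get(p)
            if j is None:
                n_missing += 1  # all-zero row: no-op under max
                continue
            np.maximum(acc, values[j], out=acc)
        out[i] = acc
    if n_missing:
        logger.warning("propagate_annotations: %d proxy ids missing from matrix (treated as all-zero)", n_missing)
    frame = pd.DataFrame(out, index=pd.Index(index_ids, name=matrix.data.index.name), columns=matrix.feature_names)
    return AnnotationMatrix(frame, matrix.features)


def clump_features(matrix: AnnotationMatrix, defs: Sequence[FeatureDef] | None = None) -> AnnotationMatrix:
    """Collapse each clump group of binary features into one indicator
    (max across members); ungrouped and quantitative columns pass through.

    Output column order follows first appearance in the input.
    """
    defs = list(matrix.features if defs is None else defs)
    by_name = {f.name: f for f in defs}
    for f in matrix.features:
        fd = by_name.get(f.name, f)
        if fd.clump_group is not None and fd.mode != "binary":
            raise ValueError(f"clump group {fd.clump_group!r} contains quantitative feature {fd.name}")

    out_cols: list[pd.Series] = []
    out_defs: list[FeatureDef] = []
    seen_groups: set[str] = set()
    for f in matrix.features:
        fd = by_name.get(f.name, f)
        if fd.clump_group is None:
            out_cols.append(matrix.data[f.name])
            out_defs.append(fd)
        elif fd.clump_group not in seen_groups:
            seen_groups.add(fd.clump_group)
            members = [g.name for g in matrix.features if by_name.get(g.name, g).clump_group == fd.clump_group]
            col = matrix.data[members].max(axis=1)
            col.name = fd.clump_group
            out_cols.append(col)
            out_defs.append(FeatureDef(fd.clump_group, "binary"))
    frame = pd.concat(out_cols, axis=1)
    return AnnotationMatrix(frame, out_defs)


# ---------------------------------------------------------------------------
# annotation of variants against interval / score tracks
# ---------------------------------------------------------------------------

@dataclass
class _ChromIntervals:
    starts: np.ndarray  # sorted 1-based inclusive starts
    ends: np.ndarray    # sorted 1-based inclusive ends
    # for quantitative tracks, kept unsorted but aligned:
    raw_starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    raw_ends: np.ndarray = field(default_factory=lambda: np.empty(0))
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))


class IntervalTrack:
    """Binary membership track over genomic intervals (1-based inclusive)."""

    def __init__(self, intervals: pd.DataFrame):
        # columns chrom, start, end — already 1-based inclusive
        self._by_chrom: dict[str, _ChromIntervals] = {}
        for chrom, grp in intervals.groupby(intervals["chrom"].map(normalize_chrom)):
            self._by_chrom[chrom] = _ChromIntervals(
                starts=np.sort(grp["start"].to_numpy(dtype=np.int64)),
                ends=np.sort(grp["end"].to_numpy(dtype=np.int64)),
            )

    def covers(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        ci = self._by_chrom.get(normalize_chrom(chrom))
        if ci is None:
            return np.zeros(len(pos), dtype=float)
        pos = np.asarray(pos, dtype=np.int64)
        n_started = np.searchsorted(ci.starts, pos, side="right")
        n_ended = np.searchsorted(ci.ends, pos, side="left")
        return (n_started > n_ended).astype(float)


class ScoreTrack:
    """Quantitative track: per-position value is the average score over all
    overlapping blocks; 0 where no block overlaps."""

    def __init__(self, blocks: pd.DataFrame):
        # columns chrom, start, end, score — 1-based inclusive
        self._by_chrom: dict[str, _ChromIntervals] = {}
        for chrom, grp in blocks.groupby(blocks["chrom"].map(normalize_chrom)):
            self._by_chrom[chrom] = _ChromIntervals(
                starts=np.empty(0),
                ends=np.empty(0),
                raw_starts=grp["start"].to_numpy(dtype=np.int64),
                raw_ends=grp["end"].to_numpy(dtype=np.int64),
                scores=grp["score"].to_numpy(dtype=float),
            )

    def value_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        ci = self._by_chrom.get(normalize_chrom(chrom))
        out = np.zeros(len(pos), dtype=float)
        if ci is None:
            return out
        for i, p in enumerate(np.asarray(pos, dtype=np.int64)):
            mask = (ci.raw_starts <= p) & (ci.raw_ends >= p)
            if mask.any():
                out[i] = float(ci.scores[mask].mean())
        return out


def annotate_variants(
    variants: Sequence[Variant],
    tracks: Sequence[tuple[FeatureDef, IntervalTrack | ScoreTrack | Mapping[str, float]]],
) -> AnnotationMatrix:
    """Build the annotation matrix for ``variants`` from feature tracks.

    Each track is either an :class:`IntervalTrack` (binary),
    a :class:`ScoreTrack` (quantitative, averaged over overlapping blocks),
    or a per-SNP ``{id: score}`` mapping.
    """
    ids = [v.id for v in variants]
    chroms = np.array([normalize_chrom(v.chrom) for v in variants])
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    cols = {}
    defs = []
    for fdef, track in tracks:
        col = np.zeros(len(variants), dtype=float)
        if isinstance(track, (IntervalTrack, ScoreTrack)):
            for chrom in np.unique(chroms):
                sel = chroms == chrom
                if isinstance(track, IntervalTrack):
                    col[sel] = track.covers(chrom, pos[sel])
                else:
                    col[sel] = track.value_at(chrom, pos[sel])
        else:
            col = np.array([float(track.get(vid, 0.0)) for vid in ids])
        cols[fdef.name] = col
        defs.append(fdef)
    frame = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    return AnnotationMatrix(frame, defs)
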