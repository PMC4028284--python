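"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are tab-separated with a header row.  Floats are written with
a fixed ``%.10g`` format so that repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from funcprior.annotation import AnnotationMatrix, FeatureDef, HitLabeling, ProxyMap, Variant
from funcprior.model import ClassWeights, ElasticNetConfig, FitResult

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- variants / catalog / labels -------------------------------------------

def read_manifest(path) -> list[Variant]:
    """Array manifest TSV with columns id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    for col in ("id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"manifest {path}: missing column {col!r}")
    return [Variant(str(r.id), str(r.chrom), int(r.pos)) for r in df.itertuples()]


def write_manifest(variants: list[Variant], path) -> None:
    df = pd.DataFrame({"id": [v.id for v in variants], "chrom": [v.chrom for v in variants], "pos": [v.pos for v in variants]})
    write_tsv(df, path)


def read_catalog(path) -> pd.DataFrame:
    """GWAS-hit catalog TSV with columns id, p_value and optional phenotype."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "p_value" not in df.columns:
        raise ValueError(f"catalog {path}: need columns id and p_value")
    return df


def read_labels(path) -> HitLabeling:
    """Labels TSV with columns id, label (1 = hit, 0 = non-hit)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    hits = frozenset(df.loc[df["label"] == 1, "id"])
    nonhits = frozenset(df.loc[df["label"] == 0, "id"])
    return HitLabeling(hit_ids=hits, nonhit_ids=nonhits)


def write_labels(labels: HitLabeling, path) -> None:
    rows = [(i, 1) for i in sorted(labels.hit_ids)] + [(i, 0) for i in sorted(labels.nonhit_ids)]
    write_tsv(pd.DataFrame(rows, columns=["id", "label"]), path)


# -- LD --------------------------------------------------------------------

def read_ld(path, r2_threshold: float = 0.8) -> ProxyMap:
    """LD table: TSV with columns id_a, id_b, r2; a PLINK ``.ld``-style
    whitespace-separated table with SNP_A/SNP_B/R2 columns is also accepted."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "id_a" in cols and "id_b" in cols and "r2" in cols:
        a, b, r = cols["id_a"], cols["id_b"], cols["r2"]
    elif "snp_a" in cols and "snp_b" in cols and "r2" in cols:
        a, b, r = cols["snp_a"], cols["snp_b"], cols["r2"]
    else:
        raise ValueError(f"LD table {path}: need columns (id_a, id_b, r2) or PLINK (SNP_A, SNP_B, R2)")
    pairs = zip(df[a].astype(str), df[b].astype(str), df[r].astype(float))
    return ProxyMap(pairs, r2_threshold=r2_threshold)


def write_ld(proxies: ProxyMap, path) -> None:
    rows = []
    for a in sorted(proxies.ids()):
        for b, r2 in sorted(proxies.proxies_of(a).items()):
            if a < b:  # each symmetric pair once
                rows.append((a, b, r2))
    write_tsv(pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]), path)


# -- tracks ----------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) converted to 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str})
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ValueError(f"BED {path}: empty or inverted interval")
    return df


def read_score_track(path):
    """Quantitative track: either blocks (chrom, start, end, score; BED-style
    coordinates) or a per-SNP table (id, score) returned as a mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    if {"chrom", "start", "end", "score"} <= set(df.columns):
        out = df[["chrom", "start", "end", "score"]].copy()
        out["start"] = out["start"].astype(int) + 1
        out["end"] = out["end"].astype(int)
        return out
    if {"id", "score"} <= set(df.columns):
        return dict(zip(df["id"].astype(str), df["score"].astype(float)))
    raise ValueError(f"score track {path}: need (chrom, start, end, score) or (id, score) columns")


# -- annotation matrix -----------------------------------------------------

def write_matrix(matrix: AnnotationMatrix, path) -> None:
    """Matrix TSV (first column id) plus a ``<path>.features.tsv`` sidecar
    recording feature modes and clump groups."""
    path = Path(path)
    df = matrix.data.copy()
    df.insert(0, "id", df.index)
    write_tsv(df, path)
    feats = pd.DataFrame(
        {
            "name": [f.name for f in matrix.features],
            "mode": [f.mode for f in matrix.features],
            "clump_group": [f.clump_group or "" for f in matrix.features],
        }
    )
    write_tsv(feats, path.with_suffix(path.suffix + ".features.tsv"))


def read_matrix(path) -> AnnotationMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
    sidecar = path.with_suffix(path.suffix + ".features.tsv")
    if sidecar.exists():
        feats = pd.read_csv(sidecar, sep="\t", keep_default_na=False)
        defs = [
            FeatureDef(str(r.name), str(r.mode), str(r.clump_group) or None)
            for r in feats.itertuples(index=False)
        ]
    else:
        defs = [
            FeatureDef(c, "binary" if df[c].isin((0, 1)).all() else "quantitative")
            for c in df.columns
        ]
    return AnnotationMatrix(df, defs)


# -- model -----------------------------------------------------------------

def save_model(fit: FitResult, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coef = pd.DataFrame({"feature": list(fit.coefficients), "coefficient": list(fit.coefficients.values())})
    write_tsv(coef, directory / "coefficients.tsv")
    meta = {
        "intercept": fit.intercept,
        "alpha": fit.config.alpha,
        "lambda": fit.config.lambda_,
        "n_folds": fit.config.n_folds,
        "seed": fit.config.seed,
        "standardize": fit.config.standardize,
        "w_hit": fit.weights.w_hit,
        "w_nonhit": fit.weights.w_nonhit,
        "constant_features": fit.constant_features,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    if fit.cv_deviance_path is not None:
        write_tsv(fit.cv_deviance_path, directory / "cv_path.tsv")


def load_model(directory) -> FitResult:
    directory = Path(directory)
    coef = pd.read_csv(directory / "coefficients.tsv", sep="\t")
    meta = json.loads((directory / "model.json").read_text())
    cfg = ElasticNetConfig(
        alpha=meta["alpha"],
        lambda_=meta["lambda"],
        n_folds=meta["n_folds"],
        seed=meta["seed"],
        standardize=meta["standardize"],
    )
    path_file = directory / "cv_path.tsv"
    return FitResult(
        intercept=float(meta["intercept"]),
        coefficients=dict(zip(coef["feature"].astype(str), coef["coefficient"].astype(float))),
        config=cfg,
        weights=ClassWeights(meta["w_hit"], meta["w_nonhit"]),
        cv_deviance_path=pd.read_csv(path_file, sep="\t") if path_file.exists() else None,
        constant_features=list(meta.get("constant_features", [])),
    )
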