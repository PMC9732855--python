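"""File dialects: GWAS summary TSV, weight tables, GMT gene sets, panel
matrices, and YAML configuration.

All tables are plain tab-delimited text.  Lines starting with ``#`` are
metadata comments (the pipeline stamps a config hash there) and are ignored on
read.  Malformed input raises :class:`~xwas.errors.ParseError` naming the line
or record at fault.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import GwasSummary
from .errors import ParseError
from .panel import VALID_ALLELES, ReferencePanel
from .simulate import GeneSetCollection
from .weights import VALID_METHODS, GeneWeights

WEIGHT_COLUMNS = ["gene_id", "snp_id", "chrom", "pos", "a1", "a2", "maf",
                  "weight", "model_tag", "cv_r2", "h2_est", "h2_raw", "h2_p"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_tsv_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a generic result table in the package's TSV dialect."""
    _write_tsv(df, path, header_comment)


def read_tsv_table(path, required=()) -> pd.DataFrame:
    return _read_tsv(path, list(required))


# ----------------------------------------------------------------------
# GWAS summary
# ----------------------------------------------------------------------

_GWAS_HEADER = {"SNP": "snp_id", "CHR": "chrom", "POS": "pos",
                "A1": "a1", "A2": "a2", "Z": "z", "N": "n"}


def write_gwas(gwas: GwasSummary, path, *, header_comment=None) -> None:
    """Write the minimal summary-statistic dialect: SNP CHR POS A1 A2 Z [N]."""
    inv = {v: k for k, v in _GWAS_HEADER.items()}
    df = gwas.table.rename(columns=inv)
    cols = [c for c in ["SNP", "CHR", "POS", "A1", "A2", "Z", "N"] if c in df.columns]
    _write_tsv(df[cols], path, header_comment)


def read_gwas(path) -> GwasSummary:
    df = _read_tsv(path, ["SNP", "CHR", "POS", "A1", "A2", "Z"])
    df = df.rename(columns=_GWAS_HEADER)
    df["chrom"] = df["chrom"].astype(str)
    dup = df["snp_id"].duplicated()
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: duplicated SNP id at line {line}")
    z = pd.to_numeric(df["z"], errors="coerce")
    if z.isna().any():
        line = int(df.index[z.isna()][0]) + 2
        raise ParseError(f"{path}: non-numeric Z at line {line}")
    df["z"] = z
    bad = ~df["a1"].isin(VALID_ALLELES) | ~df["a2"].isin(VALID_ALLELES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: allele code outside {{A,C,G,T}} at line {line}")
    return GwasSummary(df)


# ----------------------------------------------------------------------
# Weight tables (one TSV per panel, long format: one row per gene-SNP)
# ----------------------------------------------------------------------

def write_weight_panel(genes: list[GeneWeights], path, *, header_comment=None) -> None:
    rows = []
    for g in genes:
        for snp, pos, a1, a2, maf, w in zip(g.snp_ids, g.pos, g.a1, g.a2,
                                            g.maf, g.W):
            rows.append((g.gene_id, snp, g.chrom, pos, a1, a2, maf, w,
                         g.model_tag, g.cv_r2, g.h2_est, g.h2_raw, g.h2_p))
    _write_tsv(pd.DataFrame(rows, columns=WEIGHT_COLUMNS), path, header_comment)


def read_weight_panel(path) -> list[GeneWeights]:
    df = _read_tsv(path, WEIGHT_COLUMNS)
    bad_tag = ~df["model_tag"].isin(VALID_METHODS)
    if bad_tag.any():
        tag = df.loc[bad_tag, "model_tag"].iloc[0]
        raise ParseError(f"{path}: unknown model_tag {tag!r}")
    genes = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        if grp["snp_id"].duplicated().any():
            raise ParseError(f"{path}: duplicated SNP in gene {gene_id!r}")
        first = grp.iloc[0]
        genes.append(GeneWeights(
            gene_id=str(gene_id), chrom=str(first["chrom"]),
            snp_ids=grp["snp_id"].tolist(), pos=grp["pos"].tolist(),
            a1=grp["a1"].tolist(), a2=grp["a2"].tolist(),
            maf=grp["maf"].tolist(), W=grp["weight"].to_numpy(dtype=float),
            model_tag=str(first["model_tag"]), cv_r2=float(first["cv_r2"]),
            h2_est=float(first["h2_est"]), h2_raw=float(first["h2_raw"]),
            h2_p=float(first["h2_p"]),
        ))
    return genes


# ----------------------------------------------------------------------
# GMT gene sets
# ----------------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (set_id TAB description TAB gene...).

    When no universe is supplied, the union of all members is used.
    Duplicated members within a set are a parse failure naming the set.
    """
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected id, description "
                             "and at least one member")
        set_id, desc, members = fields[0], fields[1], tuple(fields[2:])
        if set_id in sets:
            raise ParseError(f"{path}: line {lineno}: duplicated set id {set_id!r}")
        if len(set(members)) != len(members):
            raise ParseError(f"{path}: set {set_id!r} has a duplicated member")
        sets[set_id] = (desc, members)
    if universe is None:
        universe = tuple(sorted({g for _, mem in sets.values() for g in mem}))
    return GeneSetCollection(sets, tuple(universe))


# ----------------------------------------------------------------------
# Reference panel (matrix TSV + SNP metadata TSV)
# ----------------------------------------------------------------------

def write_panel(panel: ReferencePanel, matrix_path, snp_path, *,
                header_comment=None) -> None:
    mat = pd.DataFrame(panel.genotypes, columns=panel.snp_ids)
    mat.insert(0, "individual_id", [f"ind{i + 1}" for i in range(panel.n_individuals)])
    _write_tsv(mat, matrix_path, header_comment)
    _write_tsv(panel.snps, snp_path, header_comment)


def read_panel(matrix_path, snp_path) -> ReferencePanel:
    snps = _read_tsv(snp_path, ["snp_id", "chrom", "pos", "a1", "a2", "maf"])
    mat = _read_tsv(matrix_path, [])
    if "individual_id" in mat.columns:
        mat = mat.drop(columns=["individual_id"])
    if list(mat.columns) != snps["snp_id"].tolist():
        raise ParseError(f"{matrix_path}: matrix columns do not match SNP metadata")
    return ReferencePanel(mat.to_numpy(dtype=float), snps)


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------

def write_config(config_dict: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config_dict, sort_keys=True))


def read_config(path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    if not isinstance(loaded, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return loaded


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration (canonical JSON, sha256)."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
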