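"""Readers and writers for the pipeline's tabular inputs.

TSV dialect: tab-separated, UTF-8, header row, '.' for missing values.
Rows violating a table's invariants are dropped with a logged count;
missing required columns are a hard error naming the column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ptmburden.config import validate_division
from ptmburden.constants import EFFECTS, MISSING, PTM_TYPES, VARIANT_KINDS

log = logging.getLogger(__name__)

MUTATION_COLUMNS = [
    "sample",
    "cancer",
    "gene",
    "protein_id",
    "aa_start",
    "aa_end",
    "effect",
    "variant_kind",
    "ref",
    "alt",
    "ref_aa",
    "sift",
    "polyphen",
]

_BASES = set("ACGT")


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _drop(df: pd.DataFrame, bad: pd.Series, path, reason: str) -> pd.DataFrame:
    n = int(bad.sum())
    if n:
        log.warning("%s: dropped %d row(s): %s", path, n, reason)
    return df.loc[~bad]


def _to_int(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def read_mutations(path) -> pd.DataFrame:
    """Read a protein-space somatic mutation table (MAF-style subset)."""
    df = _read_tsv(path, MUTATION_COLUMNS)
    df["aa_start"] = _to_int(df["aa_start"])
    df["aa_end"] = _to_int(df["aa_end"])

    bad = df["aa_start"].isna() | df["aa_end"].isna() | (df["aa_start"] < 1)
    df = _drop(df, bad, path, "unparseable or non-positive protein coordinates")
    bad = df["aa_end"] < df["aa_start"]
    df = _drop(df, bad, path, "protein_end < protein_start")
    bad = ~df["effect"].isin(EFFECTS)
    df = _drop(df, bad, path, "unknown effect class")
    bad = ~df["variant_kind"].isin(VARIANT_KINDS)
    df = _drop(df, bad, path, "unknown variant_kind")
    snp = df["variant_kind"] == "SNP"
    bad = snp & (
        ~df["ref"].isin(_BASES) | ~df["alt"].isin(_BASES) | (df["ref"] == df["alt"])
    )
    df = _drop(df, bad, path, "SNP without two distinct single bases")

    df = df.astype({"aa_start": int, "aa_end": int})
    for col in ("ref", "alt", "ref_aa", "sift", "polyphen"):
        df[col] = df[col].fillna(MISSING)
    return df.reset_index(drop=True)


def read_ptm_sites(path) -> pd.DataFrame:
    """Read the PTM-site table; (protein_id, position, ptm_type) unique."""
    df = _read_tsv(path, ["protein_id", "position", "ptm_type", "residue"])
    df["position"] = _to_int(df["position"])
    df = _drop(df, df["position"].isna() | (df["position"] < 1), path,
               "non-positive or unparseable position")
    df = _drop(df, ~df["ptm_type"].isin(PTM_TYPES), path, "unknown ptm_type")
    n0 = len(df)
    df = df.drop_duplicates(subset=["protein_id", "position", "ptm_type"])
    if len(df) < n0:
        log.warning("%s: deduplicated %d site row(s)", path, n0 - len(df))
    return df.astype({"position": int}).reset_index(drop=True)


def read_catalog(path) -> pd.DataFrame:
    """Read the gene catalog with matrisome division/category labels."""
    df = _read_tsv(
        path,
        [
            "gene_symbol",
            "protein_id",
            "gene_length",
            "protein_length",
            "is_matrisome",
            "division",
            "category",
        ],
    )
    df["gene_length"] = _to_int(df["gene_length"])
    df["protein_length"] = _to_int(df["protein_length"])
    df["is_matrisome"] = df["is_matrisome"].str.lower().isin(["true", "1", "yes"])

    bad = (
        df["gene_length"].isna()
        | df["protein_length"].isna()
        | (df["protein_length"] < 1)
        | (df["gene_length"] < 3 * df["protein_length"])
    )
    df = _drop(df, bad, path, "invalid gene/protein length")
    bad = ~df.apply(lambda r: validate_division(r["category"], r["division"]), axis=1)
    df = _drop(df, bad, path, "category inconsistent with division")
    bad = df["is_matrisome"] != (df["division"] != "none")
    df = _drop(df, bad, path, "is_matrisome inconsistent with division")
    n0 = len(df)
    df = df.drop_duplicates(subset=["gene_symbol"], keep="first")
    if len(df) < n0:
        log.warning("%s: dropped %d duplicate gene_symbol row(s)", path, n0 - len(df))
    return df.astype({"gene_length": int, "protein_length": int}).reset_index(drop=True)


def _read_intervals(path, id_col: str) -> pd.DataFrame:
    df = _read_tsv(path, ["protein_id", id_col, "start", "end"])
    df["start"] = _to_int(df["start"])
    df["end"] = _to_int(df["end"])
    bad = (
        df["start"].isna() | df["end"].isna() | (df["start"] < 1)
        | (df["end"] < df["start"])
    )
    df = _drop(df, bad, path, "degenerate interval")
    return df.astype({"start": int, "end": int}).reset_index(drop=True)


def read_domains(path) -> pd.DataFrame:
    """Read Pfam-style domain instance intervals (1-based, inclusive)."""
    return _read_intervals(path, "domain_id")


def read_regions(path) -> pd.DataFrame:
    """Read UniProt-feature-style functional region intervals."""
    return _read_intervals(path, "region")


def read_interactions(path) -> pd.DataFrame:
    """Read a BioGRID-style edge list; symmetric duplicates collapsed."""
    df = _read_tsv(path, ["gene_a", "gene_b"])
    lo = np.minimum(df["gene_a"], df["gene_b"])
    hi = np.maximum(df["gene_a"], df["gene_b"])
    return (
        pd.DataFrame({"gene_a": lo, "gene_b": hi})
        .drop_duplicates()
        .reset_index(drop=True)
    )


def read_sequences(path) -> dict[str, str]:
    """Read protein sequences from FASTA."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bundle(paths: dict) -> dict:
    """Read a full input bundle from a {name: path} mapping.

    Required: mutations, sites, catalog.  Optional: domains, regions,
    interactions, sequences, normals.
    """
    out = {
        "mutations": read_mutations(paths["mutations"]),
        "sites": read_ptm_sites(paths["sites"]),
        "catalog": read_catalog(paths["catalog"]),
    }
    if "domains" in paths:
        out["domains"] = read_domains(paths["domains"])
    if "regions" in paths:
        out["regions"] = read_regions(paths["regions"])
    if "interactions" in paths:
        out["interactions"] = read_interactions(paths["interactions"])
    if "sequences" in paths:
        out["sequences"] = read_sequences(paths["sequences"])
    if "normals" in paths:
        out["normals"] = _read_tsv(paths["normals"], ["gene", "position"]).assign(
            position=lambda d: _to_int(d["position"]).astype(int)
        )
    return out
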