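"""The PTM^mut burden and its comparisons.

The *local burden* of a protein, PTM type and cancer cohort is the
percentage of the protein's known PTM sites of that type hit by at least
one PTM^mut in that cohort (recurrent hits on one site count once).
Averaging local burdens across the pan-cancer cohort gives the *global
burden* of a gene set per PTM type; matrisome-vs-rest enrichment is
reported as ``fold = burden(matrisome) / burden(rest) - 1``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def share_ratio(numerator: float, denominator: float) -> float:
    """Percentage ``100 * numerator / denominator``; zero denominator is an error."""
    if denominator <= 0:
        raise ValueError("share_ratio: denominator must be positive")
    return 100.0 * numerator / denominator


def _exploded_hits(annotated: pd.DataFrame) -> pd.DataFrame:
    """One row per (mutation, hit site): sample, cancer, protein, position, type."""
    ptm = annotated[annotated["is_ptm_mut"]]
    if ptm.empty:
        return pd.DataFrame(
            columns=["sample", "cancer", "gene", "protein_id", "position", "ptm_type"]
        )
    rows = ptm[["sample", "cancer", "gene", "protein_id", "hit_sites"]].explode(
        "hit_sites"
    )
    rows[["position", "ptm_type"]] = pd.DataFrame(
        rows["hit_sites"].tolist(), index=rows.index
    )
    return rows.drop(columns="hit_sites")


def local_burdens(
    annotated: pd.DataFrame,
    sites: pd.DataFrame,
    cancers: list[str] | None = None,
) -> pd.DataFrame:
    """Local burden per (protein, PTM type, cancer).

    Rows exist for every protein/type with at least one known site and
    every cancer in the cohort, including zero-hit combinations; proteins
    with no known sites of a type are absent rather than zero.
    """
    if cancers is None:
        cancers = sorted(annotated["cancer"].unique())
    known = (
        sites.groupby(["protein_id", "ptm_type"], as_index=False)
        .agg(n_sites_known=("position", "nunique"))
    )
    base = known.merge(pd.DataFrame({"cancer": cancers}), how="cross")

    hits = _exploded_hits(annotated)
    if hits.empty:
        hit_counts = pd.DataFrame(
            columns=["protein_id", "ptm_type", "cancer", "n_sites_hit"]
        )
    else:
        hit_counts = (
            hits.groupby(["protein_id", "ptm_type", "cancer"], as_index=False)
            .agg(n_sites_hit=("position", "nunique"))
        )

    out = base.merge(hit_counts, on=["protein_id", "ptm_type", "cancer"], how="left")
    out["n_sites_hit"] = out["n_sites_hit"].fillna(0).astype(int)
    out["local_burden"] = 100.0 * out["n_sites_hit"] / out["n_sites_known"]
    return out.sort_values(
        ["protein_id", "ptm_type", "cancer"], ignore_index=True
    )


def gene_sets_from_catalog(catalog: pd.DataFrame) -> dict[str, set]:
    """Default matrisome / rest partition as protein-id sets."""
    m = catalog["is_matrisome"]
    return {
        "matrisome": set(catalog.loc[m, "protein_id"]),
        "rest": set(catalog.loc[~m, "protein_id"]),
    }


def global_burden(
    burden_table: pd.DataFrame,
    gene_sets: dict[str, set],
    rest_name: str = "rest",
    method: str = "mean",
) -> pd.DataFrame:
    """Global burden per gene set and PTM type, with fold vs the rest set.

    ``method='mean'`` (default) averages local burdens over all
    (protein, cancer) rows of the set; ``method='pooled'`` divides summed
    distinct-site hits by summed known sites.  Folds are reported missing
    when the rest-set burden is zero or absent.
    """
    if method not in ("mean", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for name, proteins in gene_sets.items():
        sub = burden_table[burden_table["protein_id"].isin(proteins)]
        for ptm_type, grp in sub.groupby("ptm_type"):
            if method == "mean":
                gb = float(grp["local_burden"].mean())
            else:
                gb = 100.0 * grp["n_sites_hit"].sum() / grp["n_sites_known"].sum()
            rows.append({"gene_set": name, "ptm_type": ptm_type, "global_burden": gb})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(columns=["gene_set", "ptm_type", "global_burden",
                                    "fold_vs_rest"])
    rest = out[out["gene_set"] == rest_name].set_index("ptm_type")["global_burden"]

    def fold(row):
        r = rest.get(row["ptm_type"], np.nan)
        if row["gene_set"] == rest_name or not r > 0:
            return np.nan
        return row["global_burden"] / r - 1.0

    out["fold_vs_rest"] = out.apply(fold, axis=1)
    return out.sort_values(["gene_set", "ptm_type"], ignore_index=True)


def _ptm_counts(annotated: pd.DataFrame, proteins: set) -> tuple[int, int]:
    """(PTM^mut, non-PTM non-silent) counts for a protein set."""
    sub = annotated[
        annotated["protein_id"].isin(proteins) & (annotated["effect"] != "silent")
    ]
    n_ptm = int(sub["is_ptm_mut"].sum())
    return n_ptm, len(sub) - n_ptm


def chi2_2x2(table, yates: bool = False) -> tuple[float, float, np.ndarray]:
    """Two-sided chi-square on a 2x2 table; returns (stat, p, expected)."""
    stat, p, _, expected = stats.chi2_contingency(
        np.asarray(table, dtype=float), correction=yates
    )
    return float(stat), float(p), expected


def random_set_control(
    annotated: pd.DataFrame,
    catalog: pd.DataFrame,
    n_draws: int = 100,
    set_size: int | None = None,
    seed: int = 0,
    yates: bool = False,
) -> pd.DataFrame:
    """Matrisome vs. random same-size gene sets: chi-square per draw.

    Each draw samples ``set_size`` genes (default: matrisome size)
    without replacement from the non-matrisome pool and tests the 2x2
    table [PTM^mut, non-PTM non-silent] x [matrisome, random].  Draws
    whose expected counts fall below 1 are flagged invalid and excluded
    from min/max summaries.
    """
    rng = np.random.default_rng(seed)
    matrisome = catalog.loc[catalog["is_matrisome"], "protein_id"].to_numpy()
    pool = catalog.loc[~catalog["is_matrisome"], "protein_id"].to_numpy()
    if set_size is None:
        set_size = len(matrisome)
    if len(pool) < set_size:
        raise ValueError("rest-of-genome pool smaller than the requested set size")

    m_ptm, m_non = _ptm_counts(annotated, set(matrisome))
    rows = []
    for draw in range(n_draws):
        picked = set(rng.choice(pool, size=set_size, replace=False))
        r_ptm, r_non = _ptm_counts(annotated, picked)
        table = np.array([[m_ptm, m_non], [r_ptm, r_non]], dtype=float)
        if table.sum() == 0 or (table.sum(axis=1) == 0).any() or (
            table.sum(axis=0) == 0
        ).any():
            rows.append({"draw": draw, "p_value": np.nan, "valid": False,
                         "matrisome_rate": np.nan, "random_rate": np.nan})
            continue
        stat, p, expected = chi2_2x2(table, yates=yates)
        valid = bool((expected >= 1).all())
        rows.append(
            {
                "draw": draw,
                "p_value": p,
                "valid": valid,
                "matrisome_rate": m_ptm / (m_ptm + m_non) if m_ptm + m_non else np.nan,
                "random_rate": r_ptm / (r_ptm + r_non) if r_ptm + r_non else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if not out["valid"].any():
        log.warning("random_set_control: no valid draws (expected cells < 1)")
    return out


def summarize_control(control: pd.DataFrame) -> dict:
    """min / max p over valid draws of the 100-random-set control."""
    valid = control[control["valid"]]
    return {
        "n_valid": int(len(valid)),
        "p_min": float(valid["p_value"].min()) if len(valid) else float("nan"),
        "p_max": float(valid["p_value"].max()) if len(valid) else float("nan"),
    }


def family_burden_correlation(
    burden_table: pd.DataFrame,
    annotated: pd.DataFrame,
    catalog: pd.DataFrame,
) -> pd.DataFrame:
    """Per matrisome category: Pearson r between per-cancer mean local
    burden and per-cancer PTM^mut count.

    Requires at least 3 cancers; constant vectors yield a missing r.
    """
    cancers = sorted(annotated["cancer"].unique())
    if len(cancers) < 3:
        raise ValueError("family_burden_correlation requires >= 3 cancers")
    cat_of = dict(zip(catalog["protein_id"], catalog["category"]))
    bt = burden_table.assign(category=burden_table["protein_id"].map(cat_of))
    ptm = annotated[annotated["is_ptm_mut"]].assign(
        category=annotated.loc[annotated["is_ptm_mut"], "protein_id"].map(cat_of)
    )
    rows = []
    for cat in sorted(set(cat_of.values()) - {"none"}):
        x, y = [], []
        sub_b = bt[bt["category"] == cat]
        sub_m = ptm[ptm["category"] == cat]
        for cancer in cancers:
            b = sub_b.loc[sub_b["cancer"] == cancer, "local_burden"]
            if b.empty:
                continue
            x.append(float(b.mean()))
            y.append(int((sub_m["cancer"] == cancer).sum()))
        if len(x) < 3:
            rows.append({"category": cat, "r": np.nan, "p_value": np.nan,
                         "n_points": len(x)})
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"category": cat, "r": np.nan, "p_value": np.nan,
                         "n_points": len(x)})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"category": cat, "r": float(r), "p_value": float(p),
                     "n_points": len(x)})
    return pd.DataFrame(rows)


def length_normalized_rate(
    annotated: pd.DataFrame,
    catalog: pd.DataFrame,
    genes: set | None = None,
    mut_class: str = "ptm",
) -> float:
    """Mean over genes of (mutation-class count / gene length).

    ``mut_class``: 'ptm', 'non_ptm' (non-silent, not PTM^mut),
    'nonsilent', 'silent' or 'all'.  Genes with zero mutations of the
    class contribute 0.
    """
    sub = catalog if genes is None else catalog[catalog["gene_symbol"].isin(genes)]
    if (sub["gene_length"] <= 0).any():
        raise ValueError("gene_length must be positive for all genes in the subset")
    masks = {
        "ptm": annotated["is_ptm_mut"],
        "non_ptm": (annotated["effect"] != "silent") & ~annotated["is_ptm_mut"],
        "nonsilent": annotated["effect"] != "silent",
        "silent": annotated["effect"] == "silent",
        "all": pd.Series(True, index=annotated.index),
    }
    if mut_class not in masks:
        raise ValueError(f"unknown mut_class {mut_class!r}")
    counts = annotated.loc[masks[mut_class], "gene"].value_counts()
    per_gene = sub["gene_symbol"].map(counts).fillna(0).to_numpy()
    return float(np.mean(per_gene / sub["gene_length"].to_numpy()))
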