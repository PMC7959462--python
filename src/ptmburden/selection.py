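"""Selection statistics and hotspot recurrence.

dN/dS here is the raw ratio of non-silent to silent mutation counts over
a set of residue positions — no codon-opportunity model — used as a
coarse proxy for selection pressure.  Per gene, r^dN/dS divides the
dN/dS at annotated PTM positions by the dN/dS at all other positions;
values below 1 indicate stronger purifying selection against PTM-site
disruption.  Positions are compared by residue index: a silent mutation
counts toward the PTM class when its codon maps to an annotated residue.

A pseudocount (default 0.5) is added to all four counts so that
TCGA-scale sparsity does not flood the table with undefined ratios; with
the pseudocount disabled, zero denominators yield a missing value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ptmburden.constants import AMINO_ACIDS

log = logging.getLogger(__name__)


def ptm_positions_by_protein(
    sites: pd.DataFrame, ptm_type: str | None = None
) -> dict[str, frozenset]:
    sub = sites if ptm_type is None else sites[sites["ptm_type"] == ptm_type]
    return {
        pid: frozenset(grp["position"]) for pid, grp in sub.groupby("protein_id")
    }


def gene_dnds(
    gene_muts: pd.DataFrame,
    ptm_positions: frozenset,
    position_class: str = "ptm_site",
    pseudocount: float = 0.5,
) -> float:
    """dN/dS for one gene over PTM-site or non-PTM-site positions.

    ``gene_muts`` must include silent records.  Returns NaN when the
    silent count is zero and the pseudocount is disabled.
    """
    if position_class not in ("ptm_site", "non_ptm_site"):
        raise ValueError(f"unknown position_class {position_class!r}")
    on_site = gene_muts["aa_start"].isin(ptm_positions)
    mask = on_site if position_class == "ptm_site" else ~on_site
    sub = gene_muts[mask]
    n_silent = int((sub["effect"] == "silent").sum())
    n_nonsilent = len(sub) - n_silent
    if n_silent + pseudocount == 0:
        return float("nan")
    return (n_nonsilent + pseudocount) / (n_silent + pseudocount)


def rdnds_table(
    annotated: pd.DataFrame,
    sites: pd.DataFrame,
    pseudocount: float = 0.5,
    ptm_type: str | None = None,
) -> pd.DataFrame:
    """Per-gene r^dN/dS records.

    One row per gene with at least one annotated PTM position (optionally
    restricted to one PTM type) and at least one mutation.  Columns carry
    the four raw counts, both dN/dS values and their ratio.
    """
    pos_by_protein = ptm_positions_by_protein(sites, ptm_type)
    rows = []
    for (gene, pid), grp in annotated.groupby(["gene", "protein_id"]):
        positions = pos_by_protein.get(pid)
        if not positions:
            continue
        on_site = grp["aa_start"].isin(positions)
        silent = grp["effect"] == "silent"
        n_ns_ptm = int((on_site & ~silent).sum())
        n_s_ptm = int((on_site & silent).sum())
        n_ns_non = int((~on_site & ~silent).sum())
        n_s_non = int((~on_site & silent).sum())

        def ratio(num, den):
            if den + pseudocount == 0:
                return float("nan")
            return (num + pseudocount) / (den + pseudocount)

        dnds_ptm = ratio(n_ns_ptm, n_s_ptm)
        dnds_non = ratio(n_ns_non, n_s_non)
        r = (
            dnds_ptm / dnds_non
            if np.isfinite(dnds_ptm) and np.isfinite(dnds_non) and dnds_non > 0
            else float("nan")
        )
        rows.append(
            {
                "gene_symbol": gene,
                "protein_id": pid,
                "n_nonsilent_ptm": n_ns_ptm,
                "n_silent_ptm": n_s_ptm,
                "n_nonsilent_nonptm": n_ns_non,
                "n_silent_nonptm": n_s_non,
                "dnds_ptm": dnds_ptm,
                "dnds_nonptm": dnds_non,
                "r_dnds": r,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_symbol",
            "protein_id",
            "n_nonsilent_ptm",
            "n_silent_ptm",
            "n_nonsilent_nonptm",
            "n_silent_nonptm",
            "dnds_ptm",
            "dnds_nonptm",
            "r_dnds",
        ],
    )


def summarize_rdnds(records: pd.DataFrame) -> dict:
    """Central summaries of per-gene r^dN/dS.

    The headline average is the geometric mean: r is a ratio of count
    ratios, symmetric under label exchange (r vs 1/r), so the log-scale
    mean is the appropriate central summary; the arithmetic mean of a
    small-count ratio-of-ratios is systematically inflated.
    """
    r = records["r_dnds"].to_numpy(dtype=float)
    r = r[np.isfinite(r) & (r > 0)]
    if len(r) == 0:
        return {"n_genes": 0, "geometric_mean": float("nan"),
                "median": float("nan")}
    return {
        "n_genes": int(len(r)),
        "geometric_mean": float(np.exp(np.mean(np.log(r)))),
        "median": float(np.median(r)),
    }


def compare_rdnds(
    records: pd.DataFrame,
    matrisome_genes: set,
    alpha: float = 0.05,
) -> dict:
    """Two-sided Mann-Whitney U of matrisome vs rest per-gene r^dN/dS."""
    in_m = records["gene_symbol"].isin(matrisome_genes)
    r_m = records.loc[in_m, "r_dnds"].dropna()
    r_r = records.loc[~in_m, "r_dnds"].dropna()
    if len(r_m) < 2 or len(r_r) < 2:
        log.warning("compare_rdnds: fewer than 2 defined r values in a set; skipped")
        return {"n_matrisome": len(r_m), "n_rest": len(r_r),
                "median_matrisome": float("nan"), "median_rest": float("nan"),
                "u_stat": float("nan"), "p_value": float("nan"),
                "significant": False}
    stat, p = stats.mannwhitneyu(r_m, r_r, alternative="two-sided")
    return {
        "n_matrisome": int(len(r_m)),
        "n_rest": int(len(r_r)),
        "median_matrisome": float(r_m.median()),
        "median_rest": float(r_r.median()),
        "u_stat": float(stat),
        "p_value": float(p),
        "significant": bool(p < alpha),
    }


def find_hotspots(
    annotated: pd.DataFrame,
    min_cohorts: int = 3,
    by_ptm_type: bool = True,
) -> pd.DataFrame:
    """PTM^mut recurrent across at least ``min_cohorts`` distinct cohorts.

    Groups PTM^mut by (gene, position, PTM type) — or by position only
    with ``by_ptm_type=False`` — and keeps groups observed in at least
    ``min_cohorts`` distinct cancer types, sorted by cohort count
    (descending) then gene and position.
    """
    from ptmburden.burden import _exploded_hits

    hits = _exploded_hits(annotated)
    cols = ["gene", "position"] + (["ptm_type"] if by_ptm_type else [])
    if hits.empty:
        return pd.DataFrame(
            columns=cols + ["n_cohorts", "cohorts", "n_samples"]
        )
    grouped = hits.groupby(cols).agg(
        n_cohorts=("cancer", "nunique"),
        cohorts=("cancer", lambda c: ",".join(sorted(set(c)))),
        n_samples=("sample", "nunique"),
    )
    out = grouped[grouped["n_cohorts"] >= min_cohorts].reset_index()
    return out.sort_values(
        ["n_cohorts", "gene", "position"],
        ascending=[False, True, True],
        ignore_index=True,
    )


def residue_composition(annotated: pd.DataFrame, ptm_only: bool = True) -> pd.DataFrame:
    """Reference-residue tally over PTM^mut (or all mutations)."""
    sub = annotated[annotated["is_ptm_mut"]] if ptm_only else annotated
    if sub.empty:
        return pd.DataFrame(columns=["residue", "count", "percent"])
    residues = sub["ref_aa"].where(sub["ref_aa"].isin(set(AMINO_ACIDS)), "unknown")
    counts = residues.value_counts()
    out = counts.rename_axis("residue").reset_index(name="count")
    out["percent"] = 100.0 * out["count"] / out["count"].sum()
    return out
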