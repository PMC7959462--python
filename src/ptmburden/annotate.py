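"""Mutation classification: transition/transversion and PTM^mut calling.

A non-silent mutation is a PTM^mut iff its residue footprint (1-based,
inclusive on both ends) contains at least one annotated PTM position of
the same protein.  Footprints follow UniProt convention:

* SNVs (missense, nonsense, splice-site, other non-silent) — the single
  reported residue;
* in-frame indels — the reported [start, end] span;
* frameshifts — the start residue only (downstream loss is not counted
  as PTM disruption, which would otherwise dominate the tallies).

Silent mutations are never PTM^mut.
"""

from __future__ import annotations

import pandas as pd

from ptmburden.constants import TRANSITION_PAIRS


def classify_titv(ref: str, alt: str, variant_kind: str = "SNP") -> str:
    """Classify one substitution as transition / transversion / not_applicable."""
    if variant_kind != "SNP":
        return "not_applicable"
    return "transition" if (ref, alt) in TRANSITION_PAIRS else "transversion"


def add_titv(muts: pd.DataFrame) -> pd.Series:
    """Vectorized Ti/Tv classification for a mutation table."""
    snp = muts["variant_kind"] == "SNP"
    transition = [
        (r, a) in TRANSITION_PAIRS for r, a in zip(muts["ref"], muts["alt"])
    ]
    out = pd.Series("not_applicable", index=muts.index, dtype=object)
    out[snp] = pd.Series(transition, index=muts.index)[snp].map(
        {True: "transition", False: "transversion"}
    )
    return out


def footprint(muts: pd.DataFrame) -> pd.DataFrame:
    """Residue footprint [f_start, f_end] per mutation (see module docs)."""
    f_start = muts["aa_start"]
    f_end = f_start.where(muts["effect"] != "inframe_indel", muts["aa_end"])
    return pd.DataFrame({"f_start": f_start, "f_end": f_end}, index=muts.index)


def call_ptm_mut(muts: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Annotate each mutation with its PTM-site overlaps.

    Returns a copy of ``muts`` with columns ``titv``, ``f_start``,
    ``f_end``, ``is_ptm_mut`` and ``hit_sites`` (sorted list of
    ``(position, ptm_type)`` tuples; empty when not a PTM^mut).  A
    mutation on a protein absent from the site table simply gets
    ``is_ptm_mut=False``.
    """
    out = muts.copy()
    out["titv"] = add_titv(out)
    fp = footprint(out)
    out["f_start"] = fp["f_start"]
    out["f_end"] = fp["f_end"]

    hits: dict[int, list[tuple[int, str]]] = {}
    if len(out) and len(sites):
        nonsilent = out[out["effect"] != "silent"]
        merged = nonsilent.reset_index()[
            ["index", "protein_id", "f_start", "f_end"]
        ].merge(
            sites[["protein_id", "position", "ptm_type"]], on="protein_id", how="inner"
        )
        merged = merged[
            (merged["position"] >= merged["f_start"])
            & (merged["position"] <= merged["f_end"])
        ]
        for idx, grp in merged.groupby("index"):
            hits[idx] = sorted(zip(grp["position"], grp["ptm_type"]))

    out["hit_sites"] = [hits.get(i, []) for i in out.index]
    out["is_ptm_mut"] = [len(h) > 0 for h in out["hit_sites"]]
    return out


def mutation_classes(annotated: pd.DataFrame) -> pd.Series:
    """Exhaustive, disjoint partition: ptm_mut / non_ptm_nonsilent / silent."""
    cls = pd.Series("non_ptm_nonsilent", index=annotated.index, dtype=object)
    cls[annotated["effect"] == "silent"] = "silent"
    cls[annotated["is_ptm_mut"]] = "ptm_mut"
    return cls
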