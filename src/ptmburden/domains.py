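"""Domain, functional-region, motif and sequence-context analysis.

Mutations are assigned to Pfam-style domain instances by footprint
overlap; a domain's counts pool all of its instances across the proteins
of a gene set.  The domain-specific PTM^mut ratio is the count of
PTM^mut divided by the count of non-PTM non-silent mutations inside the
domain, compared matrisome vs rest; domains whose ratio differs by at
least the fold threshold (default 2x, either direction) are called
differential.

Motif scanning reports occurrences of short ECM interaction motifs
(GPP, GVD, RGD, LDV, GFPGER, GLPGER by default) whose span intersects a
±window interval around the mutated residue (default ±3).  Sequence
context extraction fetches ±10 residues and the physico-chemical
property profile of each aligned offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ptmburden.constants import DEFAULT_MOTIFS, RESIDUE_TO_PROPERTY


def domain_ratios(
    annotated: pd.DataFrame,
    domains: pd.DataFrame,
    catalog: pd.DataFrame,
) -> pd.DataFrame:
    """Per (domain, gene set) PTM^mut / non-PTM^mut counts and ratio.

    A mutation falling in overlapping instances of the same domain
    counts once per domain; the ratio is missing when a domain has no
    non-PTM mutations in a gene set.  The per-domain matrisome-vs-rest
    fold is defined only when both ratios are defined and rest > 0.
    """
    is_matrisome = dict(zip(catalog["protein_id"], catalog["is_matrisome"]))
    nonsilent = annotated[annotated["effect"] != "silent"]
    merged = nonsilent.reset_index()[
        ["index", "protein_id", "f_start", "f_end", "is_ptm_mut"]
    ].merge(domains, on="protein_id", how="inner")
    merged = merged[
        (merged["f_start"] <= merged["end"]) & (merged["f_end"] >= merged["start"])
    ]
    # one count per (mutation, domain) even with overlapping instances
    merged = merged.drop_duplicates(subset=["index", "domain_id"])
    merged["gene_set"] = merged["protein_id"].map(is_matrisome).map(
        {True: "matrisome", False: "rest"}
    )
    counts = (
        merged.groupby(["domain_id", "gene_set"])
        .agg(
            n_ptm_mut=("is_ptm_mut", "sum"),
            n_total=("is_ptm_mut", "size"),
        )
        .reset_index()
    )
    counts["n_non_ptm_mut"] = counts["n_total"] - counts["n_ptm_mut"]
    counts["ratio"] = np.where(
        counts["n_non_ptm_mut"] > 0,
        counts["n_ptm_mut"] / counts["n_non_ptm_mut"],
        np.nan,
    )
    counts = counts.drop(columns="n_total")

    wide = counts.pivot(index="domain_id", columns="gene_set", values="ratio")
    for col in ("matrisome", "rest"):
        if col not in wide:
            wide[col] = np.nan
    fold = np.where(
        np.isfinite(wide["matrisome"]) & np.isfinite(wide["rest"]) & (wide["rest"] > 0),
        wide["matrisome"] / wide["rest"],
        np.nan,
    )
    counts["fold_matrisome_vs_rest"] = counts["domain_id"].map(
        dict(zip(wide.index, fold))
    )
    return counts.sort_values(["domain_id", "gene_set"], ignore_index=True)


def differential_domains(records: pd.DataFrame, fold: float = 2.0) -> list[str]:
    """Domains whose matrisome and rest ratios differ by >= ``fold`` (either
    direction).  Domains with an undefined ratio in either set, or present
    in only one set, are excluded."""
    wide = records.pivot(index="domain_id", columns="gene_set", values="ratio")
    if "matrisome" not in wide or "rest" not in wide:
        return []
    m, r = wide["matrisome"], wide["rest"]
    defined = np.isfinite(m) & np.isfinite(r)
    different = m != r
    hit = defined & different & ((m >= fold * r) | (r >= fold * m))
    return sorted(wide.index[hit])


def region_overlap(
    annotated: pd.DataFrame, regions: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Flag PTM^mut overlapping annotated functional regions.

    Mutations on proteins with no region annotation at all form a
    separate 'no information' stratum excluded from the denominator of
    the summary fraction.
    """
    ptm = annotated[annotated["is_ptm_mut"]].copy()
    annotated_proteins = set(regions["protein_id"])
    ptm["has_info"] = ptm["protein_id"].isin(annotated_proteins)

    flagged = set()
    if not ptm.empty and not regions.empty:
        merged = ptm.reset_index()[["index", "protein_id", "f_start", "f_end"]].merge(
            regions, on="protein_id", how="inner"
        )
        merged = merged[
            (merged["f_start"] <= merged["end"]) & (merged["f_end"] >= merged["start"])
        ]
        flagged = set(merged["index"])
    ptm["in_region"] = [i in flagged for i in ptm.index]

    n_info = int(ptm["has_info"].sum())
    n_overlap = int(ptm["in_region"].sum())
    summary = {
        "n_ptm_mut": int(len(ptm)),
        "n_with_info": n_info,
        "n_no_info": int(len(ptm) - n_info),
        "n_in_region": n_overlap,
        "fraction_in_region": 100.0 * n_overlap / n_info if n_info else float("nan"),
    }
    return ptm, summary


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based position of the motif occurrence
    distance: int  # residues between the mutated position and the motif span


def motif_scan(
    sequence: str,
    position: int,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    window: int = 3,
) -> list[MotifHit]:
    """All motif occurrences whose span lies within ``window`` residues of
    the mutated position (span intersection with [position-window,
    position+window]; case-insensitive exact match)."""
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    seq = sequence.upper()
    lo, hi = position - window, position + window
    hits = []
    for motif in motifs:
        m = motif.upper()
        start = seq.find(m)
        while start != -1:
            s, e = start + 1, start + len(m)  # 1-based inclusive span
            if s <= hi and e >= lo:
                distance = max(s - position, position - e, 0)
                hits.append(MotifHit(motif=motif, start=s, distance=distance))
            start = seq.find(m, start + 1)
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def extract_context(
    sequence: str, position: int, flank: int = 10
) -> tuple[str, int]:
    """±``flank`` residues around the mutated position (clipped at the
    termini) and the 1-based offset of the mutated residue within the
    returned window."""
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    lo = max(1, position - flank)
    hi = min(len(sequence), position + flank)
    return sequence[lo - 1 : hi], position - lo + 1


def residue_property(aa: str) -> str:
    """Physico-chemical class of a residue: polar (S,T,N,Q,Y,C),
    hydrophobic (A,V,L,I,M,F,W), acidic (D,E), basic (K,R,H) or
    special (G,P); anything else is 'unknown'."""
    return RESIDUE_TO_PROPERTY.get(aa.upper(), "unknown")


def context_property_profile(
    contexts: list[tuple[str, int]], flank: int = 10
) -> pd.DataFrame:
    """Per-offset residue-property frequency table over aligned contexts.

    ``contexts`` is a list of (window, offset) pairs as returned by
    :func:`extract_context`.  Rows are relative offsets (-flank..+flank,
    0 = mutated residue); percentages sum to 100 within each offset.
    """
    tallies: dict[int, dict[str, int]] = {}
    for window, offset in contexts:
        for i, aa in enumerate(window, start=1):
            rel = i - offset
            if abs(rel) > flank:
                continue
            prop = residue_property(aa)
            tallies.setdefault(rel, {}).setdefault(prop, 0)
            tallies[rel][prop] += 1
    rows = []
    for rel in sorted(tallies):
        total = sum(tallies[rel].values())
        for prop, n in sorted(tallies[rel].items()):
            rows.append(
                {
                    "offset": rel,
                    "property": prop,
                    "count": n,
                    "percent": 100.0 * n / total,
                }
            )
    return pd.DataFrame(rows, columns=["offset", "property", "count", "percent"])
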