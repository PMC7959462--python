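"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive double/triple loops over plain Python
rows so they share no code path with the vectorized implementations they
check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ptmburden as pb
from ptmburden.config import SimulationConfig

# ---------------------------------------------------------------- builders


def make_mut(
    sample="S1",
    cancer="C01",
    gene="GENE1",
    protein_id="PROT1",
    aa_start=1,
    aa_end=None,
    effect="missense",
    variant_kind="SNP",
    ref="A",
    alt="G",
    ref_aa="S",
    sift="unknown",
    polyphen="unknown",
):
    return {
        "sample": sample,
        "cancer": cancer,
        "gene": gene,
        "protein_id": protein_id,
        "aa_start": aa_start,
        "aa_end": aa_end if aa_end is not None else aa_start,
        "effect": effect,
        "variant_kind": variant_kind,
        "ref": ref,
        "alt": alt,
        "ref_aa": ref_aa,
        "sift": sift,
        "polyphen": polyphen,
    }


def mut_table(rows):
    if not rows:
        return pd.DataFrame(columns=list(make_mut()))
    return pd.DataFrame([make_mut(**r) if isinstance(r, dict) else r for r in rows])


def site_table(rows):
    """rows: (protein_id, position, ptm_type[, residue])"""
    recs = []
    for r in rows:
        protein_id, position, ptm_type = r[:3]
        residue = r[3] if len(r) > 3 else "S"
        recs.append(
            {
                "protein_id": protein_id,
                "position": position,
                "ptm_type": ptm_type,
                "residue": residue,
            }
        )
    return pd.DataFrame(
        recs, columns=["protein_id", "position", "ptm_type", "residue"]
    )


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_genes=40,
        matrisome_fraction=0.3,
        n_cancers=3,
        samples_per_cancer=10,
        mutation_rate=20.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    catalog = pb.generate_gene_catalog(small_cfg)
    annotations = pb.generate_annotations(catalog, small_cfg)
    mutations = pb.simulate_cohort(catalog, annotations, small_cfg)
    annotated = pb.call_ptm_mut(mutations, annotations.ptm_sites)
    return {
        "config": small_cfg,
        "catalog": catalog,
        "annotations": annotations,
        "mutations": mutations,
        "annotated": annotated,
    }


# ---------------------------------------------------------------- oracles


def footprint_of(row) -> tuple[int, int]:
    if row["effect"] == "inframe_indel":
        return int(row["aa_start"]), int(row["aa_end"])
    return int(row["aa_start"]), int(row["aa_start"])


def oracle_ptm_calls(muts: pd.DataFrame, sites: pd.DataFrame):
    """Naive O(n*m) double loop: list of sorted hit lists, one per mutation."""
    site_rows = sites.to_dict("records")
    out = []
    for _, m in muts.iterrows():
        hits = []
        if m["effect"] != "silent":
            lo, hi = footprint_of(m)
            for s in site_rows:
                if s["protein_id"] == m["protein_id"] and lo <= s["position"] <= hi:
                    hits.append((s["position"], s["ptm_type"]))
        out.append(sorted(hits))
    return out


def oracle_local_burdens(annotated: pd.DataFrame, sites: pd.DataFrame, cancers):
    """Per-(protein, type, cancer) recount of distinct hit sites."""
    known = {}
    for _, s in sites.iterrows():
        known.setdefault((s["protein_id"], s["ptm_type"]), set()).add(s["position"])
    hit = {}
    for _, m in annotated.iterrows():
        if not m["is_ptm_mut"]:
            continue
        for pos, t in m["hit_sites"]:
            hit.setdefault((m["protein_id"], t, m["cancer"]), set()).add(pos)
    rows = []
    for (pid, t), positions in known.items():
        for cancer in cancers:
            h = len(hit.get((pid, t, cancer), set()))
            rows.append(
                {
                    "protein_id": pid,
                    "ptm_type": t,
                    "cancer": cancer,
                    "n_sites_known": len(positions),
                    "n_sites_hit": h,
                    "local_burden": 100.0 * h / len(positions),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["protein_id", "ptm_type", "cancer"], ignore_index=True)
    )


def oracle_domain_counts(annotated: pd.DataFrame, domains: pd.DataFrame, catalog):
    """Triple loop over mutations x domain instances, one count per domain."""
    is_m = dict(zip(catalog["protein_id"], catalog["is_matrisome"]))
    counts = {}
    for idx, m in annotated.iterrows():
        if m["effect"] == "silent":
            continue
        lo, hi = footprint_of(m)
        seen_domains = set()
        for _, d in domains.iterrows():
            if d["protein_id"] != m["protein_id"]:
                continue
            if lo <= d["end"] and hi >= d["start"] and d["domain_id"] not in seen_domains:
                seen_domains.add(d["domain_id"])
                gs = "matrisome" if is_m[m["protein_id"]] else "rest"
                key = (d["domain_id"], gs)
                a, b = counts.get(key, (0, 0))
                if m["is_ptm_mut"]:
                    counts[key] = (a + 1, b)
                else:
                    counts[key] = (a, b + 1)
    return counts


def oracle_motif_scan(sequence: str, position: int, motifs, window: int):
    """Exhaustive substring scan."""
    seq = sequence.upper()
    hits = []
    for start in range(len(seq)):
        for motif in motifs:
            m = motif.upper()
            if seq[start : start + len(m)] == m:
                s, e = start + 1, start + len(m)
                if s <= position + window and e >= position - window:
                    hits.append((motif, s))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def oracle_cooccurrence(annotated: pd.DataFrame, interactions: pd.DataFrame):
    """Triple loop over samples x gene pairs x edges."""
    edges = set()
    for _, e in interactions.iterrows():
        if e["gene_a"] != e["gene_b"]:
            edges.add((min(e["gene_a"], e["gene_b"]), max(e["gene_a"], e["gene_b"])))
    by_sample = {}
    for _, m in annotated.iterrows():
        if m["is_ptm_mut"]:
            by_sample.setdefault(m["sample"], set()).add(m["gene"])
    rows = []
    for sample in sorted(by_sample):
        genes = sorted(by_sample[sample])
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if (a, b) in edges:
                    rows.append((sample, a, b))
    return rows


def random_fixture(seed: int, n_mut: int = 300):
    """A random small cohort for oracle-equivalence sweeps."""
    cfg = SimulationConfig(
        n_genes=15,
        matrisome_fraction=0.4,
        n_cancers=3,
        samples_per_cancer=5,
        mutation_rate=n_mut / 15.0,
        sites_per_100aa=15.0,
        mean_protein_length=200.0,
        seed=seed,
    )
    catalog = pb.generate_gene_catalog(cfg)
    annotations = pb.generate_annotations(catalog, cfg)
    mutations = pb.simulate_cohort(catalog, annotations, cfg)
    return cfg, catalog, annotations, mutations
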