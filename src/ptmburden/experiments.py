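"""Reproducibility experiments: worked-example arithmetic and simulation-based
parameter recovery.

Two kinds of quantities live here.  First, the headline ratios of the
TCGA MC3 pan-cancer matrisome analysis, recomputed from the published
raw counts (the counts are inputs; every percentage is computed at run
time via :func:`ptmburden.burden.share_ratio`).  Second, desk-scale
generative experiments that verify the pipeline recovers the structure
the generator encodes: neutral cohorts should show r^dN/dS near 1 and
vanishing burden folds, selected cohorts should show depressed matrisome
r^dN/dS and PTM^mut counts, and injected hotspots should be recovered
exactly on a low-background cohort.
"""

from __future__ import annotations

import numpy as np

import ptmburden as pb
from ptmburden import burden as bd
from ptmburden import selection as sel
from ptmburden.config import HotspotSpec, SimulationConfig, child_seed

# Raw counts of the TCGA MC3 pan-cancer matrisome analysis (inputs for
# the worked-example arithmetic below).
PAN_CANCER_COUNTS = {
    "nonsilent_total": 2_277_979,
    "nonsilent_matrisome": 151_088,
    "ptm_mut_total": 42_733,
    "ptm_mut_matrisome": 1_811,
    "genes_total": 21_255,
    "genes_matrisome": 1_027,
    "domains_total": 3_373,
    "domains_differential": 128,
    "ptm_mut_with_region_info": 921,
    "ptm_mut_in_region": 286,
    "genes_in_differential_domains": 437,
    "genes_interacting": 230,
    "collagen_ptm_mut_in_regions": 156,
    "collagen_ptm_mut_triple_helix": 124,
    "hotspots_total": 19,
    "hotspots_phospho": 16,
    "interacting_genes_functional": 39,
}


def printed_ratios(counts: dict | None = None) -> dict[str, dict]:
    """Recompute the worked-example percentages and per-gene means from
    raw counts.  Returns {name: {"value": ..., "n": ...}}."""
    c = dict(PAN_CANCER_COUNTS if counts is None else counts)
    rest_nonsilent = c["nonsilent_total"] - c["nonsilent_matrisome"]
    rest_genes = c["genes_total"] - c["genes_matrisome"]
    rest_ptm = c["ptm_mut_total"] - c["ptm_mut_matrisome"]

    def entry(value, n):
        return {"value": float(value), "n": int(n)}

    return {
        "matrisome_share_percent": entry(
            bd.share_ratio(c["nonsilent_matrisome"], c["nonsilent_total"]),
            c["nonsilent_total"],
        ),
        "mean_mutations_per_matrisome_gene": entry(
            c["nonsilent_matrisome"] / c["genes_matrisome"], c["genes_matrisome"]
        ),
        "mean_mutations_per_rest_gene": entry(
            rest_nonsilent / rest_genes, rest_genes
        ),
        "ptm_mut_share_percent": entry(
            bd.share_ratio(c["ptm_mut_total"], c["nonsilent_total"]),
            c["nonsilent_total"],
        ),
        "matrisome_ptm_ratio_percent": entry(
            bd.share_ratio(c["ptm_mut_matrisome"], c["nonsilent_matrisome"]),
            c["nonsilent_matrisome"],
        ),
        "rest_ptm_ratio_percent": entry(
            bd.share_ratio(rest_ptm, rest_nonsilent), rest_nonsilent
        ),
        "differential_domain_percent": entry(
            bd.share_ratio(c["domains_differential"], c["domains_total"]),
            c["domains_total"],
        ),
        "region_overlap_percent": entry(
            bd.share_ratio(c["ptm_mut_in_region"], c["ptm_mut_with_region_info"]),
            c["ptm_mut_with_region_info"],
        ),
        "interacting_gene_percent": entry(
            bd.share_ratio(
                c["genes_interacting"], c["genes_in_differential_domains"]
            ),
            c["genes_in_differential_domains"],
        ),
        "collagen_triple_helix_percent": entry(
            bd.share_ratio(
                c["collagen_ptm_mut_triple_helix"], c["collagen_ptm_mut_in_regions"]
            ),
            c["collagen_ptm_mut_in_regions"],
        ),
        "hotspot_phospho_percent": entry(
            bd.share_ratio(c["hotspots_phospho"], c["hotspots_total"]),
            c["hotspots_total"],
        ),
        "functional_interacting_percent": entry(
            bd.share_ratio(
                c["interacting_genes_functional"], c["genes_interacting"]
            ),
            c["genes_interacting"],
        ),
    }


def _simulate_annotated(cfg: SimulationConfig):
    catalog = pb.generate_gene_catalog(cfg)
    anns = pb.generate_annotations(catalog, cfg)
    muts = pb.simulate_cohort(catalog, anns, cfg)
    annotated = pb.call_ptm_mut(muts, anns.ptm_sites)
    return catalog, anns, annotated


def neutral_recovery(seed: int, n_replicates: int = 20) -> dict:
    """Neutral cohorts (s=0, uniform PTM densities): per-replicate
    geometric-mean r^dN/dS and per-type burden folds for PTM types with
    at least 200 observed distinct-site hits."""
    mean_r = []
    folds: dict[str, list[float]] = {}
    for rep in range(n_replicates):
        cfg = SimulationConfig.neutral(seed=child_seed(seed, 100 + rep))
        catalog, anns, annotated = _simulate_annotated(cfg)
        records = sel.rdnds_table(annotated, anns.ptm_sites)
        mean_r.append(sel.summarize_rdnds(records)["geometric_mean"])

        local = bd.local_burdens(annotated, anns.ptm_sites)
        gb = bd.global_burden(local, bd.gene_sets_from_catalog(catalog))
        hits_per_type = local.groupby("ptm_type")["n_sites_hit"].sum()
        for row in gb.itertuples():
            if row.gene_set != "matrisome":
                continue
            if hits_per_type.get(row.ptm_type, 0) < 200:
                continue
            folds.setdefault(row.ptm_type, []).append(row.fold_vs_rest)
    fold_means = {t: float(np.mean(v)) for t, v in folds.items()}
    return {
        "mean_rdnds_per_replicate": [float(x) for x in mean_r],
        "mean_rdnds": float(np.mean(mean_r)),
        "burden_fold_by_type": fold_means,
        "max_abs_burden_fold": (
            max(abs(v) for v in fold_means.values()) if fold_means else float("nan")
        ),
        "n_replicates": n_replicates,
    }


def selected_recovery(seed: int, n_replicates: int = 20, s: float = 0.8) -> dict:
    """Selected cohorts (rejection probability ``s`` against non-silent
    mutations at matrisome PTM sites): median matrisome-vs-rest r^dN/dS
    per replicate and the 100-random-set burden control."""
    wins = 0
    control_sig = []
    medians_m, medians_r = [], []
    for rep in range(n_replicates):
        cfg = SimulationConfig.selected(s=s, seed=child_seed(seed, 200 + rep))
        catalog, anns, annotated = _simulate_annotated(cfg)
        records = sel.rdnds_table(annotated, anns.ptm_sites)
        matrisome = set(catalog.loc[catalog["is_matrisome"], "gene_symbol"])
        cmp = sel.compare_rdnds(records, matrisome)
        medians_m.append(cmp["median_matrisome"])
        medians_r.append(cmp["median_rest"])
        if cmp["median_matrisome"] < cmp["median_rest"]:
            wins += 1

        control = bd.random_set_control(
            annotated, catalog, n_draws=100, seed=child_seed(seed, 300 + rep)
        )
        valid = control[control["valid"]]
        sig = (
            (valid["p_value"] < 0.05)
            & (valid["matrisome_rate"] < valid["random_rate"])
        ).mean()
        control_sig.append(float(sig))
    return {
        "n_replicates": n_replicates,
        "median_matrisome": [float(x) for x in medians_m],
        "median_rest": [float(x) for x in medians_r],
        "replicates_matrisome_lower": int(wins),
        "control_fraction_significant": [float(x) for x in control_sig],
        "mean_control_fraction_significant": float(np.mean(control_sig)),
    }


def hotspot_detection(seed: int) -> dict:
    """Recall/precision of injected >=3-cohort hotspots on a cohort whose
    background per-site hit probability is far below 1e-3 per cohort."""
    hotspots = (
        HotspotSpec("G0005", 10, "phosphorylation", ("C01", "C02", "C03")),
        HotspotSpec("G0012", 40, "n_glycosylation", ("C01", "C03", "C04", "C05")),
        HotspotSpec("G0033", 25, "acetylation", ("C02", "C03", "C05")),
        HotspotSpec("G0033", 25, "ubiquitylation", ("C02", "C03", "C05")),
        HotspotSpec("G0090", 7, "phosphorylation", ("C01", "C02", "C04")),
    )
    cfg = SimulationConfig(
        n_genes=100,
        matrisome_fraction=0.25,
        n_cancers=5,
        samples_per_cancer=10,
        mutation_rate=2.0,
        hotspot_specs=hotspots,
        seed=child_seed(seed, 400),
    )
    catalog, anns, annotated = _simulate_annotated(cfg)
    found = pb.find_hotspots(annotated, min_cohorts=3)
    found_keys = set(zip(found["gene"], found["position"], found["ptm_type"]))
    # an injected mutation disrupts every PTM type annotated at its
    # residue, so the expected records enumerate all co-located types
    pid_of = dict(zip(catalog["gene_symbol"], catalog["protein_id"]))
    sites = anns.ptm_sites
    true_keys = set()
    for h in hotspots:
        at_pos = sites[
            (sites["protein_id"] == pid_of[h.gene])
            & (sites["position"] == h.position)
        ]
        for t in at_pos["ptm_type"]:
            true_keys.add((h.gene, h.position, t))
    tp = len(found_keys & true_keys)
    recall = 100.0 * tp / len(true_keys)
    precision = 100.0 * tp / len(found_keys) if found_keys else float("nan")
    return {
        "n_injected": len(true_keys),
        "n_found": len(found_keys),
        "recall_percent": recall,
        "precision_percent": precision,
    }
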