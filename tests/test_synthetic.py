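"""Generator contracts: determinism, composition, placement chemistry,
selection behavior and hotspot injection."""

import numpy as np
import pandas as pd
import pytest

import ptmburden as pb
from ptmburden.config import ConfigError, HotspotSpec, SimulationConfig
from ptmburden.constants import PTM_VALID_RESIDUES


def test_matrisome_count_follows_rounded_fraction():
    cfg = SimulationConfig(n_genes=100, matrisome_fraction=0.05, seed=1)
    cat = pb.generate_gene_catalog(cfg)
    assert cat["is_matrisome"].sum() == 5

    # genome-like proportion: 1027/21255 ~ 4.8%
    cfg = SimulationConfig(n_genes=1000, matrisome_fraction=0.048, seed=1)
    cat = pb.generate_gene_catalog(cfg)
    assert cat["is_matrisome"].sum() == 48


def test_catalog_invariants_and_determinism():
    cfg = SimulationConfig(n_genes=120, seed=3)
    a = pb.generate_gene_catalog(cfg)
    b = pb.generate_gene_catalog(cfg)
    pd.testing.assert_frame_equal(a, b)

    assert a["gene_symbol"].is_unique
    assert (a["protein_length"] >= 1).all()
    assert (a["gene_length"] >= 3 * a["protein_length"]).all()
    # division consistent with category and matrisome flag
    assert ((a["division"] == "none") == ~a["is_matrisome"]).all()
    core = a["category"].isin(["collagens", "ecm_glycoproteins", "proteoglycans"])
    assert (a.loc[core, "division"] == "core_matrisome").all()


def test_invalid_fractions_rejected():
    with pytest.raises(ConfigError, match="matrisome_fraction"):
        SimulationConfig(matrisome_fraction=1.5)
    with pytest.raises(ConfigError, match="n_genes"):
        SimulationConfig(n_genes=5)


def test_sites_on_chemically_valid_residues(small_bundle):
    anns = small_bundle["annotations"]
    cat = small_bundle["catalog"]
    seqs = anns.sequences
    for row in anns.ptm_sites.itertuples():
        residue = seqs[row.protein_id][row.position - 1]
        assert residue in PTM_VALID_RESIDUES[row.ptm_type]
        assert residue == row.residue

    # hydroxylation exists only on collagen-category proteins
    collagens = set(cat.loc[cat["category"] == "collagens", "protein_id"])
    hydroxy = anns.ptm_sites[anns.ptm_sites["ptm_type"] == "hydroxylation"]
    assert set(hydroxy["protein_id"]) <= collagens


def test_annotation_intervals_within_protein(small_bundle):
    anns = small_bundle["annotations"]
    lengths = {p: len(s) for p, s in anns.sequences.items()}
    for df in (anns.domains, anns.regions):
        for row in df.itertuples():
            assert 1 <= row.start <= row.end <= lengths[row.protein_id]
    for row in anns.ptm_sites.itertuples():
        assert 1 <= row.position <= lengths[row.protein_id]


def test_cohort_determinism(small_cfg, small_bundle):
    muts2 = pb.simulate_cohort(
        small_bundle["catalog"], small_bundle["annotations"], small_cfg
    )
    pd.testing.assert_frame_equal(small_bundle["mutations"], muts2)


def test_bundle_files_byte_identical(tmp_path, small_cfg, small_bundle):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        pb.write_bundle(
            d,
            small_bundle["catalog"],
            small_bundle["annotations"],
            small_bundle["mutations"],
        )
    for f in sorted(d1.iterdir()):
        assert f.read_bytes() == (d2 / f.name).read_bytes()


def test_titv_and_silent_fractions_match_config():
    cfg = SimulationConfig(
        n_genes=50, n_cancers=2, samples_per_cancer=50, mutation_rate=150.0,
        titv_ratio=3.0, silent_fraction=0.4, seed=11,
    )
    cat = pb.generate_gene_catalog(cfg)
    anns = pb.generate_annotations(cat, cfg)
    muts = pb.simulate_cohort(cat, anns, cfg)
    assert len(muts) >= 10_000

    snv = muts[muts["variant_kind"] == "SNP"]
    ti = pb.classify_titv
    is_ti = np.array([ti(r, a) == "transition" for r, a in zip(snv["ref"], snv["alt"])])
    p = cfg.titv_ratio / (cfg.titv_ratio + 1)
    se = np.sqrt(p * (1 - p) / len(snv))
    assert abs(is_ti.mean() - p) < 3 * se

    sf = (muts["effect"] == "silent").mean()
    se = np.sqrt(cfg.silent_fraction * (1 - cfg.silent_fraction) / len(muts))
    assert abs(sf - cfg.silent_fraction) < 3 * se


def test_neutral_ptm_hit_fraction_matches_site_share():
    """With s=0 the fraction of mutations landing on PTM positions should
    match the enumerated share of annotated positions (length-weighted),
    within binomial error."""
    cfg = SimulationConfig(
        n_genes=30, n_cancers=2, samples_per_cancer=40, mutation_rate=130.0,
        ptm_selection_s=0.0, seed=5,
    )
    cat = pb.generate_gene_catalog(cfg)
    anns = pb.generate_annotations(cat, cfg)
    muts = pb.simulate_cohort(cat, anns, cfg)
    assert len(muts) >= 10_000

    # exact expectation by enumerating annotated positions per gene,
    # weighted by the length-proportional gene draw probability
    lengths = dict(zip(cat["protein_id"], cat["protein_length"]))
    glen = dict(zip(cat["protein_id"], cat["gene_length"]))
    total_glen = sum(glen.values())
    sites_per_protein = anns.ptm_sites.groupby("protein_id")["position"].nunique()
    expected = sum(
        (glen[p] / total_glen) * (sites_per_protein.get(p, 0) / lengths[p])
        for p in lengths
    )
    on_site = np.array(
        [
            (p, q)
            in set(zip(anns.ptm_sites["protein_id"], anns.ptm_sites["position"]))
            for p, q in zip(muts["protein_id"], muts["aa_start"])
        ]
    )
    se = np.sqrt(expected * (1 - expected) / len(muts))
    assert abs(on_site.mean() - expected) < 4 * se


def test_total_rejection_leaves_no_uninjected_ptm_mut():
    cfg = SimulationConfig(
        n_genes=20, n_cancers=2, samples_per_cancer=10, mutation_rate=30.0,
        ptm_selection_s=1.0, seed=2,
    )
    cat = pb.generate_gene_catalog(cfg)
    anns = pb.generate_annotations(cat, cfg)
    muts = pb.simulate_cohort(cat, anns, cfg)
    annotated = pb.call_ptm_mut(muts, anns.ptm_sites)
    assert annotated["is_ptm_mut"].sum() == 0


def test_selection_monotonically_depresses_ptm_mut_counts():
    """Mean realized PTM^mut count is non-increasing in s over replicates."""
    means = []
    for s in (0.0, 0.5, 0.9):
        counts = []
        for seed in range(8):
            cfg = SimulationConfig(
                n_genes=20, n_cancers=2, samples_per_cancer=10,
                mutation_rate=30.0, ptm_selection_s=s, seed=100 + seed,
            )
            cat = pb.generate_gene_catalog(cfg)
            anns = pb.generate_annotations(cat, cfg)
            muts = pb.simulate_cohort(cat, anns, cfg)
            annotated = pb.call_ptm_mut(muts, anns.ptm_sites)
            counts.append(int(annotated["is_ptm_mut"].sum()))
        means.append(np.mean(counts))
    assert means[0] > means[1] > means[2]


def test_hotspot_injection_contract():
    hotspots = (
        HotspotSpec("G0003", 10, "phosphorylation", ("C01", "C02", "C03")),
    )
    cfg = SimulationConfig(
        n_genes=20, n_cancers=3, samples_per_cancer=5, mutation_rate=5.0,
        ptm_selection_s=1.0, hotspot_specs=hotspots, seed=4,
    )
    cat = pb.generate_gene_catalog(cfg)
    anns = pb.generate_annotations(cat, cfg)
    muts = pb.simulate_cohort(cat, anns, cfg)
    for cancer in ("C01", "C02", "C03"):
        hit = muts[
            (muts["cancer"] == cancer)
            & (muts["gene"] == "G0003")
            & (muts["aa_start"] == 10)
            & (muts["effect"] == "missense")
        ]
        assert len(hit) >= 1
    # the injected site is annotated, so the mutation is a genuine PTM^mut
    annotated = pb.call_ptm_mut(muts, anns.ptm_sites)
    injected = annotated[(annotated["gene"] == "G0003") & (annotated["aa_start"] == 10)]
    assert injected["is_ptm_mut"].all()


def test_hotspot_referencing_unknown_cancer_rejected():
    with pytest.raises(ConfigError, match="cohorts"):
        SimulationConfig(
            n_cancers=2,
            hotspot_specs=(HotspotSpec("G0001", 5, "phosphorylation", ("C09",)),),
        )
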