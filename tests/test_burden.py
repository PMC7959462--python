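"""Burden measure: local/global definitions, folds, controls, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ptmburden as pb
from ptmburden.burden import (
    chi2_2x2,
    gene_sets_from_catalog,
    global_burden,
    local_burdens,
)
from tests.conftest import mut_table, oracle_local_burdens, site_table


def _annotate(muts, sites):
    return pb.call_ptm_mut(muts, sites)


def test_local_burden_definition():
    # 10 N-glyc sites, 2 distinct sites hit in one cohort -> 20%
    sites = site_table([("P1", i, "n_glycosylation", "N") for i in range(1, 11)])
    muts = mut_table(
        [
            dict(protein_id="P1", aa_start=1, cancer="C"),
            dict(protein_id="P1", aa_start=2, cancer="C", sample="S2"),
            dict(protein_id="P1", aa_start=2, cancer="C", sample="S3"),  # recurrent
        ]
    )
    bt = local_burdens(_annotate(muts, sites), sites)
    row = bt[(bt["protein_id"] == "P1") & (bt["cancer"] == "C")].iloc[0]
    assert row["n_sites_known"] == 10
    assert row["n_sites_hit"] == 2
    assert row["local_burden"] == pytest.approx(20.0)


def test_zero_hit_rows_present():
    sites = site_table([("P1", 5, "phosphorylation"), ("P2", 7, "acetylation", "K")])
    muts = mut_table([dict(protein_id="P1", aa_start=5, cancer="C")])
    bt = local_burdens(_annotate(muts, sites), sites)
    p2 = bt[bt["protein_id"] == "P2"]
    assert len(p2) == 1
    assert p2.iloc[0]["local_burden"] == 0.0


def test_burden_invariant_to_duplicate_records():
    sites = site_table([("P1", i, "phosphorylation") for i in range(1, 6)])
    muts = mut_table([dict(protein_id="P1", aa_start=3, cancer="C")])
    dup = pd.concat([muts, muts], ignore_index=True)
    a = local_burdens(_annotate(muts, sites), sites)
    b = local_burdens(_annotate(dup, sites), sites)
    pd.testing.assert_frame_equal(a, b)


def test_local_burdens_match_oracle(small_bundle):
    annotated = small_bundle["annotated"]
    sites = small_bundle["annotations"].ptm_sites
    cancers = sorted(annotated["cancer"].unique())
    got = local_burdens(annotated, sites, cancers)
    expected = oracle_local_burdens(annotated, sites, cancers)
    pd.testing.assert_frame_equal(
        got[expected.columns].reset_index(drop=True), expected
    )


def test_global_burden_of_singleton_set_is_mean_of_local(small_bundle):
    annotated = small_bundle["annotated"]
    sites = small_bundle["annotations"].ptm_sites
    bt = local_burdens(annotated, sites)
    pid = bt["protein_id"].iloc[0]
    ptm_type = bt[bt["protein_id"] == pid]["ptm_type"].iloc[0]
    gb = global_burden(bt, {"one": {pid}, "rest": set()})
    row = gb[(gb["gene_set"] == "one") & (gb["ptm_type"] == ptm_type)]
    manual = bt[(bt["protein_id"] == pid) & (bt["ptm_type"] == ptm_type)][
        "local_burden"
    ].mean()
    assert row["global_burden"].iloc[0] == pytest.approx(manual)


def test_fold_identity_and_zero_guard():
    bt = pd.DataFrame(
        {
            "protein_id": ["P1", "P2"],
            "ptm_type": ["phosphorylation"] * 2,
            "cancer": ["C"] * 2,
            "n_sites_known": [10, 10],
            "n_sites_hit": [2, 2],
            "local_burden": [20.0, 20.0],
        }
    )
    gb = global_burden(bt, {"matrisome": {"P1"}, "rest": {"P2"}})
    m = gb[gb["gene_set"] == "matrisome"].iloc[0]
    assert m["fold_vs_rest"] == pytest.approx(0.0)

    # all-zero rest burden -> fold missing
    bt.loc[1, ["n_sites_hit", "local_burden"]] = [0, 0.0]
    gb = global_burden(bt, {"matrisome": {"P1"}, "rest": {"P2"}})
    assert np.isnan(gb[gb["gene_set"] == "matrisome"]["fold_vs_rest"].iloc[0])


def test_fold_magnitude_example():
    # matrisome mean 0.85 vs rest 0.10 -> 7.5-fold enrichment
    bt = pd.DataFrame(
        {
            "protein_id": ["P1", "P2"],
            "ptm_type": ["o_glycosylation"] * 2,
            "cancer": ["C"] * 2,
            "n_sites_known": [100, 100],
            "n_sites_hit": [1, 1],
            "local_burden": [0.85, 0.10],
        }
    )
    gb = global_burden(bt, {"matrisome": {"P1"}, "rest": {"P2"}})
    assert gb[gb["gene_set"] == "matrisome"]["fold_vs_rest"].iloc[0] == pytest.approx(
        7.5
    )


def test_chi2_matches_closed_form():
    # hand-computed Pearson chi-square, 1 df, no continuity correction
    table = np.array([[10, 90], [20, 80]])
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    stat_manual = ((table - expected) ** 2 / expected).sum()
    p_manual = stats.chi2.sf(stat_manual, df=1)
    stat, p, _ = chi2_2x2(table)
    assert stat == pytest.approx(stat_manual)
    assert p == pytest.approx(p_manual)


def test_random_set_control_no_signal_when_identical(small_bundle):
    # compare the matrisome against itself: p = 1 exactly
    stat, p, _ = chi2_2x2([[50, 950], [50, 950]])
    assert p == pytest.approx(1.0)


def test_random_set_control_shapes_and_determinism(small_bundle):
    annotated = small_bundle["annotated"]
    catalog = small_bundle["catalog"]
    a = pb.random_set_control(annotated, catalog, n_draws=10, seed=3)
    b = pb.random_set_control(annotated, catalog, n_draws=10, seed=3)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == 10
    assert a["p_value"].between(0, 1).all()


def test_family_correlation_perfect_anticorrelation():
    catalog = pd.DataFrame(
        {
            "gene_symbol": ["G1"],
            "protein_id": ["P1"],
            "gene_length": [300],
            "protein_length": [99],
            "is_matrisome": [True],
            "division": ["core_matrisome"],
            "category": ["collagens"],
        }
    )
    cancers = ["C1", "C2", "C3", "C4"]
    bt = pd.DataFrame(
        {
            "protein_id": "P1",
            "ptm_type": "hydroxylation",
            "cancer": cancers,
            "n_sites_known": 10,
            "n_sites_hit": [4, 3, 2, 1],
            "local_burden": [40.0, 30.0, 20.0, 10.0],
        }
    )
    rows = []
    for cancer, n in zip(cancers, [1, 2, 3, 4]):  # counts anti-ordered vs burden
        for i in range(n):
            rows.append(
                dict(protein_id="P1", gene="G1", cancer=cancer, aa_start=1,
                     sample=f"{cancer}-{i}")
            )
    sites = site_table([("P1", 1, "hydroxylation", "P")])
    annotated = _annotate(mut_table(rows), sites)
    out = pb.family_burden_correlation(bt, annotated, catalog)
    row = out[out["category"] == "collagens"].iloc[0]
    assert row["r"] == pytest.approx(-1.0)


def test_family_correlation_refuses_two_points():
    catalog = pd.DataFrame(
        {
            "gene_symbol": ["G1"],
            "protein_id": ["P1"],
            "gene_length": [300],
            "protein_length": [99],
            "is_matrisome": [True],
            "division": ["core_matrisome"],
            "category": ["collagens"],
        }
    )
    sites = site_table([("P1", 1, "hydroxylation", "P")])
    muts = mut_table(
        [dict(protein_id="P1", gene="G1", cancer=c, aa_start=1) for c in ("C1", "C2")]
    )
    annotated = _annotate(muts, sites)
    bt = local_burdens(annotated, sites)
    with pytest.raises(ValueError, match=">= 3"):
        pb.family_burden_correlation(bt, annotated, catalog)


def test_family_correlation_matches_pearson_formula(small_bundle):
    annotated = small_bundle["annotated"]
    sites = small_bundle["annotations"].ptm_sites
    catalog = small_bundle["catalog"]
    bt = local_burdens(annotated, sites)
    out = pb.family_burden_correlation(bt, annotated, catalog)
    cat_of = dict(zip(catalog["protein_id"], catalog["category"]))
    for _, row in out.dropna(subset=["r"]).iterrows():
        cat = row["category"]
        xs, ys = [], []
        for cancer in sorted(annotated["cancer"].unique()):
            sub = bt[
                (bt["cancer"] == cancer)
                & (bt["protein_id"].map(cat_of) == cat)
            ]
            if sub.empty:
                continue
            xs.append(sub["local_burden"].mean())
            ptm = annotated[annotated["is_ptm_mut"]]
            ys.append(
                int(
                    (
                        (ptm["cancer"] == cancer)
                        & (ptm["protein_id"].map(cat_of) == cat)
                    ).sum()
                )
            )
        x, y = np.array(xs, float), np.array(ys, float)
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert row["r"] == pytest.approx(r_manual)


def test_length_normalized_rate_examples():
    catalog = pd.DataFrame(
        {
            "gene_symbol": ["G1", "G2"],
            "protein_id": ["P1", "P2"],
            "gene_length": [1000, 2000],
            "protein_length": [300, 600],
            "is_matrisome": [True, True],
            "division": ["core_matrisome"] * 2,
            "category": ["collagens"] * 2,
        }
    )
    sites = site_table([("P2", i, "phosphorylation") for i in (1, 2, 3, 4)])
    muts = mut_table(
        [dict(protein_id="P2", gene="G2", aa_start=i, sample=f"S{i}") for i in (1, 2, 3, 4)]
    )
    annotated = _annotate(muts, sites)
    # genes (0/1000, 4/2000) -> mean 1.0e-3; zero-count gene included
    rate = pb.length_normalized_rate(annotated, catalog, mut_class="ptm")
    assert rate == pytest.approx(1.0e-3)
    # one gene, 2 PTM^mut, length 2000 -> 1.0e-3
    rate = pb.length_normalized_rate(
        annotated.iloc[:2], catalog[catalog["gene_symbol"] == "G2"], mut_class="ptm"
    )
    assert rate == pytest.approx(1.0e-3)


def test_share_ratio_guards():
    assert pb.share_ratio(0, 10) == 0.0
    with pytest.raises(ValueError):
        pb.share_ratio(1, 0)
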