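"""End-to-end pipeline: simulate/read -> annotate -> burden -> selection ->
context -> network, with a summary report and reproducibility block.

All randomness flows from the root seed in :class:`RunConfig`; per-stage
child seeds are derived deterministically so module-level reruns match
pipeline runs.  Rerunning the same config yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from ptmburden import annotate as ann
from ptmburden import burden as bd
from ptmburden import domains as dom
from ptmburden import io as ptio
from ptmburden import network as net
from ptmburden import selection as sel
from ptmburden import synthetic as syn
from ptmburden.config import ConfigError, RunConfig, child_seed

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _serialize_hits(hit_sites: list) -> str:
    return ";".join(f"{pos}:{t}" for pos, t in hit_sites) if hit_sites else "."


def top_genes_table(annotated: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k genes by PTM^mut count per cancer (ties broken alphabetically)."""
    ptm = annotated[annotated["is_ptm_mut"]]
    counts = (
        ptm.groupby(["cancer", "gene"], as_index=False)
        .size()
        .rename(columns={"size": "n_ptm_mut"})
    )
    counts = counts.sort_values(
        ["cancer", "n_ptm_mut", "gene"], ascending=[True, False, True]
    )
    out = counts.groupby("cancer", group_keys=False).head(k).copy()
    out["rank"] = out.groupby("cancer").cumcount() + 1
    return out.reset_index(drop=True)


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("outdir", None)  # the output location is not part of the analysis
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline and write every module's outputs.

    Returns the report bundle: all in-memory tables plus the summary
    dictionary written to ``summary.json``.
    """
    from ptmburden import __version__

    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # ---- inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate is not None:
            catalog = syn.generate_gene_catalog(config.simulate)
            annotations = syn.generate_annotations(catalog, config.simulate)
            mutations = syn.simulate_cohort(catalog, annotations, config.simulate)
            syn.write_bundle(outdir / "inputs", catalog, annotations, mutations)
            domains_df = annotations.domains
            regions_df = annotations.regions
            interactions_df = annotations.interactions
            sequences = annotations.sequences
            normals = None
        else:
            tables = ptio.read_bundle(dict(config.inputs))
            mutations = tables["mutations"]
            catalog = tables["catalog"]
            sites = tables["sites"]
            domains_df = tables.get("domains", pd.DataFrame(
                columns=["protein_id", "domain_id", "start", "end"]))
            regions_df = tables.get("regions", pd.DataFrame(
                columns=["protein_id", "region", "start", "end"]))
            interactions_df = tables.get("interactions", pd.DataFrame(
                columns=["gene_a", "gene_b"]))
            sequences = tables.get("sequences", {})
            normals = tables.get("normals")
        if config.simulate is not None:
            sites = annotations.ptm_sites
    except ConfigError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- annotate ---------------------------------------------------
    stage = "annotate"
    try:
        annotated = ann.call_ptm_mut(mutations, sites)
        towrite = annotated.copy()
        towrite["hit_sites"] = towrite["hit_sites"].map(_serialize_hits)
        ptio.write_tsv(towrite, outdir / "annotated.tsv")
        bundle["annotated"] = annotated
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    gene_sets = bd.gene_sets_from_catalog(catalog)
    matrisome_genes = set(catalog.loc[catalog["is_matrisome"], "gene_symbol"])

    # ---- burden -----------------------------------------------------
    stage = "burden"
    try:
        local = bd.local_burdens(annotated, sites)
        global_b = bd.global_burden(local, gene_sets)
        control = bd.random_set_control(
            annotated,
            catalog,
            n_draws=config.n_random_draws,
            seed=child_seed(config.seed, 10),
        )
        try:
            family_corr = bd.family_burden_correlation(local, annotated, catalog)
        except ValueError as e:
            log.warning("family correlation skipped: %s", e)
            family_corr = pd.DataFrame(columns=["category", "r", "p_value", "n_points"])
        ptio.write_tsv(local, outdir / "burden_local.tsv")
        ptio.write_tsv(global_b, outdir / "burden_global.tsv")
        ptio.write_tsv(control, outdir / "random_control.tsv")
        ptio.write_tsv(family_corr, outdir / "family_correlation.tsv")
        bundle.update(
            burden_local=local, burden_global=global_b,
            random_control=control, family_correlation=family_corr,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- selection --------------------------------------------------
    stage = "selection"
    try:
        rdnds = sel.rdnds_table(annotated, sites, pseudocount=config.dnds_pseudocount)
        rdnds_cmp = sel.compare_rdnds(rdnds, matrisome_genes, alpha=config.alpha)
        hotspots = sel.find_hotspots(annotated, min_cohorts=config.min_cohorts)
        composition = sel.residue_composition(annotated)
        top_genes = top_genes_table(annotated)
        ptio.write_tsv(rdnds, outdir / "rdnds.tsv")
        ptio.write_tsv(hotspots, outdir / "hotspots.tsv")
        ptio.write_tsv(composition, outdir / "residue_composition.tsv")
        ptio.write_tsv(top_genes, outdir / "top_genes.tsv")
        bundle.update(
            rdnds=rdnds, rdnds_comparison=rdnds_cmp,
            hotspots=hotspots, residue_composition=composition,
            top_genes=top_genes,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- context ----------------------------------------------------
    stage = "context"
    try:
        dratios = dom.domain_ratios(annotated, domains_df, catalog)
        differential = dom.differential_domains(dratios, fold=config.domain_fold)
        region_flags, region_summary = dom.region_overlap(annotated, regions_df)
        motif_rows = []
        context_rows = []
        for rec in annotated[annotated["is_ptm_mut"]].itertuples():
            seq = sequences.get(rec.protein_id)
            if not seq or rec.aa_start > len(seq):
                continue
            for hit in dom.motif_scan(
                seq, rec.aa_start, window=config.motif_window
            ):
                motif_rows.append(
                    {
                        "gene": rec.gene,
                        "protein_id": rec.protein_id,
                        "position": rec.aa_start,
                        "motif": hit.motif,
                        "motif_start": hit.start,
                        "distance": hit.distance,
                    }
                )
            window, offset = dom.extract_context(
                seq, rec.aa_start, flank=config.context_flank
            )
            context_rows.append(
                {
                    "gene": rec.gene,
                    "protein_id": rec.protein_id,
                    "position": rec.aa_start,
                    "window": window,
                    "offset": offset,
                }
            )
        motif_hits = pd.DataFrame(
            motif_rows,
            columns=["gene", "protein_id", "position", "motif", "motif_start",
                     "distance"],
        )
        contexts = pd.DataFrame(
            context_rows,
            columns=["gene", "protein_id", "position", "window", "offset"],
        )
        profile = dom.context_property_profile(
            list(zip(contexts["window"], contexts["offset"])),
            flank=config.context_flank,
        )
        ptio.write_tsv(dratios, outdir / "domain_ratios.tsv")
        (outdir / "differential_domains.txt").write_text(
            "\n".join(differential) + ("\n" if differential else "")
        )
        ptio.write_tsv(
            region_flags.assign(hit_sites=region_flags["hit_sites"].map(_serialize_hits)),
            outdir / "region_overlap.tsv",
        )
        ptio.write_tsv(motif_hits, outdir / "motif_hits.tsv")
        ptio.write_tsv(contexts, outdir / "contexts.tsv")
        ptio.write_tsv(profile, outdir / "context_profile.tsv")
        bundle.update(
            domain_ratios=dratios, differential_domains=differential,
            region_overlap=region_flags, region_summary=region_summary,
            motif_hits=motif_hits, contexts=contexts, context_profile=profile,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- network ----------------------------------------------------
    stage = "network"
    try:
        ptm_gene_set = set(annotated.loc[annotated["is_ptm_mut"], "gene"])
        functional = set(region_flags.loc[region_flags["in_region"], "gene"])
        graph = net.build_network(ptm_gene_set, interactions_df, functional)
        cooc = net.patient_cooccurrence(annotated, interactions_df)
        net.write_graphml(graph, outdir / "network.graphml")
        net.write_edge_list(graph, outdir / "network_edges.tsv")
        ptio.write_tsv(net.network_table(graph), outdir / "network_nodes.tsv")
        ptio.write_tsv(cooc, outdir / "cooccurrence.tsv")
        if normals is not None:
            ptm_rows = annotated[annotated["is_ptm_mut"]]
            retained, n_removed = net.healthy_filter(ptm_rows, normals)
            ptio.write_tsv(
                retained.assign(hit_sites=retained["hit_sites"].map(_serialize_hits)),
                outdir / "ptm_mut_not_in_normals.tsv",
            )
            bundle["healthy_filter"] = {"n_retained": len(retained),
                                        "n_removed": n_removed}
        bundle.update(network=graph, cooccurrence=cooc)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- summary ----------------------------------------------------
    stage = "summary"
    try:
        classes = ann.mutation_classes(annotated)
        in_matrisome = annotated["gene"].isin(matrisome_genes)
        nonsilent = annotated["effect"] != "silent"
        n_total = int(len(annotated))
        n_silent = int((classes == "silent").sum())
        n_ptm = int((classes == "ptm_mut").sum())
        n_non_ptm = int((classes == "non_ptm_nonsilent").sum())
        n_m_nonsilent = int((in_matrisome & nonsilent).sum())
        n_r_nonsilent = int((~in_matrisome & nonsilent).sum())
        n_m_ptm = int((in_matrisome & annotated["is_ptm_mut"]).sum())
        n_r_ptm = n_ptm - n_m_ptm

        folds = {
            f"{row.gene_set}:{row.ptm_type}": row.fold_vs_rest
            for row in global_b.itertuples()
            if row.gene_set == "matrisome"
        }
        summary = {
            "counts": {
                "total_mutations": n_total,
                "silent": n_silent,
                "ptm_mut": n_ptm,
                "non_ptm_nonsilent": n_non_ptm,
                "matrisome_nonsilent": n_m_nonsilent,
                "rest_nonsilent": n_r_nonsilent,
                "matrisome_ptm_mut": n_m_ptm,
                "rest_ptm_mut": n_r_ptm,
                "hotspots": int(len(hotspots)),
                "cooccurring_pairs": int(len(cooc)),
                "network_nodes": int(graph.number_of_nodes()),
                "network_edges": int(graph.number_of_edges()),
            },
            "shares_percent": {
                "matrisome_of_nonsilent": bd.share_ratio(
                    n_m_nonsilent, n_m_nonsilent + n_r_nonsilent
                ),
                "ptm_mut_of_nonsilent": bd.share_ratio(n_ptm, n_ptm + n_non_ptm),
                "ptm_mut_of_matrisome": (
                    bd.share_ratio(n_m_ptm, n_m_nonsilent) if n_m_nonsilent else None
                ),
                "ptm_mut_of_rest": (
                    bd.share_ratio(n_r_ptm, n_r_nonsilent) if n_r_nonsilent else None
                ),
            },
            "burden_folds_vs_rest": folds,
            "rdnds": {**sel.summarize_rdnds(rdnds), "comparison": rdnds_cmp},
            "random_control": bd.summarize_control(control),
            "region_overlap": region_summary,
            "reproducibility": {
                "seed": config.seed,
                "version": __version__,
                "config_sha256": _config_hash(config),
            },
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True,
                      default=_json_default)
            fh.write("\n")
        bundle["summary"] = summary
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    return bundle
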