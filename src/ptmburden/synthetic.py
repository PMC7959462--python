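"""Synthetic cohort generator.

Emulates every input the analysis consumes: a gene/protein catalog split
into matrisome divisions and categories, protein sequences, PTM sites with
category-dependent type frequencies placed on chemically valid residues,
Pfam-style domain and UniProt-style functional-region intervals, a
BioGRID-style interaction edge list, and a tumor cohort of protein-space
somatic mutations with configurable silent fraction, Ti/Tv structure,
per-site selection against PTM positions, and injected recurrent hotspots.

Mutations are generated directly in protein coordinates (residue index +
silent flag + nucleotide-change class) rather than through a codon model:
the downstream analysis consumes protein-level mutation fields only, and
this keeps the generator exact and fast.  One protein isoform per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ptmburden.config import ConfigError, SimulationConfig
from ptmburden.constants import (
    AMINO_ACIDS,
    CATEGORY_TO_DIVISION,
    NUCLEOTIDES,
    PTM_VALID_RESIDUES,
)

log = logging.getLogger(__name__)

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

_REGION_LABELS = (
    "triple-helical region",
    "heparin-binding domain",
    "GAG attachment domain",
    "catalytic domain",
    "integrin-binding region",
    "protease-sensitive linker",
)


@dataclass
class Annotations:
    """Bundle of per-protein annotation tables produced by the generator."""

    ptm_sites: pd.DataFrame
    domains: pd.DataFrame
    regions: pd.DataFrame
    sequences: dict[str, str]
    interactions: pd.DataFrame


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one independent, reproducible stream per generation stage
    return np.random.default_rng([int(config.seed), stage])


def _allocate_counts(total: int, split: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of `total` items over a proportion map."""
    keys = sorted(split)
    weights = np.array([split[k] for k in keys], dtype=float)
    weights = weights / weights.sum()
    raw = weights * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts))


def generate_gene_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Generate the gene/protein catalog.

    Exactly ``round(n_genes * matrisome_fraction)`` genes are flagged as
    matrisome, allocated over the six categories by the configured split
    (largest remainder, so small catalogs still cover every category with
    nonzero share).  Protein lengths are log-normal; gene length is the
    coding length ``3 * protein_length + 3``.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    n_matrisome = int(round(n * config.matrisome_fraction))

    protein_length = np.maximum(
        50,
        rng.lognormal(
            mean=np.log(config.mean_protein_length),
            sigma=config.protein_length_sigma,
            size=n,
        ).astype(int),
    )
    gene_length = 3 * protein_length + 3

    categories = np.array(["none"] * n, dtype=object)
    cat_counts = _allocate_counts(n_matrisome, dict(config.category_split))
    idx = 0
    for cat in sorted(cat_counts):
        k = cat_counts[cat]
        categories[idx : idx + k] = cat
        idx += k

    df = pd.DataFrame(
        {
            "gene_symbol": [f"G{i:04d}" for i in range(1, n + 1)],
            "protein_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "gene_length": gene_length,
            "protein_length": protein_length,
            "category": categories,
        }
    )
    df["is_matrisome"] = df["category"] != "none"
    df["division"] = df["category"].map(CATEGORY_TO_DIVISION)
    return df[
        [
            "gene_symbol",
            "protein_id",
            "gene_length",
            "protein_length",
            "is_matrisome",
            "division",
            "category",
        ]
    ]


def _place_sites(
    rng: np.random.Generator,
    protein_id: str,
    length: int,
    category: str,
    config: SimulationConfig,
    seq: np.ndarray,
) -> list[tuple[str, int, str, str]]:
    profile = dict(config.ptm_density_by_category.get(category, {}))
    if category != "collagens":
        # hydroxylation has no correspondences outside collagens
        profile.pop("hydroxylation", None)
    if not profile:
        return []
    types = sorted(profile)
    weights = np.array([profile[t] for t in types], dtype=float)
    if weights.sum() <= 0:
        return []
    weights = weights / weights.sum()

    n_sites = rng.binomial(length, min(1.0, config.sites_per_100aa / 100.0))
    if n_sites == 0:
        return []
    positions = rng.choice(length, size=n_sites, replace=False) + 1  # 1-based
    site_types = rng.choice(types, size=n_sites, p=weights)
    rows = []
    for pos, t in zip(positions, site_types):
        valid = PTM_VALID_RESIDUES[t]
        residue = valid[rng.integers(len(valid))]
        seq[pos - 1] = residue
        rows.append((protein_id, int(pos), t, residue))
    return rows


def generate_annotations(
    catalog: pd.DataFrame, config: SimulationConfig
) -> Annotations:
    """Generate sequences, PTM sites, domains, regions and interactions.

    Sequences are uniform over the 20 amino acids except at PTM sites,
    which are forced to a chemically valid acceptor residue for their
    modification type.  Hotspot positions from the config are guaranteed a
    matching PTM site so injected mutations are genuine PTM^mut.
    """
    if catalog.empty:
        raise ConfigError("catalog is empty")
    rng = _rng(config, 2)
    aa = np.array(list(AMINO_ACIDS))

    sequences: dict[str, str] = {}
    site_rows: list[tuple[str, int, str, str]] = []
    domain_rows = []
    region_rows = []

    gene_to_protein = dict(zip(catalog["gene_symbol"], catalog["protein_id"]))
    gene_to_cat = dict(zip(catalog["gene_symbol"], catalog["category"]))

    for rec in catalog.itertuples(index=False):
        L = int(rec.protein_length)
        seq = aa[rng.integers(0, len(aa), size=L)]
        site_rows.extend(
            _place_sites(rng, rec.protein_id, L, rec.category, config, seq)
        )

        # Pfam-style domain instances drawn from a shared family pool so
        # the same domain id recurs in matrisome and non-matrisome proteins
        for _ in range(rng.poisson(max(1.0, L / 300.0))):
            fam = int(rng.integers(1, config.n_domain_families + 1))
            span = int(rng.integers(40, 121))
            if span >= L:
                start = 1
            else:
                start = int(rng.integers(1, L - span + 1))
            domain_rows.append(
                (rec.protein_id, f"DOM{fam:03d}", start, min(L, start + span - 1))
            )

        if rng.random() < config.region_coverage:
            for _ in range(1 + rng.poisson(1.0)):
                label = _REGION_LABELS[rng.integers(len(_REGION_LABELS))]
                span = int(rng.integers(20, 81))
                start = 1 if span >= L else int(rng.integers(1, L - span + 1))
                region_rows.append(
                    (rec.protein_id, label, start, min(L, start + span - 1))
                )

        sequences[rec.protein_id] = "".join(seq)

    # guarantee annotated sites under every injected hotspot
    existing = {(p, pos, t) for p, pos, t, _ in site_rows}
    for h in config.hotspot_specs:
        if h.gene not in gene_to_protein:
            raise ConfigError(f"hotspot_specs: gene {h.gene!r} not in catalog")
        pid = gene_to_protein[h.gene]
        if h.ptm_type == "hydroxylation" and gene_to_cat[h.gene] != "collagens":
            raise ConfigError(
                f"hotspot_specs: hydroxylation hotspot on non-collagen gene {h.gene!r}"
            )
        seq = sequences[pid]
        if h.position > len(seq):
            raise ConfigError(
                f"hotspot_specs: position {h.position} beyond protein {pid} "
                f"length {len(seq)}"
            )
        if (pid, h.position, h.ptm_type) not in existing:
            valid = PTM_VALID_RESIDUES[h.ptm_type]
            residue = seq[h.position - 1]
            if residue not in valid:
                residue = valid[0]
                sequences[pid] = (
                    seq[: h.position - 1] + residue + seq[h.position :]
                )
            site_rows.append((pid, h.position, h.ptm_type, residue))
            existing.add((pid, h.position, h.ptm_type))

    ptm_sites = pd.DataFrame(
        site_rows, columns=["protein_id", "position", "ptm_type", "residue"]
    ).sort_values(["protein_id", "position", "ptm_type"], ignore_index=True)

    domains = pd.DataFrame(
        domain_rows, columns=["protein_id", "domain_id", "start", "end"]
    )
    regions = pd.DataFrame(
        region_rows, columns=["protein_id", "region", "start", "end"]
    )

    # BioGRID-style undirected edges among catalog genes
    genes = catalog["gene_symbol"].to_numpy()
    n_edges = int(round(config.edges_per_gene * len(genes)))
    a = rng.choice(genes, size=n_edges)
    b = rng.choice(genes, size=n_edges)
    homotypic = rng.random(n_edges) < config.homotypic_fraction
    b = np.where(homotypic, a, b)
    # drop accidental (non-flagged) self-loops, then symmetric-dedup
    keep = (a != b) | homotypic
    lo = np.minimum(a[keep], b[keep])
    hi = np.maximum(a[keep], b[keep])
    interactions = (
        pd.DataFrame({"gene_a": lo, "gene_b": hi})
        .drop_duplicates()
        .sort_values(["gene_a", "gene_b"], ignore_index=True)
    )

    return Annotations(ptm_sites, domains, regions, sequences, interactions)


def _draw_alleles(rng: np.random.Generator, n: int, titv_ratio: float):
    ref = np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=n)]
    is_transition = rng.random(n) < titv_ratio / (titv_ratio + 1.0)
    alt = np.empty(n, dtype=object)
    pick = rng.integers(0, 2, size=n)
    for i in range(n):
        if is_transition[i]:
            alt[i] = _TRANSITION_PARTNER[ref[i]]
        else:
            alt[i] = _TRANSVERSION_PARTNERS[ref[i]][pick[i]]
    return ref.astype(object), alt


def _draw_candidates(
    rng: np.random.Generator,
    n: int,
    catalog: pd.DataFrame,
    gene_probs: np.ndarray,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Draw `n` candidate mutations (gene, position, effect, alleles)."""
    gi = rng.choice(len(catalog), size=n, p=gene_probs)
    genes = catalog["gene_symbol"].to_numpy()[gi]
    proteins = catalog["protein_id"].to_numpy()[gi]
    lengths = catalog["protein_length"].to_numpy()[gi]
    pos = (rng.random(n) * lengths).astype(int) + 1  # uniform in [1, L]

    silent = rng.random(n) < config.silent_fraction
    eff_names = sorted(config.nonsilent_effects)
    eff_w = np.array([config.nonsilent_effects[e] for e in eff_names], dtype=float)
    eff_w = eff_w / eff_w.sum()
    effects = np.where(silent, "silent", rng.choice(eff_names, size=n, p=eff_w))

    kinds = np.full(n, "SNP", dtype=object)
    indel_mask = np.isin(effects, ("frameshift", "inframe_indel"))
    kinds[indel_mask] = np.where(rng.random(indel_mask.sum()) < 0.5, "DEL", "INS")

    ref, alt = _draw_alleles(rng, n, config.titv_ratio)
    ref[indel_mask] = "."
    alt[indel_mask] = "."

    end = pos.copy()
    inframe = effects == "inframe_indel"
    end[inframe] = np.minimum(lengths[inframe], pos[inframe] + 2)

    return pd.DataFrame(
        {
            "gene": genes,
            "protein_id": proteins,
            "aa_start": pos,
            "aa_end": end,
            "effect": effects,
            "variant_kind": kinds,
            "ref": ref,
            "alt": alt,
        }
    )


def simulate_cohort(
    catalog: pd.DataFrame,
    annotations: Annotations,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate the somatic mutation table for the whole cohort.

    Per sample the mutation count is Poisson(``mutation_rate``); each
    mutation picks a gene with probability proportional to gene length, a
    residue uniform along the protein, a silent flag, and SNV alleles with
    the configured Ti/Tv structure.  A non-silent candidate whose residue
    is an annotated PTM position is rejected and redrawn with probability
    ``ptm_selection_s`` (optionally only for matrisome genes).  Hotspot
    specs are injected verbatim afterwards, so they survive any ``s``.
    """
    if catalog.empty:
        raise ConfigError("catalog is empty")
    rng = _rng(config, 3)

    gene_probs = catalog["gene_length"].to_numpy(dtype=float)
    gene_probs = gene_probs / gene_probs.sum()
    matrisome_proteins = set(catalog.loc[catalog["is_matrisome"], "protein_id"])
    ptm_positions = set(
        zip(annotations.ptm_sites["protein_id"], annotations.ptm_sites["position"])
    )

    cancers = config.cancer_names()
    sample_ids, sample_cancers, counts = [], [], []
    for cancer in cancers:
        for i in range(1, config.samples_per_cancer + 1):
            sample_ids.append(f"{cancer}-S{i:03d}")
            sample_cancers.append(cancer)
            counts.append(rng.poisson(config.mutation_rate))
    counts = np.asarray(counts)
    total = int(counts.sum())

    muts = _draw_candidates(rng, total, catalog, gene_probs, config)
    muts.insert(0, "cancer", np.repeat(sample_cancers, counts))
    muts.insert(0, "sample", np.repeat(sample_ids, counts))

    # selection: reject-and-redraw loop over non-silent candidates on PTM sites
    s = config.ptm_selection_s
    if s > 0:
        for iteration in range(1000):
            on_site = np.fromiter(
                (
                    (p, q) in ptm_positions
                    for p, q in zip(muts["protein_id"], muts["aa_start"])
                ),
                dtype=bool,
                count=len(muts),
            )
            candidate = on_site & (muts["effect"] != "silent").to_numpy()
            if config.selection_matrisome_only:
                in_matrisome = muts["protein_id"].isin(matrisome_proteins).to_numpy()
                candidate &= in_matrisome
            reject = candidate & (rng.random(len(muts)) < s)
            if not reject.any():
                break
            redraw = _draw_candidates(
                rng, int(reject.sum()), catalog, gene_probs, config
            )
            redraw.index = muts.index[reject]
            muts.loc[reject, redraw.columns] = redraw
        else:
            raise RuntimeError("selection redraw did not converge")

    # inject hotspots: one missense SNP in the first sample of each cohort
    hot_rows = []
    pid_of = dict(zip(catalog["gene_symbol"], catalog["protein_id"]))
    for h in config.hotspot_specs:
        for cancer in h.cancers:
            ref, alt = _draw_alleles(rng, 1, config.titv_ratio)
            hot_rows.append(
                {
                    "sample": f"{cancer}-S001",
                    "cancer": cancer,
                    "gene": h.gene,
                    "protein_id": pid_of[h.gene],
                    "aa_start": h.position,
                    "aa_end": h.position,
                    "effect": "missense",
                    "variant_kind": "SNP",
                    "ref": ref[0],
                    "alt": alt[0],
                }
            )
    if hot_rows:
        muts = pd.concat([muts, pd.DataFrame(hot_rows)], ignore_index=True)

    muts["ref_aa"] = [
        annotations.sequences[p][q - 1] if q <= len(annotations.sequences[p]) else "."
        for p, q in zip(muts["protein_id"], muts["aa_start"])
    ]
    muts["sift"] = "unknown"
    muts["polyphen"] = "unknown"
    muts = muts.astype({"aa_start": int, "aa_end": int})
    log.info("simulated %d mutations across %d samples", len(muts), len(sample_ids))
    return muts


def write_bundle(
    outdir,
    catalog: pd.DataFrame,
    annotations: Annotations,
    mutations: pd.DataFrame,
) -> dict[str, str]:
    """Write the full fixture bundle as TSV files plus FASTA sequences."""
    from pathlib import Path

    from ptmburden import io as ptio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "sites": outdir / "ptm_sites.tsv",
        "catalog": outdir / "catalog.tsv",
        "domains": outdir / "domains.tsv",
        "regions": outdir / "regions.tsv",
        "interactions": outdir / "interactions.tsv",
        "sequences": outdir / "sequences.fasta",
    }
    ptio.write_tsv(mutations, paths["mutations"])
    ptio.write_tsv(annotations.ptm_sites, paths["sites"])
    ptio.write_tsv(catalog, paths["catalog"])
    ptio.write_tsv(annotations.domains, paths["domains"])
    ptio.write_tsv(annotations.regions, paths["regions"])
    ptio.write_tsv(annotations.interactions, paths["interactions"])
    ptio.write_fasta(annotations.sequences, paths["sequences"])
    return {k: str(v) for k, v in paths.items()}
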