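"""Controlled vocabularies shared across the pipeline."""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

NUCLEOTIDES = "ACGT"

# purine<->purine / pyrimidine<->pyrimidine substitutions
TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

PTM_TYPES = (
    "hydroxylation",
    "phosphorylation",
    "n_glycosylation",
    "o_glycosylation",
    "acetylation",
    "ubiquitylation",
    "sumoylation",
    "methylation",
)

# chemically valid acceptor residues for each modification
PTM_VALID_RESIDUES = {
    "hydroxylation": "PK",
    "phosphorylation": "STY",
    "n_glycosylation": "N",
    "o_glycosylation": "ST",
    "acetylation": "K",
    "ubiquitylation": "K",
    "sumoylation": "K",
    "methylation": "K",
}

EFFECTS = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "silent",
    "other_nonsilent",
)

VARIANT_KINDS = ("SNP", "INS", "DEL")

MATRISOME_DIVISIONS = ("core_matrisome", "matrisome_associated", "none")

MATRISOME_CATEGORIES = (
    "collagens",
    "ecm_glycoproteins",
    "proteoglycans",
    "ecm_affiliated",
    "ecm_regulators",
    "secreted_factors",
    "none",
)

CATEGORY_TO_DIVISION = {
    "collagens": "core_matrisome",
    "ecm_glycoproteins": "core_matrisome",
    "proteoglycans": "core_matrisome",
    "ecm_affiliated": "matrisome_associated",
    "ecm_regulators": "matrisome_associated",
    "secreted_factors": "matrisome_associated",
    "none": "none",
}

# ECM interaction motifs scanned around mutated residues (integrin-binding
# RGD/LDV, collagenous GPP repeats, GFPGER/GLPGER integrin recognition,
# GVD cleavage-adjacent motif)
DEFAULT_MOTIFS = ("GPP", "GVD", "RGD", "LDV", "GFPGER", "GLPGER")

# coarse physico-chemical partition of the 20 amino acids
RESIDUE_PROPERTIES = {
    "polar": set("STNQYC"),
    "hydrophobic": set("AVLIMFW"),
    "acidic": set("DE"),
    "basic": set("KRH"),
    "special": set("GP"),
}

RESIDUE_TO_PROPERTY = {
    aa: prop for prop, aas in RESIDUE_PROPERTIES.items() for aa in aas
}

MISSING = "."
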