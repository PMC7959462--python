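# Methods

## Scope and data model

The pipeline consumes protein-space somatic mutation calls (sample,
cohort, gene, protein, 1-based residue interval, effect class, alleles),
a PTM-site table (protein, residue position, PTM type, acceptor
residue), a gene catalog with matrisome division/category labels, gene
and protein lengths, Pfam-style domain and UniProt-feature-style region
intervals, protein sequences, an undirected interaction edge list, and
optionally a table of variants observed in healthy samples.  All tables
are TSVs with a header row and `.` for missing values; sequences are
FASTA.  Rows violating a table's invariants are dropped with a logged
count; a missing required column is a hard error naming the column.

Protein coordinates are 1-based and intervals inclusive on both ends
(UniProt convention).  One protein isoform per gene.

## PTM^mut calling

A non-silent mutation is a PTM^mut iff its residue footprint contains at
least one annotated PTM position of the same protein.  Footprints:
single reported residue for SNVs (missense, nonsense, splice-site,
other non-silent), the reported `[start, end]` span for in-frame indels,
and the start residue only for frameshifts.  Truncating mutations are
deliberately *not* credited with every downstream site: footprint
inflation would let nonsense/frameshift calls dominate the tallies and
turn the statistic into a truncation counter.  This choice is
configurable in principle (the footprint rule is one small function) and
is the main known divergence risk against analyses that count downstream
loss.  Splice-site records are admissible whenever the input carries a
protein position.  A mutation overlapping several PTM types at one
residue is one PTM^mut overall but contributes to each
(position, type) pair in type-stratified tallies.

## Burden

Local burden: percentage of a protein's known sites of one PTM type hit
in one cohort, counting *distinct* sites (recurrence at a site does not
inflate it).  Proteins with no known site of a type are absent rather
than zero — the measure conditions on the baseline PTM repertoire.
Global burden: unweighted mean of local burdens over (protein, cancer)
rows of a gene set, per type; a pooled variant (summed hits / summed
known sites) is available (`method="pooled"`), mean-of-means is the
default because it weights proteins, not site counts.  Folds are
`matrisome/rest − 1` and reported missing when the rest burden is zero.

The 100-random-set control draws same-size gene sets from the
non-matrisome pool without replacement (seeded) and applies a two-sided
Pearson χ² (2×2, no Yates correction by default — the analysis operates
in a large-count regime; a flag enables the correction) to
PTM^mut vs non-PTM non-silent counts.  Draws with any expected cell
below 1 are flagged invalid and excluded from min/max summaries.

## Selection (r^dN/dS)

dN/dS is the raw non-silent/silent count ratio over a residue-position
class — no codon-opportunity or trinucleotide-context model, matching
the definition of the statistic being implemented.  Silent mutations
are assigned to the PTM class by residue index (the same-codon
alternative is not recoverable from protein-space inputs).  A
pseudocount of 0.5 (configurable, 0 disables) is added to all four
counts; with it disabled, a zero denominator yields a missing value.

Across genes, the headline average of r^dN/dS is the **geometric mean**:
r is a ratio of count ratios and symmetric under label exchange
(r ↔ 1/r), so the log-scale mean is the appropriate central summary.
The arithmetic mean of a small-count ratio-of-ratios is systematically
inflated by the harmonic term E[1/(S+a)] > 1/E[S+a] and would sit well
above 1 even for a neutral cohort.  Set comparisons use the two-sided
Mann–Whitney U test (rank-based, hence insensitive to this choice) at
α = 0.05.

## Hotspots, composition, context, network

Hotspots group PTM^mut by (gene, position, PTM type) — a position-only
relaxation is available — and keep groups observed in ≥ 3 distinct
cohorts (configurable), sorted by cohort count then gene and position.

Domain ratios pool all instances of a domain across the proteins of a
gene set; a mutation in overlapping instances of one domain counts
once.  Differential domains require both set ratios defined and a ≥ 2×
difference in either direction; with fold = 1 the call degenerates to
"defined and unequal", so the default set is always a subset of that.

Motif scanning uses span intersection: a motif occurrence is reported
when its span intersects ±window residues around the mutation
(window = 3 by default).  The alternative reading — distance to the
motif start — is a one-line change; span intersection was chosen as the
natural geometric meaning of "within ±3 residues".  Context windows are
±10 residues clipped at the termini; the residue-property partition is
polar S,T,N,Q,Y,C / hydrophobic A,V,L,I,M,F,W / acidic D,E / basic
K,R,H / special G,P, chosen as a complete partition of the 20 residues
(only "polar or hydrophobic" is externally constrained; profiles need
the rest).

The network is the induced subgraph of the edge list on PTM^mut genes;
self-loops are kept as homotypic interactions but counted once in
`total_degree` (one biological partner); isolated PTM^mut genes are
excluded.  Patient co-occurrence lists (sample, pair) rows where a
sample carries PTM^mut in both genes of a heterodimeric edge.  The
healthy-sample filter is a set difference on (gene, position) by
default; an allele-aware key is configurable since the stricter match
is defensible but cannot be resolved from counts alone.

## Synthetic cohorts

The generator encodes the structure the analysis is designed to detect.
Per sample, the mutation count is Poisson(`mutation_rate`); each
mutation picks a gene ∝ gene length, a residue uniform along the
protein, a silent flag (Bernoulli `silent_fraction`, default 0.30 — a
realistic synonymous share of coding SNVs), and SNV alleles with
transition probability `titv/(titv+1)` (default Ti/Tv = 2, typical of
exome calls).  Non-silent candidates on annotated PTM positions are
rejected and redrawn with probability `ptm_selection_s`, optionally only
in matrisome genes; hotspot specs are injected verbatim afterwards so
they survive any `s`.  Sequences are uniform over the 20 amino acids
except at PTM sites, which are forced to chemically valid acceptors
(hydroxylation P/K — collagens only; phosphorylation S/T/Y;
N-glycosylation N; O-glycosylation S/T; lysine modifications K).  PTM
sites are placed binomially at ~12 sites/100 residues with
category-dependent type profiles (collagens hydroxylation-heavy, core
glycoproteins and proteoglycans glycosylation-heavy, the rest of the
genome phosphorylation/lysine-modification-heavy); matrisome category
proportions follow the matrisome-project split.  Domains draw from a
shared 30-family pool so the same domain id recurs in both gene sets.

Two presets define the study conditions for the recovery experiments
(200 genes, 25% matrisome so every category is populated at desk scale,
5 cohorts × 50 samples, ~10⁴ mutations — sizes chosen so each gene
accumulates enough silent counts for a stable per-gene r^dN/dS while a
full replicate set runs in seconds): `neutral()` (s = 0 with a uniform
4-type PTM profile identical in both gene sets, so burden folds and
r^dN/dS carry no built-in signal and each checked type accumulates
≥ 200 hits) and `selected(s=0.8)` (rejection against matrisome PTM
sites only).

What the generator does **not** emulate: genomic coordinates and
signature-dependent mutation spectra, codon structure (mutations are
drawn directly in protein space), copy-number events, inter-gene
correlation of mutation rates, and realistic interaction-network
topology (edges are uniform random).  Passing recovery tests therefore
demonstrates that the statistics detect the encoded selection and
recurrence structure — not that real cohorts satisfy the generator's
independence assumptions.

## Numerical and degenerate-input choices

χ² tests are two-sided Pearson without continuity correction by
default; degenerate 2×2 tables (zero margins) yield a missing p with a
warning.  Pearson correlations require ≥ 3 points and non-constant
vectors, else missing (fewer than 3 cohorts raises).  Zero-denominator
folds and ratios are missing, never ±inf.  Ranking ties in top-gene
tables break alphabetically.  The selection redraw loop is capped at
1000 vectorized iterations (it converges in a handful).  All randomness
derives from a single root seed: generator stages use
`default_rng([seed, stage])`, pipeline stages use a deterministic
child-seed map, so module-level reruns match pipeline runs and rerun
outputs are byte-identical.

The worked-example numbers printed in the README come from the snippet
below run against `run_pipeline`'s returned summary:

```python
c, s = summary["counts"], summary["shares_percent"]
print(f"total mutations        {c['total_mutations']}")
print(f"PTM^mut                {c['ptm_mut']}  ({s['ptm_mut_of_nonsilent']:.2f}% of non-silent)")
print(f"  matrisome / rest     {c['matrisome_ptm_mut']} / {c['rest_ptm_mut']}")
print(f"PTM^mut share          matrisome {s['ptm_mut_of_matrisome']:.2f}%  rest {s['ptm_mut_of_rest']:.2f}%")
r = summary["rdnds"]; cmp = r["comparison"]; ctl = summary["random_control"]
print(f"r_dN/dS geometric mean {r['geometric_mean']:.3f} over {r['n_genes']} genes")
print(f"  matrisome vs rest medians {cmp['median_matrisome']:.3f} vs {cmp['median_rest']:.3f} (Mann-Whitney p = {cmp['p_value']:.2e})")
print(f"100-random-set control p range [{ctl['p_min']:.2e}, {ctl['p_max']:.2e}]")
```

## Known limitations

* The truncation-footprint rule (start residue only) will undercount
  PTM^mut relative to any analysis crediting downstream site loss.
* Raw-count dN/dS has no mutational-opportunity correction; it is a
  comparative statistic between position classes within a gene, not an
  absolute selection estimate.
* Burden folds computed as mean-of-means differ from pooled-count folds
  when site counts are very skewed; both are implemented.
* The generator's neutrality is exact only under its own uniformity
  assumptions; real cohorts violate them (signatures, hotspot genes,
  covariate-driven rates).
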