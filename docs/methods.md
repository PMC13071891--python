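# Methods

## Detection model and its assumptions

The pipeline treats HGT detection as three nested decisions per gene.

**Hit-profile screen.** From the gene's homology hits we first drop hits
with E-value above `evalue_cutoff` (default 1e-5) and hits whose genus is in
`self_taxon_excluded` (default {Euplotes}). Self-hit removal is essential:
a host gene always finds itself and its congeners first, so retaining those
rows would make every best hit eukaryotic and void the rule. The screen
passes iff the retained set is non-empty, its best hit (minimal E-value;
ties by maximal bitscore, then lexicographic subject id — deterministic and
row-order independent) is prokaryotic (Bacteria or Archaea), and the
prokaryotic fraction strictly exceeds `prokaryote_fraction_threshold`
(default 0.5; exactly half fails). "Hits" are retained rows counted once
each; HSP-level multiplicity is the caller's responsibility. An empty
retained set fails with the fraction reported as 0.

**Contamination filter.** A candidate must be demonstrably on a host
molecule: telomeric repeat detected at a contig end, or ≥ 1 intron in the
gene model; either suffices. Genes with neither are treated as bacterial
contamination (metagenome-style assemblies routinely carry such contigs).

**Phylogenetic validation.** With > 5 prokaryotic homologs and none in
eukaryotes the gene is accepted without a tree (verdict `HGT_NO_TREE`; 5 is
not "more than five"). With homologs in both domains the gene tree decides:
the query must fall inside a purely prokaryotic clade with a eukaryotic
outgroup. Because fast ML trees are effectively unrooted, the test is
defined on the unrooted bipartition set: an edge (terminal edges included)
must split the tips into (A, B) with A ⊇ all query tips, A \ QUERY
non-empty and all-prokaryote, and ≥ 1 eukaryote in B. Terminal edges must
be scanned — for a quartet (query, 2 prokaryotes, 1 eukaryote) the only
witnessing bipartition hangs off the eukaryote's own edge, and any
rooted-clade reading of "clade" counts that rooting. A query-only clade
sister to eukaryotes does not qualify (A \ QUERY must be non-empty).
Multiple query tips (in-paralogs) must all fall on the prokaryote side of a
single bipartition. Branch supports are ignored; the test is a pure
function of the topology, hence invariant under rerooting and tip order.
Genes with ≤ 5 prokaryote-only homologs are conservatively rejected
(`UNSUPPORTED`) and flagged for manual review rather than guessed.

`UNSUPPORTED`/`REJECTED` candidates and everything failing an earlier stage
finalize as `NOT_HGT`; the per-gene report retains every intermediate flag
so the reason is always recoverable.

## Telomere detection

The telomere unit is an 8-mer (C₄A₄ and its strand-reading G₄T₄); both
configured motifs and their reverse complements are scanned at both ends.
A tandem run may start at any offset within `telomere_window_bp` (50) of
the end, which also tolerates a ragged partial leading/trailing unit —
macronuclear telomere boundaries are rarely flush with the assembled end.
The right end is scanned as the left end of the reverse complement, making
detection exactly strand-symmetric. A contig "has a telomere" when either
end carries ≥ `telomere_min_units` (2) tandem copies: one full unit (8 bp)
matches by chance once per ~65 kb of random sequence, two tandem units
(16 bp) essentially never on gene-sized contigs, while requiring three
would start costing truncated real telomeres. One telomeric end suffices
for the filter, since nanochromosome ends are often lost in assembly.

## Statistics

* **Wilcoxon rank-sum** (two-sided, statistic = rank sum of the first
  sample). `exact` mode enumerates all C(n+m, n) group assignments of the
  pooled mid-ranks (ties handled by mid-ranks; p = 2·min(tails) capped
  at 1). `normal` mode is the tie- and continuity-corrected normal
  approximation (scipy). `auto` picks exact when min(n, m) ≤ 8, the pool is
  tie-free, and C(n+m, n) ≤ 2·10⁵ — beyond that the enumeration buys
  nothing over the approximation and costs minutes.
* **χ² independence** on the 2×2 intron-containing table: Pearson statistic
  without Yates correction, df = 1, upper-tail p; zero margins are errors.
* **TPM**: tpm_i = 10⁶·(c_i/ℓ_i)/Σ_j(c_j/ℓ_j); sums to 10⁶ by construction
  (relative tolerance 10⁻⁶ asserted in tests).
* **Enrichment**: per term, upper-tail hypergeometric P(X ≥ k) for k study
  hits of a K-gene term in an N-gene universe with an n-gene study set,
  then Benjamini–Hochberg step-up across all tested terms. The universe is
  every screened gene of the genome under analysis, not only annotated
  genes — the conservative choice when the annotation's coverage is itself
  uncertain.
* **Translation** uses the Euplotid nuclear code (NCBI table 10; UGA =
  Cys, stops UAA/UAG only) by default — the standard choice for these
  genomes and the one consistent with stop-exclusive ORF arithmetic
  (1,209 bp ↔ 403 aa); the table id is configurable.

## Donor attribution and families

The donor is the taxonomy of the best retained hit, with the same filtering
and tie-breaking as the screen. Endosymbiont matching is a case-folded
exact genus comparison after stripping "Candidatus " prefixes; phylum names
are taken verbatim from the hit table (no synonym resolution — Proteobacteria
and Pseudomonadota are distinct strings unless the input says otherwise).
Cross-species families are connected components of the bidirectional-best-
hit graph (per gene and partner species, the top-scoring partner, ties by
gene id; an edge requires mutuality and both directed scores ≥ the
threshold). When self-scores are present, scores are normalized to
bitscore ratios first (default threshold 0.5 of self-score). This is a
deliberately self-contained substitute for full orthogroup inference, not a
reproduction of it: single-linkage over BBH edges can merge families that
graph-aware methods would split, which is acceptable for presence/absence
sharing counts but not for fine-grained orthology.

## The synthetic-data generator

The generator emulates the structure the pipeline assumes, at the layer the
pipeline consumes — hit tables and trees are drawn directly; no sequences
are evolved and no alignment or search is simulated. Defaults define the
reference regime used throughout the tests: 200 native, 20 transferred and
10 contaminant genes (seed 1).

* Native and HGT genes sit on single-gene nanochromosomes capped by 3
  tandem telomere units at **both** ends, with 20–40 bp subtelomeric
  spacers; contaminant contigs are telomere-free, intron-free random DNA at
  GC 0.5 (regenerated in the astronomically unlikely event a telomere
  arises by chance).
* GC is controlled per class by weighted base sampling (defaults 0.35 for
  both classes — the "similar GC" regime; divergent GC is configurable).
* Each gene has one 26 bp intron with probability `intron_prob` (0.5),
  shared between native and HGT classes, so the intron-proportion test is
  null by construction. CDS lengths are 3·U{150..499} bp for both classes.
* HGT hit profiles: prokaryotic best hit (the planted donor) and prokaryote
  fraction 0.9; native profiles: eukaryotic best hit, fraction 0.1. Both
  include a deliberately superior *Euplotes* self-hit that the screen must
  exclude. E-values are a descending ladder strictly below the cutoff.
* Half the HGT genes (rounded) carry prokaryote-only homolog counts in
  6..24 (shortcut route); the other half get counts in both domains plus a
  random binary tree nesting the query inside 3–6 prokaryotes with a 2–4
  tip eukaryote outgroup clade (tree route).
* Expression counts are negative binomial with var = μ + 0.3·μ², μ
  proportional to CDS length (200 per kb for natives) and scaled by
  `hgt_expression_multiplier` (0.3) for HGT genes; multiplier 1 is the
  calibration null, dispersion 0 degenerates to the deterministic mean.
* The family layer plants 7 core families spanning all 5 species plus 3
  private families per species, with self-scores 500, within-family scores
  300 (ratio 0.6) and sparse background scores below threshold.
* Donor genera for the endosymbiont-derived genes (default 3) come from a
  genus list of known host endosymbionts; the free-living donor pool is
  disjoint from that list so the configured count is exact.

Every dataset self-validates at generation time: each planted class is
checked against its own defining rules (HGT profiles must pass the screen,
contaminants must fail the contamination filter, planted trees must pass
the placement test), so truth labels are correct by construction. Fixed
seed ⇒ byte-identical output files.

What passing on this generator does **not** show: robustness to borderline
hit profiles (fractions near 0.5), taxonomically misannotated hits, trees
with weakly supported or wrong topologies, chimeric contigs carrying both
host and bacterial genes, or E-value/bitscore distributions of real
searches. The generator separates classes cleanly by design; recovery is
exact because the planted margins are wide, and the end-to-end checks are
integration tests of the decision logic, not a measurement of real-data
sensitivity or specificity.

## Verification scale and numerical choices

The exhaustive placement check compares the edge-scan implementation
against an independent brute-force rooted-clade enumerator on **every**
unrooted labeled topology with 4–8 tips under every assignment of the
non-query tips to prokaryote/eukaryote (≈1.4M verdicts) in the test suite;
the acceptance script repeats it up to 7 tips (61,968 verdicts) to stay
fast. Null calibration uses 200 seeded replicates of 100-vs-100 samples
per test, with the rejection rate at α = 0.05 required to fall inside the
exact binomial 99% interval. Exact-statistic oracles (full rank-sum
enumeration, exhaustive hypergeometric draws for N ≤ 12, independent BH
step-up) are recomputed in the tests, never frozen from the implementation.

Degenerate inputs are errors, not warnings: empty sequences, unknown
superkingdoms (viral hits are rejected at parse time rather than silently
binned — the rules are a binary prokaryote/eukaryote dichotomy and silent
binning would change fractions), unclassifiable tree tips, zero χ² margins,
all-zero count vectors, study genes outside the universe, candidates
missing required trees or homolog counts.

## Known limitations

* The screen is profile-based; compositional (parametric) HGT signals and
  BLASTX-only candidates on unpredicted genes are out of scope.
* The placement test ignores branch supports and treats the topology as
  fixed truth; there is no bootstrap or site-level uncertainty.
* BBH single-linkage families approximate, and can lump, true orthogroups.
* Donor attribution by single best hit inherits every bias of the database
  the hits came from; it identifies a nearest sampled relative, not the
  literal donor lineage.
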