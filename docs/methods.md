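# Methods

## Pairwise alignment and percent statistics

Alignments are global (Needleman–Wunsch) with affine gap cost: a gap of
length L costs `open + L·extend`. The dynamic programme is the three-state
Gotoh formulation, row-vectorised in numpy; the within-row horizontal gap
state is computed in closed form with a running prefix maximum
(`E[j] = −open − j·extend + cummax(G[k] + k·extend)`), so the fill is
O(mn) with no Python-level inner loop.

Defaults mirror EMBOSS Needle for proteins: BLOSUM62 (loaded from
Biopython's `substitution_matrices`; any NCBI/EMBOSS-format matrix file
can be read instead), `open = 10.0`, `extend = 0.5`, terminal gaps free.
With free end gaps the optimum is taken over the last row and column and
trailing gaps are appended at zero cost. Residues outside the matrix
alphabet score a configurable default (−1).

Reported statistics follow the EMBOSS Needle report: percent identity =
identical columns / alignment length, percent similarity = columns whose
residue pair scores > 0 (identities always counted) / alignment length,
percent gaps = gap columns / alignment length, all over the full
alignment including terminal gaps. The conservation map uses percent
similarity by default; identity is a config switch.

Traceback ties are broken in a fixed order (match column, then gap in the
second sequence, then gap in the first). Co-optimal global alignments can
differ in *length* when end gaps are free, which would make the percent
statistics depend on argument order; the aligner therefore canonicalises
the argument order internally (lexicographically smaller sequence first)
and swaps the gapped strings back, making score **and** statistics exactly
symmetric while staying fully reproducible.

## Similarity map

Cell (g, s) is the chosen percent statistic of the alignment between
reference gene g and its ortholog in organism s. When the ortholog table
maps one (gene, organism) pair to several sequences the best hit
(maximum) is used — the conservative answer to "how conserved is this
gene here" — with `mean` available as an alternative. Orthology itself is
always an input; the package does not infer it.

Absent orthologs are written as 0, matching the heatmap convention in
which lineage-restricted genes show blocks of zeros in distant organisms,
and the clustering stage operates on these raw zero-filled values.
Because a zero from absence and a zero from extreme divergence are
different facts, a boolean presence mask is carried through the TSV
round-trip (sidecar `*.mask.tsv`); it is informational and does not enter
the distance computation.

## Two-way clustering

Both axes are clustered agglomeratively with Euclidean distance between
raw percent-similarity profiles (no standardisation) and complete
linkage. The agglomeration is written out longhand (Lance–Williams
max-update) rather than delegated to `scipy.cluster.hierarchy`, because
the tie rule is part of the reproducibility contract: among equally close
cluster pairs, the pair whose members contain the smallest original leaf
indices merges first, so duplicated rows agglomerate in input order.
scipy's implementation serves as an independent cross-check in the test
suite, alongside a naive oracle that re-scans original leaf pairs at
every step. Complete linkage is monotone; non-decreasing merge heights
are asserted on every dendrogram construction.

Cluster counts are user choices (defaults: 4 gene clusters, 3 organism
clusters); no automatic cut-height selection is attempted, since any such
rule would be arbitrary for this data shape. `cut_tree(k)` removes the
k−1 highest merges; `leaf_order` is the in-order traversal visiting the
subtree with the smallest original leaf first; Newick export writes
branch lengths as parent height − own height, with metacharacter labels
quoted.

## Enrichment

Annotations are closed under the true-path rule before testing (a gene
annotated to a term is annotated to all its is_a ancestors). Term depth
is the shortest is_a path to any root; reporting is restricted to depths
4–5 by default — the common compromise between specificity and
cross-organism comparability — and the window is configurable.

For each testable term (reference count K ≥ 1, depth in range), the
sample count k out of n is tested against Binomial(n, p0 = K/N) with
exact tails (`P(X ≥ k)` and `P(X ≤ k)` via scipy's binomial
distribution). Both tails of every testable term enter the Bonferroni
family: `p_adj = min(1, T·p)` with T = 2 × number of testable terms, and
a term is significant when either adjusted tail is ≤ α (default 0.05).
The binomial is the named test of record for this analysis even though
gene sampling is without replacement; the hypergeometric is available via
`method="hypergeom"` and agrees closely whenever n ≪ N. Tissue labels are
tested identically as flat categories (no DAG, no depth filter).

The resampling control draws `n_reps` gene sets of `set_size` uniformly
without replacement from the reference (defaults 30 × 200, the
conventional scale for this control) and re-runs the full enrichment on
each; the report is the per-repetition count of significant terms and its
total. Bonferroni control at α = 0.05 makes any positive a < 5%
family-wise event per repetition, so an unstructured annotation universe
should, and in the seeded runs does, return a total of zero. Inside the
pipeline the control's set size is capped at the analysed gene list
(default 30 of 60 genes), since the desk-scale universe is smaller than
200; the 30 × 200 control runs against the 1000-gene null universe in the
acceptance script.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a real comparative study:

* **Reference proteome** — i.i.d. uniform residues over the 20 standard
  amino acids; `n_genes = 60`, `protein_length = 200` by default.
* **Species panel** — a star phylogeny of 9 organisms in 3 complexity
  groups with branch lengths 0.10–0.20 (high), 0.55–0.75 (medium) and
  1.30–1.60 (low) expected substitutions per site, spanning near-identical
  to deeply diverged orthologs.
* **Gene tiers** — 4 tiers of 15 genes with rate multipliers 0.3 / 1.0 /
  1.6 / 2.2; tier III is additionally deleted in the low-complexity group
  and tier IV in both the medium and low groups, reproducing the
  zero-filled blocks that characterise lineage-restricted genes. Group
  separations are deliberately wide so that recovery of the planted
  partitions is the expected outcome, not a coin flip.
* **Substitution model** — Poisson(branch × multiplier × length) point
  substitutions at uniform positions, replacement uniform over the other
  19 residues, plus Poisson(indel_rate × length) single-residue indels
  (default rate 0.01). Sites can be hit repeatedly, so expected identity
  saturates toward the random-alignment baseline rather than reaching 0.
  There is no rate matrix, no site heterogeneity, no codon structure and
  no duplication/paralogy — graded divergence is all the downstream
  statistics need, and anything more would be false precision here.
* **Ontology** — a single-rooted DAG with six terms at each depth 1–6
  (occasional double parents make it a DAG, not a tree). One term per
  tier is planted at depth 4; genes of that tier are annotated to it with
  probability 0.9, and every gene is annotated to background terms at
  rate 0.05. Planted terms sit at a single depth so none is an ancestor
  of another, and their descendant subtrees are excluded from background
  annotation — otherwise true-path propagation funnels background signal
  into a planted term and dilutes the contrast the benchmark exists to
  measure. Tissue labels are flat categories planted per tier (kidney and
  adrenal for the conserved tiers, nervous system for the
  lineage-restricted ones) over a 10% background.

Passing tests on this generator demonstrate that the machinery —
alignment statistics, linkage, counting, tail probabilities, multiple
testing, determinism — is correct and that planted structure of realistic
magnitude is recovered. They do not demonstrate anything about real
proteome evolution: real substitution processes, ortholog-calling errors,
annotation bias and ontology shape are all richer than the simulation.

## Numerical and design notes

* One integer seed drives everything (numpy `default_rng` /
  `SeedSequence`); identical configs give byte-identical text artifacts,
  asserted in the acceptance suite.
* DP traceback matches use a 1e-9 tolerance; scores are sums of matrix
  integers and half-unit gap penalties, so this never misidentifies a
  predecessor state.
* Dendrogram height monotonicity allows 1e-9 slack for floating-point
  ties; degenerate inputs (all-identical profiles) merge at height 0 in
  input order.
* `binomial_test` with p0 ∈ {0, 1} returns the degenerate-distribution
  limits (e.g. P(X ≥ 1 | p0 = 0) = 0) rather than NaN.
* Terms with K = 0 are untestable and skipped; an empty depth window
  produces an empty result with an explicit warning rather than an error.
* Problem sizes throughout (60 × 9 study, 8-leaf oracle instances,
  1000-gene null universe, 200-draw calibrations) are chosen so the whole
  test suite and the acceptance script each complete in well under a
  minute on one CPU while still exercising every code path at
  statistically meaningful scale.

## Known limitations

* The aligner is O(mn) memory; fine for proteins, not meant for genomic
  sequences. No local alignment, no Hirschberg variant.
* Complete-linkage agglomeration is O(n³) in pure Python — ample for
  hundreds of leaves, not for tens of thousands.
* Enrichment treats the reference as fixed and exhaustive; no propagation
  of annotation uncertainty, no FDR alternatives beyond Bonferroni, no
  term–term redundancy pruning.
* The heatmap rendering is cosmetic (existence is tested, pixels are
  not), and dendrogram leaf order is not optimised for display (no
  optimal-leaf-ordering rotation), so two visually different heatmaps can
  encode identical partitions.
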