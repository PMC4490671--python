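# Methods

This note documents the models and procedures implemented in
`virocurate`, the defaults they use, and the choices made where the
underlying workflow left the design open.

## Pooling and redundancy removal (`dedup`)

Contigs from several k-mer assemblies of one virome are pooled (minimum
export length 5 kb; contigs below the 1 kb assembly cut-off are not
admissible at all) and redundancy is removed from the pool. A
self-comparison hit qualifies per HSP when its aligned length is
strictly greater than 1000 bp, identity ≥ 97 % and E ≤ 10⁻⁵; several
shorter HSPs never sum to a qualifying match, because the criterion
names a single hit. The sweep runs once over the pool in descending
length order (ties broken by id): a contig is removed iff it has a
qualifying hit to a strictly longer contig that is *still retained* when
the sweep reaches it. Matching against the retained set rather than
against all longer contigs prevents cascade removal through contigs that
were themselves discarded (A > B > C with B ≈ A and C ≈ B only: B is
removed, C survives because its only partner is gone); the
all-larger-contigs behaviour is available via `retained_only=False`.
Equal-length mutual pairs keep the lexicographically earlier id — a pure
determinism tie-break. The self-comparison itself (Megablast-style, word
size 100) is an external input consumed as 12-column tabular hits;
`find_exact_containments` is a naive quadratic oracle used only to
verify planted redundancy in tests.

The candidate gate keeps linear contigs ≥ 15 kb and circular contigs
≥ 10 kb, and rejects anything under 10-fold mean coverage (chimera
risk). Both reasons are reported when they co-occur.

## Circularity (`circularity`)

Read pairs mapped to the linearised scaffold are partitioned by their
apparent span — the outermost distance between the two alignment
intervals. Spans above 900 bp (the upper end of the 0–900 bp mapping
distance range, comfortably above a 400 ± 80 bp insert) are discordant.
A discordant pair is *circularly mapped* when one mate's alignment lies
entirely within the first `end_window` = 1000 bp and the other entirely
within the last 1000 bp; three or more such pairs call the scaffold
circular. Choices within this rule:

* **Both terminal windows are required** (one mate in each). The
  alternative reading — "the discordant distance is within 1000 bp of
  the scaffold length" — is subsumed by this stricter geometric form.
* **Containment is by full alignment interval**, not midpoint; with
  100 bp reads the difference is at most one read length and the
  interval form is conservative.
* **Orientation is not checked** by default; `require_fr=True` demands
  the reverse-forward orientation that true origin-crossing pairs show.
* **Short scaffolds** (≤ 2 windows) truncate the windows at the midpoint
  and flag the call `short_scaffold` rather than refusing it.
* Duplicate fragments are counted as given; no PCR-duplicate collapsing
  is attempted.

Terminal-overlap detection returns the longest exact prefix–suffix
repeat ≥ 20 bp (at most half the sequence). A chance 20-mer repeat in a
random 30 kb sequence has probability ≈ 3 × 10⁻⁸, so the threshold is
effectively specific.

## Triage (`triage`)

Because most viral genes match nothing, per-database gene-hit counts are
normalised to the number of genes with a Pfam-A hit (E < 10⁻⁵) rather
than to all gene predictions. Rules are evaluated in a fixed precedence:

1. coverage < 10× → `low_coverage_reject`;
2. ≥ 1 Silva SSU/LSU hit → `cellular_review`;
3. mitochondrion hits > 50 % of Pfam hits → `mito_review`;
4. ACLAME plasmid hits > 50 % of Pfam hits → `plasmid_review`;
5. ≥ 1 hit to the phage-exclusive POGs-7 families → `viral`;
6. RefSeq-virus ≥ 50 % **and** POGs-10 ≥ 10 % of Pfam hits → `viral`;
7. otherwise `ambiguous`.

The precedence is a design choice: the source workflow does not say what
happens when a scaffold satisfies the viral rule *and* carries an rRNA
hit. Contamination flags are ordered first because flagged scaffolds
were manually inspected in the original procedure — a review label here
is a queue, not a verdict, and can be overridden downstream. Two further
interpretation choices: the POGs-7 criterion is implemented as ≥ 1 hit
(the printed "≥ 0" is vacuous and contradicts the prose, which uses
POGs-7 to positively assign scaffolds), and the mitochondrion ratio uses
Pfam hits as denominator even though the mitochondrion search is
scaffold-level, because all ratios are stated to be normalised to the
Pfam-A hit count. With zero Pfam hits the ratio rules evaluate false
(noted in the rationale), never divide.

Batch summaries print per-database gene-hit percentages at one decimal
place and the confirmed-viral fraction of candidates; virome-level read
fractions (in `summaries`) use mixed precision — ≥ 1 % to one decimal,
< 1 % to two, integer mode for headline shares — matching how such
tables are conventionally printed.

## Genome comparison (`distance`)

Qualifying translated hits (> 30 % identity, ≥ 30 aa, E < 0.01; the
identity and E-value cuts are strict inequalities) have their bitscores
summed per genome pair; hits in both search directions accumulate into
the same unordered pair, making S symmetric by construction (a
directional mode averages the two directions instead). Similarity is the
self-score-normalised Dice coefficient
D(a,b) = 2 S(a,b) / (S(a,a) + S(b,b)); a genome with zero self-score
cannot be normalised, is flagged, and gets D = 0 against everything.

Neighbor joining is implemented directly (Saitou–Nei, O(n³)) so that its
determinism is under our control: when several pairs minimise the
Q-criterion, the lexicographically smallest pair of cluster labels (each
cluster labelled by its smallest leaf id) is joined. Negative branch
lengths are clamped to zero with the deficit moved to the sibling
branch — standard practice — while the raw lengths are kept in a side
channel. On additive matrices the implementation recovers the generating
tree's topology and branch lengths exactly (NJ is consistent), which the
tests verify against path-length matrices of randomly generated trees
and against an independent implementation.

Genome groups are single-linkage connected components of the graph with
edges D ≥ threshold; genomes in no group are reported as singletons.
The grouping threshold is a free parameter (default D ≥ 0.05) — the
original clustering criterion is not stated, so the default is
deliberately permissive and exposed on the interface.

## Host links (`hosts`)

attP detection reports every maximal, 100 %-identity shared substring
≥ 25 bp between a scaffold (either strand) and a taxon-annotated tRNA
database, via a seed table over the whole database and bidirectional
exact extension — for exact hits this is equivalent to a BLASTN search
filtered at 100 % identity. The 25 bp floor is a design choice: observed
genuine attP matches run 28–60 bp, while exact matches much below ~20 bp
arise by chance against large databases. Assignment requires an
annotated integrase gene on the scaffold (keyword match in the gene
annotations, configurable); matches without one go to a side table.
Because tRNA genes are conserved, taxa are reported at class (or phylum)
rank only, and scaffolds matching tRNAs from different phyla are flagged
ambiguous with all taxa reported. Whether the match must be intergenic
is not constrained — planted and real attP sites may overlap gene calls.

CRISPR arrays are inputs (array detection is an upstream tool); spacers
are matched exactly and full-length on both strands against all contigs,
excluding hits inside the source array's own locus. Spacers under 15 bp
are searched but trigger a chance-match warning.

## Synthetic communities (`synthetic`)

The generator emulates the features downstream stages key on, and only
those:

* **Sequencing design**: 100 bp paired-end reads, 400 ± 80 bp inserts, a
  60–650 bp concordant range and ~40× mean coverage — the conditions the
  pipeline's thresholds assume. `pairs_for_coverage` converts coverage
  to a pair count (cov·L / 2·read length).
* **Circular genomes**: fragments are drawn uniformly on the circle; a
  fragment crossing the origin has its mates reported at wrapped
  linearised coordinates. When a single mate would itself straddle the
  origin the fragment is nudged into the inter-mate gap, preserving the
  number of origin-crossing fragments exactly (expected n·insert/L), so
  the wrap statistic the detector relies on is unbiased.
* **Genes** are 900 bp windows laid head-to-tail, content-free except
  planted motifs; triage consumes counts, not sequences.
* **Class regimes**: hit tables are emitted directly from
  class-conditional profiles (viral: RefSeq-virus on 70 % and POGs-10 on
  25 % of Pfam-hit genes; cellular: 2 Silva hits; plasmid: ACLAME on
  70 %; mitochondrial: mitochondrion hits on 80 % of the Pfam count) —
  comfortably inside each decision region, so triage must recover every
  class exactly. Pfam hits cover 55–60 % of genes, in the range observed
  for real virome assemblies.
* **Planted truth**: redundant contigs are verbatim substrings (≥ 5 kb,
  half the donor) of distinct donors; attP segments are 28–60 bp copied
  verbatim from database tRNAs onto integrase-bearing phages; CRISPR
  arrays use a 29 bp repeat and 32 bp spacers with one spacer copied
  onto another phage. Planted intervals never overlap one another.
* **Determinism**: one root seed; every scaffold and every planting step
  draws from its own spawned stream, so adding scaffolds does not
  perturb existing ones and equal specs produce byte-identical FASTA.

Not modelled, deliberately: sequence evolution (redundancy is 100 %
identity rather than ≥ 97 %), base-call error and quality values,
abundance distributions, chimeras, and repeat structure. Passing the
synthetic suite therefore demonstrates that the decision logic,
coordinate arithmetic and exact-matching machinery are correct under the
stated sequencing design — not that the thresholds themselves are robust
to divergent real-world data, which only external benchmarking could
show.

## Problem sizes and numerics

The test suite and the acceptance script run communities of 20–50
scaffolds of 16–40 kb with coverage-matched read simulation (roughly
10⁵–2·10⁵ pairs end-to-end), 10⁴ random profiles for the triage
equivalence check, and trees of up to 8 taxa for exact NJ verification —
sizes at which every oracle (brute-force scans, substring enumeration,
independent NJ) is exact and fast. Percent values are rounded with
half-up decimal arithmetic to match printed tables; NJ comparisons use
absolute tolerances of 10⁻⁸ on branch-length sums; Dice matrices are
validated to be symmetric within 10⁻⁹.

## Known limitations

* Review labels (`cellular_review`, `plasmid_review`, `mito_review`)
  model queues for manual follow-up (BLASTX against GenBank NR,
  mitochondrial annotation); the follow-up itself is out of scope.
* The terminal-overlap scan is exact-match only; diverged or gapped
  terminal repeats are not detected.
* Spacer matching is exact and full-length; the biology tolerates a few
  protospacer mismatches, so sensitivity on real data is conservative.
* GAAS-style abundance estimation is iterative; `normalize_composition`
  implements the plain hit-count / genome-length ratio, which is the
  operation actually described for the composition tables.
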