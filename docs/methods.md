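# Methods

## The co-localization model

The pipeline treats literature evidence as geometry on the B73 RefGen_v4
physical map. A QTL is a closed 1-based interval delimited by the physical
positions of its two flanking markers; a QTN is a point. Three stacked rules
turn these into consensus regions:

* **QTL cluster** — a connected component of pairwise interval overlap with
  at least `min_qtl_members = 3` QTLs, per trait per chromosome.
* **QTN cluster** — a region where a sliding window of `qtn_window = 5 Mb`
  holds at least `min_qtn_count = 5` QTNs, per trait per chromosome.
* **Hotspot** — a connected overlap component of at least
  `min_hotspot_clusters = 3` clusters, pooled across all traits and kinds.

The underlying assumption is that independent mapping studies of a real
causal locus produce intervals or hits that physically co-localize, while
scattered false positives do not recur; the rules are deliberately
count-based and use no effect sizes, p-values or LOD scores (those fields
are carried as metadata only).

### Interpretation choices

Component (transitive) overlap, not clique overlap, defines co-localization:
a chain a∩b, b∩c groups {a, b, c} even when a and c are disjoint. This is
the behaviour of `bedtools merge` at distance 0, the field's reference tool
for the operation, and it is what makes published cluster spans wider than
any single member. Touching-but-not-overlapping intervals (end + 1 = start)
are not merged — co-localization requires at least one shared nucleotide.

The QTN window slides continuously. Since a window boundary only matters at
a data point, candidate windows are anchored at QTN positions, which is
exactly equivalent to a 1-nt stride without the arbitrary step parameter.
Qualifying windows that overlap are chained, and the chained region is
trimmed to the extremal member positions, so cluster spans are data-defined
and may exceed one window length. Each qualifying window individually holds
≥ 5 QTNs; the chain as a whole is not re-tested (the alternative —
re-testing every sub-window of the chain — would discard regions the
per-window rule already accepted).

A hotspot's extent is the union span of its member clusters, and numbering
is genome-ordered (chromosome, then start). Cloned genes are co-located into
hotspots by any overlap (≥ 1 nt), the least arbitrary containment rule;
genes without physical coordinates (the cloned-gene survey prints only the
chromosome) are skipped with a logged warning.

Spans in megabases are reported as (end − start)/10⁶ with half-up rounding.
This difference convention, not the inclusive length (end − start + 1),
reproduces the published span figures exactly.

## Candidate screening

Kernel specificity is summarised by MaxExp (max FPKM over all tissues) and
MaxExpKernel (max over the designated kernel tissues); their ratio is ≥ 1
whenever defined and equals 1 for genes that peak in kernels. The filter
keeps genes with MaxExpKernel ≥ 50 FPKM and ratio ≤ 3, both bounds
inclusive. Genes with no expression data are excluded from the pass/fail
partition and tallied separately. Which tissues count as "kernel" is a
configuration input, not a constant, because expression atlases differ in
how they split kernel sub-tissues; the simulator's panel uses whole kernel
at two stages plus embryo and endosperm.

Histogram bins for reporting follow the survey convention: MaxExpKernel in
{>500, 200–500, 100–200, 50–100, 20–50, 10–20, <10} with ">500" strict and
each lower edge inclusive (so 500 falls in 200–500), and ratio in
{=1, (1,3], (3,5], >5}.

PPR (pentatricopeptide-repeat) genes — the dominant family among cloned
kernel-development genes — are detected in annotation text by a
case-insensitive match of "pentatricopeptide" or "PPR" as a whole token;
token boundaries prevent substring artefacts ("suppressor" does not match).

## GO enrichment

Over-representation is the one-sided upper-tail hypergeometric probability
P(X ≥ k), computed through `scipy.stats.hypergeom.sf` (log-space stable),
with Benjamini–Hochberg FDR from `statsmodels` across all terms that have at
least one study hit. The default background is the set of all annotated
genes in the provided table, the significance threshold FDR ≤ 0.05. GO-graph
ancestor propagation is not performed: the annotation table is taken as
given. Output ordering is (p-value, term id), making results invariant under
permutation of the input.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
dense co-localized loci over a sparse background — not maize linkage
disequilibrium, allele frequencies or effect sizes, which the rules never
consume. What passing tests show is therefore that the inference rules
recover exactly the planted co-localization geometry under the stated
separation conditions; they say nothing about marker quality, population
structure, or the curation errors of real literature tables.

Each planted locus is a ~1 Mb core region. Clusters planted at a locus get
distinct (trait, kind) combinations — at most 8 = 4 traits × 2 kinds,
because two same-trait clusters at one locus would merge under per-trait
clustering. Every planted QTL interval contains its locus core (so members
mutually overlap), with widths log-normal, median 5 Mb, σ = 0.5, capped at
9 Mb; every planted QTN falls within ±1.25 Mb of the core, so each QTN
cluster fits one 5 Mb window. Locus cores are rejection-sampled with ≥ 20 Mb
edge separation; with the 9 Mb width cap, intervals from neighbouring loci
can never touch, which is the recoverability guarantee behind the
precision = recall = 1 acceptance runs. Background QTLs/QTNs are placed
uniformly (chromosome weighted by length) and rejected within 20 Mb of any
locus, so background can create spurious clusters but cannot corrupt planted
ones.

Default conditions: 5 loci, 4 clusters per locus, 6 QTLs / 8 QTNs per
cluster, 60 background QTLs, 100 background QTNs, and a 25 % blanked-marker
rate applied per QTL — the unprojectable fraction observed in curated
collections. Noise-free recovery runs set the rate and background counts to
zero. Expression profiles are generated with known pass/fail labels: passing
genes draw a kernel peak from a log-normal (median 200 FPKM) truncated at
50, with other tissues scaled by factors ≤ 3; failing genes either stay
below 45 FPKM in kernels or get one non-kernel tissue at 3.5–8× the kernel
peak. One GO term is planted on the in-locus genes as a positive enrichment
control.

All randomness derives from a single seed through per-table substreams
(`numpy.random.SeedSequence.spawn`), so the same seed gives byte-identical
tables and enlarging one table does not perturb the others.

Recovery is scored by greedy one-to-one interval matching at reciprocal
overlap ≥ 0.5, with (trait, kind) required to agree for clusters; precision
and recall are matched/predicted and matched/expected respectively, defined
as 1.0 on empty denominators.

## Numerical and degenerate-input choices

* Interval validation is strict: 1 ≤ start ≤ end ≤ chromosome length;
  a QTL whose two markers coincide projects to a 1-nt interval rather than
  being rejected; marker pairs in reversed physical order are swapped
  silently (genetic-map orientation routinely disagrees with physical).
* Unknown trait symbols and duplicate record IDs are errors naming the row,
  never silent drops — curation mistakes must surface.
* Empty inputs propagate cleanly: empty tables give empty reports, zero
  clusters, zero hotspots, all-zero summaries, and exit success.
* Half-up decimal rounding (not banker's) for reported megabase spans.
* Cluster and hotspot naming is fully determined by (chromosome order,
  start, end), so re-runs are byte-identical; ties on identical intervals
  are broken by input order, which is itself deterministic.

## Problem sizes

Oracle-equivalence suites run the sweep-line merge against an O(n²)
overlap-graph oracle on 100 random instances of up to 500 intervals, the
window clustering against an exhaustive anchored-window oracle on instances
of up to 300 points, and the hypergeometric tail against full subset
enumeration for backgrounds up to N = 12. Planted-recovery acceptance uses
20 noise-free simulations of 5 loci each. These sizes exercise every
branch of the algorithms while keeping the whole suite in the
tens-of-seconds range.

## Known limitations

* The published headline inference counts (1082 projected QTLs, 187 QTL
  clusters, 84 QTN clusters, the specific 31 hotspots, 85 PPR genes, 148
  candidates) depend on supplementary collections, the full genome
  annotation and an external expression atlas that are not redistributable
  here; the package validates the rules on the in-survey tables and on
  synthetic data instead, and ships the published hotspot table as a fixture.
* No maximum cluster width is enforced; very long overlap chains merge into
  one cluster by construction.
* Whether projected spans should be trimmed by reported confidence intervals
  is unknowable from the survey; the raw flanking-marker span is used.
* Chained QTN regions are not re-tested for per-window density (see above).
* GO enrichment does not propagate annotations up the ontology graph.
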