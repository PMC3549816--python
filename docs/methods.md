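# Methods

## Mapping model and coordinates

A paired-end mapping is reduced to four numbers: chromosome, the position
just past the left read's alignment (`left_inner`), the start of the right
read's alignment (`right_inner`), and the outer span `d` from the first base
of the left read to one past the last base of the right read. Coordinates
are 0-based and half-open internally; the cluster table converts to 1-based
inclusive. With a per-sample fragment-length model N(μ, σ) — estimated
upstream from concordant pairs and supplied in the sample config — a mapping
is *stretched*, hence potentially deletion-supporting, when
`d ≥ μ + k·σ` (`--stretch-sds`, default k = 3).

Filters applied to BAM input before clustering: both mates mapped to the
same chromosome in forward–reverse orientation, mapping quality ≥ 20 on both
mates (`--min-mapq`; applied per mate, the stricter reading), gap-free and
unclipped alignments (CIGAR ops M/=/X only), and unique placement (MAPQ > 0
and no alternative-hit tag; the tag list is configurable, default `XA`).
Duplicate removal is left to upstream tools; `--dedup` enables optional
exact-duplicate collapsing. Pairs with an empty inner gap
(`left_inner ≥ right_inner`) are dropped: their geometric representation is
degenerate.

## Geometric representation and similarity

A cluster is a triangle `{(x, y): l ≤ x ≤ y ≤ r}` in the (deletion start,
deletion end) plane with height `pdf(y − x; μ_c, σ_c)`. The height is
constant on lines parallel to the diagonal, so the volume is computed by
traversing the triangle from its hypotenuse: at integer size offset `s` the
line has length `w − s` (`w = r − l`), giving

    V(C) = Σ_{s=0}^{w−1} (w − s) · pdf(s; μ_c, σ_c).

The discrete 1-bp sum is the normative definition (the per-score cost is
O(r − l)); tests verify agreement with fine-grid numerical integration to
within 0.5% for σ ≥ 5 on clusters whose ridge lies inside the base — the
realistic case, since read placement always leaves slack between the ridge
and the triangle corner. The constant line-length factor √2 is omitted: it
cancels in the similarity ratio. The intersection volume uses the pointwise
minimum of the two heights over the intersected base. Similarity is
`V(C₁)∩V(C₂) / max{V(C₁), V(C₂)}`.

Numerical choices:

* The normal pdf is evaluated directly; underflow far from the ridge is left
  at zero, so a touching pair whose score underflows is treated as
  non-overlapping. The stop threshold makes this immaterial.
* `s` runs over `[0, w−1]`; the `s = w` line has zero length, so the
  inclusive/exclusive choice changes nothing.
* Volumes are cached on the cluster and computed at most once per cluster
  lifetime (clusters are immutable after creation).

## Merge rule

Bounds intersect (`l = max`, `r = min`) — average-link on the geometry — and
the variance update is the population rule for pooling two sub-populations:
`σ² = (n₁σ₁² + n₂σ₂²)/n + n₁n₂(μ₁−μ₂)²/n²`. The variance is deliberately
*not* shrunk by cluster size (no σ²/n): shrinking would make large clusters
geometrically narrow and bias the agglomeration order toward cardinality
rather than similarity. The pairwise update is applied incrementally during
clustering; for unequal sub-cluster sizes the result can depend on merge
order, which is accepted as inherent to the published update rule — only
the pairwise contract is tested.

## Agglomeration and the stop threshold

Each region (connected component of genomic-footprint overlap; footprint =
`[outer start, outer start + d)`, half-open) is clustered independently.
The engine keeps a max-heap of candidate pair scores with lazy invalidation
(a heap entry is valid iff both cluster ids are still alive — clusters are
immutable, so scores never go stale in value), merges while the maximum
score strictly exceeds S_min, and after each merge scores the new cluster
only against triangle-overlapping survivors (scores to the rest are
provably zero). Equal scores are broken toward the lexicographically
smaller (older) cluster-id pair, making results deterministic and
order-independent. Cost: O(N² log N) score computations per region. Tests
verify exact partition agreement with a naive engine that rescans all pairs
at every step.

S_min is estimated globally in a preprocessing pass: for every mapping, the
smallest strictly positive similarity to another mapping in its region;
S_min is the median of these minima. For an even count the lower central
value is taken, so the threshold is always an observed score. If no mapping
has a positive score to any other, a fallback of 0.5 is used (no merge is
possible then anyway).

**Scale dependence of the estimate.** The estimator's median reflects how
many weakly-overlapping mapping pairs the data contains. Full-scale data —
hundreds of variant loci with realistic (clustered) placement, plus
aligner artifacts — contains a large population of barely-overlapping pairs
with tiny positive scores, which pushes the median to ~10⁻³. The clean,
uniformly placed, well-separated desk-scale simulations in this package
lack that population, and the estimate lands around 0.03–0.07 — above the
score (~0.02) at which a deletion's main cluster absorbs small satellite
clusters formed by fragment-length-tail mappings, so single deletions can
split. The desk-scale benchmark of overlap separation therefore runs the
clustering at a fixed operating threshold of S_min = 0.002, the value the
data-driven estimator yields on full-scale data for this scenario; the
estimator itself remains the pipeline default and is verified against a
brute-force implementation. The recovery and outlier studies use the
default estimate, which they are insensitive to.

## Synthetic data

The simulator emulates paired-end sequencing of a multi-haplotype donor at
the mapping level; read sequences and alignment are not modelled, since a
cleanly aligned stretched pair is fully determined by fragment placement.
Defaults describe a typical short-read experiment on a mixed diploid
sample: 4 haplotypes (two diploid copies), fragment length N(300, 35),
read length 100, minimum deletion size 105 (below which stretched pairs
become indistinguishable from fragment-length noise at 3σ filtering),
deletion sizes log-uniform on [105, 10000] (a stand-in for an empirical
size list, which can be supplied as a file), coverage 20× per haplotype,
500 single loci plus 500 overlapping pairs on a 249 Mb chromosome.
Overlapping pairs come in two zygosity modes: both partners homozygous in
their copy ({0,1} vs {2,3}), or one homozygous and one heterozygous
({0,1} vs {2}); partner overlap fraction is uniform on [0.2, 0.8]
(configurable — empirical overlap statistics for real variant pairs are
not well characterised).

Fragment starts follow a Poisson process at rate `coverage / (2·read_length)`
per donor bp. For efficiency the process is sampled only inside the windows
upstream of deletion junctions from which a spanning pair can arise
(fragment length truncated below at 2·read_length, where a fragment
degenerates to abutting reads, and above at μ + 6σ); this is an exact
restriction of the generative model for the stretched output. A fragment
whose reads cleanly flank one or more junctions on its haplotype projects
to a stretched mapping with `d = fragment length + deleted bases spanned`;
fragments whose reads would cross a junction are discarded, as they would
not align cleanly. Two optional imperfections: spurious "noise" mappings at
a configurable expected count per true deletion (position near a random
locus, span uniform above the stretch cutoff — a crude model of alignment
artifacts), and breakpoint-free pairs from the long fragment-length tail
(`emit_tail_background`, off by default), which at 20×+ coverage otherwise
dominate the call set with two-mapping false clusters.

What passing the simulation studies does **not** show: robustness to
alignment noise that is position- or sequence-correlated, to mis-estimated
fragment models, to duplicate pairs, or to the clustered locus placement of
real genomes — the generator places loci uniformly with a configurable
margin and emits ideal coordinates.

## Evaluation

Truth deletions are grouped into loci (connected components of reference
overlap). A cluster with `n ≥ min_support` *matches* a deletion when its
bounds contain it (`l ≤ start`, `end ≤ r`) and `|size − μ_c| ≤ 3σ_c` — a
rule built purely from the reported cluster fields. Each supported cluster
is assigned to one locus: the locus of its matched deletions, else (no
size-consistent match) the locus its `[l, r]` interval overlaps most — so a
vague cluster spanning a whole pair still counts as one (wrong) prediction
there — else it founds a false locus, grouped with other such clusters by
mutual overlap. A locus predicted by exactly one / two / three-plus clusters
is classified single / pair / multi. Rates:

    TPR1 = #(single → single) / #singles
    FPR1 = #(→ single elsewhere) / (#pairs + #false loci)
    TPR2 = #(pair → pair) / #pairs
    FPR2 = #(→ pair elsewhere) / (#singles + #false loci)

Mis-assignment is measured over pairs resolved into two clusters matching
the two distinct partners: the fraction of member mappings whose
haplotype-of-origin deletion is not the one their cluster matched (noise
mappings excluded). Zero denominators yield NaN, never a crash.

## Output

The cluster table is TSV (chrom, region, cluster, l, r, μ, σ, n, one count
column per sample, below-min-support flag; full float precision so parsing
round-trips exactly), with a members companion file. Per-region plots draw
each mapping's triangle in its sample's color, Gaussian height as ≤16 gray
bands at equal pdf quantiles, supported clusters as yellow trapezoids
spanned by l, r, μ−3σ, μ+3σ (clipped to the triangle and the diagonal)
labeled with n, and below-support mappings dotted. Plots are rendered
directly to PNG/PDF/SVG rather than emitting a plotting script.

## Problem sizes used in the shipped studies

The acceptance studies run at desk scale: 50 single + 25 pair loci
(scenario studies) or 100 single loci (recovery) on 20–50 Mb chromosomes at
20× per haplotype, sizes log-uniform [105, 5000], pair partners ≥ 3σ apart
in size where stated. These sizes keep every study in seconds while leaving
≥ 10 mappings per deletion copy, the regime the method is designed for.

## Known limitations

* Only deletions: no insertions, inversions, translocations or copy-number
  output, and no split-read or coverage evidence.
* Breakpoints are reported as regions `[l, r]` with a size distribution,
  not base-pair-resolved calls; no VCF export.
* The σ² merge rule's order dependence means region results are
  deterministic but not invariant to hypothetical alternative merge orders.
* The data-driven threshold needs data with a realistic background of weak
  overlaps; on small clean instances it is conservative (see above).
* Overlapping deletions closer than ~3σ in size are fundamentally hard to
  separate with fragment-length evidence alone and may merge into one call.
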