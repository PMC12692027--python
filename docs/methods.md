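# Methods

## Coordinate model and interval primitives

All coordinates are 0-based half-open (`[start, end)`), the BED dialect:
every track consumed or emitted is BED, and mixing conventions is the
classic source of off-by-one errors in interval arithmetic. Consequences
that follow from the convention:

* two intervals sharing only a boundary base-pair coordinate
  (`[0,100)`/`[100,200)`) overlap by 0 bases;
* merging treats bookended intervals as mergeable (`[0,10)+[10,20)` →
  `[0,20)`), matching the default behaviour of the standard BED toolchain;
* the set-level Jaccard is computed on merged covers: intersection bases /
  union bases, with an empty union defined as 0.

Strand is parsed and round-tripped but ignored by every spatial operation:
enhancer activity is position- and orientation-independent, and pairing
here is purely positional.

**TAD assignment.** A feature overlapping exactly one TAD by ≥1 bp belongs
to it. A feature straddling a boundary is assigned *uniquely* to the TAD
with the larger overlap (ties to the lower-coordinate TAD). Unique
assignment is a deliberate choice over duplication: it makes per-TAD count
aggregation conservative (sum over TADs + unassigned = grand total), which
the correlation stage's conservation invariant relies on. Coverage-style
counting would instead count straddlers once per touched TAD. How the
original toolchain treated straddlers is not observable from its outputs;
the unique rule is documented here as this package's policy.

## Consensus TADs

Two parent TAD sets rarely agree interval-for-interval, and two readings of
"consensus of the overlap" are defensible; both are implemented:

* `intersect` (default): one consensus interval per maximal pairwise
  overlap region. Because one parent interval can overlap several partners,
  the consensus can hold *more* intervals than either parent — which is the
  only reading consistent with a consensus count exceeding both parent
  counts.
* `merge_chained`: overlap regions deriving from one parent-A TAD are
  merged into a single interval spanning first-to-last region, reproducing
  the "multiple overlapping partners were merged" narrative.

A TAD is *tissue-specific* when it shares zero bases with the entire other
set; a single shared base disqualifies. No minimum-overlap fraction is
applied because none is defined for the source procedure. Consensus ids are
regenerated ordinals (`TAD_<chrom>_<k>` in coordinate order) so identical
coordinates always produce identical ids.

## Pair enumeration and DE filtering

Distance is midpoint-to-midpoint. Midpoints of half-open intervals can be
half-integral, so comparisons use doubled midpoints (`start+end`) in exact
integer arithmetic — the 500 kb boundary is inclusive and float-rounding
free. Midpoints are the natural anchor for point-like CAGE tag clusters.

The DE filter is strict (`fdr < 0.05`), both members must pass, and a pair
member absent from its DE table drops the pair. A record that is
significant but has log2FC exactly 0 is rejected as contradictory rather
than silently assigned a sign. Pattern strings put the promoter sign first
(`-+` = down-regulated promoter, up-regulated enhancer).

Pair identity is `(promoter_id, enhancer_id)`; TAD id and distance are
annotations. Cross-tissue *stable pairs* are therefore a plain key
intersection, insensitive to per-tissue TAD-assignment edge cases, and the
per-tissue patterns of each stable pair are reported alongside.

## Interaction quantification

The per-TAD interaction count is exactly the combinatorial product of DE
promoters and DE enhancers, split by sign class — no weighting by effect
size or distance, because the product *is* the statistic being studied.
Class counts are exact integers; tissue proportions divide by the grand
total (an empty tissue is flagged rather than divided by zero).
*Consolidated* TADs require sign uniformity of both promoters and
enhancers (a promoter-only relaxation is available via a flag, since the
narrower reading is also defensible). The annotated-subset profile counts
only promoters whose mapped gene is in a user-supplied list and reports
distinct annotated DE genes; whether "count" should mean distinct genes or
gene–TAD combinations is ambiguous in the source material — distinct genes
was chosen.

## TAD-aggregated correlation

Counts are summed per TAD (promoters and enhancers separately; only TADs
with at least one of each enter, since both aggregates must exist to form a
point) and transformed as log2(sum + pseudocount). The pseudocount defaults
to 1 — it anchors empty aggregates at 0 and is the conventional choice for
count data; it is configurable. Axes are fixed: enhancer aggregate on X,
promoter aggregate on Y; slope signs follow.

The battery: Pearson r (t-transform p, n−2 df), Spearman ρ (Pearson on
average ranks), Kendall τ-b (tie-corrected — ties are common after integer
aggregation; τ-a vs τ-b is unstated in the source, τ-b chosen and flagged),
least-squares line, and Theil–Sen. Theil–Sen uses the all-pairs median
slope (pairs with equal x excluded) and the median-residual intercept
`median(y − slope·x)`; even-cardinality medians average the central pair.
Implementation delegates to `scipy.stats.theilslopes(method="joint")`,
which computes precisely this estimator; tests verify it against an
independent brute-force all-pairs oracle. Degenerate inputs (zero variance
on either axis, <2 distinct x) yield flagged NaN coefficients rather than
exceptions mid-pipeline; p-values with n < 3 are reported missing.
P-values below 1e−300 are printed as `<1e-300` — reporting them as hard
zeros would misstate underflow.

**Adjacent-TAD null.** Within each chromosome, in coordinate order, the
enhancer aggregate of TAD *k* is paired with the promoter aggregate of TAD
*k+1*; the last TAD pairs with nothing (no wrap-around). TADs missing from
the aggregate list (no features) are skipped, so adjacency is over the
usable TADs — a gap links its two neighbours rather than discarding both
pairs. At least 3 shifted pairs are required.

## Synthetic data generator

The generator emulates the structure the analysis measures, not CAGE reads:

* TADs tile each chromosome end to end (default 2 chromosomes × 60 TADs of
  400 kb — sub-500 kb TADs keep same-TAD pairs a subset of proximity
  pairs); promoters (100 bp) and enhancers (400 bp) are placed uniformly,
  non-overlapping within their TAD, 3 of each per TAD by default.
* Count model: `count = round(2^(b_f + a_t + g_f·c_s + ε_fs))` with TAD
  activity `a_t ~ N(0, σ_a²)` (default σ_a = 1, the co-expression signal),
  feature baseline `b_f ~ N(μ_b, σ_b²)` (defaults 5 and 1, i.e. counts of
  order 2⁵ so rounding noise is mild), sample noise `ε ~ N(0, σ_e²)`
  (default 0.5), condition indicator `c_s ∈ {0,1}` (5+5 samples by
  default).
* Condition effects are TAD-wise: a DE-carrying TAD (default fraction 0.5)
  draws one sign pattern from the mixture (default 0.55/0.15/0.15/0.15,
  leaning `++` to reflect the predominance of coordinated up-regulation in
  tissue data of this kind) and every promoter/enhancer in it receives
  `±δ` (default δ = 2 log2 units) per its slot's sign.

Counts are rounded log-normal, not negative binomial: the log-normal shared
factor is what induces the same-TAD correlation and the sign structure, and
it keeps the generator analytically transparent; NB dispersion is a noted
extension. What the generator does **not** emulate: library-size
differences, sequencing-depth normalization, mappability artifacts,
sub-TAD structure, distance-dependent contact decay, or correlated noise
between neighbouring TADs. Passing tests therefore demonstrate the
*machinery* (counting identities, estimator correctness, boundary-respect
discrimination under the assumed model), not robustness to real-data
pathologies.

`naive_de` (two-sample t on log2(count+1), BH step-up across features) is a
stand-in DE caller that exists to exercise the FDR-filter contract; it is
not a count-model DE method. Zero-variance features: identical values in
both conditions give p = 1; unequal constant groups (t undefined) are
assigned p = 0 as the limiting case. `perturb_tads` produces a synthetic
second TAD annotation by jittering internal boundaries (Normal offsets,
clamped to preserve order and a minimum length) and optionally dropping a
fraction of TADs — the dropped TADs become tissue-specific on the other
side and pull the Jaccard below 1.

## Problem sizes and determinism

Validation simulations use 300 TADs × (5+5) features for the
correlation-discrimination checks (100 replicates), 500 TADs for mixture
recovery, and 2000 features for DE null calibration — sizes at which the
targeted effects are unambiguous while the whole suite runs in seconds.
All randomness flows through `numpy.random.default_rng(seed)`; a fixed
seed reproduces every count bit-exactly, and the pipeline writes no
timestamps into artifacts, so identical (config, seed) reruns are
byte-identical.

## Known limitations

* Enumerated pairs are putative: product counting deliberately assumes
  every DE promoter interacts with every DE enhancer in its TAD.
* Unique TAD assignment of boundary-straddling features is a policy choice
  (see above); results for features near boundaries depend on it.
* The adjacent-TAD null controls for TAD-scale ordering but not for
  long-range chromosomal trends smoother than one TAD length.
* `naive_de` is underpowered and miscalibrated for low counts compared to
  dedicated count-model DE methods; real studies should supply their own DE
  tables (the pipeline consumes any table with feature_id/log2fc/fdr).
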