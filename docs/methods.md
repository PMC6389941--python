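# Methods

This note documents the models, estimators and numerical choices behind
`convtrace`, in the spirit of a statistics package's model
documentation: what is assumed, what is tunable, and what passing the
test suite does and does not demonstrate.

## Coordinates and input conventions

All sequence coordinates are **1-based inclusive**; CDS positions count
from the A of the ATG. The region-map file (`name  kind  start  end
frame_offset`, tab-separated) shares this convention — it is BED-like
in shape only, *not* BED (which is 0-based half-open). Quartet rows are
always in the fixed role order (species A paralogue a, A-b, B-a, B-b);
"A"/"B" and "a"/"b" are abstract labels the caller assigns.

## Site-pattern model

For a gap-free column with letters (a₁, b₁, a₂, b₂) in role order:

* `invariant` — all four equal;
* `orthologue_conserved` — a₁ = a₂, b₁ = b₂, a₁ ≠ b₁ (pattern P,Q,P,Q):
  each paralogue keeps a private state across species, as expected when
  duplication precedes speciation with no subsequent homogenization;
* `paralogue_conserved` — a₁ = b₁, a₂ = b₂, a₁ ≠ a₂ (P,P,Q,Q): the
  duplicates agree within species but differ between species. A single
  such site can arise by two parallel identical mutations; a run of
  them is the signature of post-speciation gene conversion;
* `other` — singletons, triallelic columns, and any column containing
  N (ambiguity is flagged, never guessed);
* `gapped` — any `-`; gapped columns are excluded from identity and
  pattern counts and tallied separately as inserted/deleted positions.

Percent identity is reported to one decimal with gapped columns removed
from numerator and denominator.

Coding substitutions are classified site-wise: each differing CDS site
is judged by substituting that site alone into the partner sequence's
codon context under the standard genetic code. A codon with two or
three hits contributes one class per differing site (flagged
`multi_hit`); this reproduces the site-count convention of published
substitution tables without asserting an evolutionary order for the
hits. Internal stop codons warn but do not abort.

## Conversion inference

**Informative sites** are the `orthologue_conserved` and
`paralogue_conserved` columns in alignable regions. Intergenic columns
are excluded: between tandem duplicates the intergenic sequence
diverges too fast to align reliably, which is also why published
quartet tables cover exons and introns only.

**Boundary.** The tract edge is the changepoint of a two-segment 0/1
sequence: choose the cut k minimizing (# paralogue-conserved sites at
positions ≤ k) + (# orthologue-conserved sites > k). All optimal cuts
are reported as an ambiguous interval — (last orthologue-conserved site
before the optimal region, first paralogue-conserved site after it).
When the labels separate perfectly the interval provably contains every
zero-misclassification cut, matching the practice of excluding the
undecidable window between the last upstream and first downstream
informative site from partitioned analyses. With sites of only one
label the result is "no boundary detectable", not an exception.

**Event count.** Two rules, both thresholds exposed in
`ConversionThresholds`:

* R1 (`min_shared_sites`, default 3): at least `t₁`
  paralogue-conserved sites inside the tract reject independent
  parallel mutation (the real medaka locus shows 13 such sites, and the
  per-site probability of a parallel identical substitution is tiny),
  establishing ≥ 1 post-speciation conversion.
* R2 (`max_divergence_ratio`, default 0.5): a lineage whose
  within-tract paralogue divergence per compared site is below
  `t₂` × its upstream-of-boundary divergence per site is called as an
  independent, lineage-specific homogenization.

`minimum_events = max(1, #lineages passing R2)` **gated on R1**:
without the shared-site evidence no event is called at all. The gate is
what keeps the false-positive rate on conversion-free simulations below
5% — divergence-ratio noise alone (R2) fires occasionally on spurious
boundaries, but essentially never together with ≥ 3 shared tract sites.
Defaults were chosen so the published scenario (13 shared sites, 2 vs
17 within-tract differences) is called decisively. An
`upstream_conversion_possible` flag (never counted as an event) is
raised when the upstream region also lacks orthologue-conserved signal,
the situation in which still older conversions may have affected the 5′
region.

**Recency order.** Lineages are ranked by within-tract paralogue
difference counts (strictly fewer = more recent conversion; equality =
"tie"); gaps are counted separately and never enter the ordering. Only
an order is reported, never absolute times — a single extant quartet
cannot date the earlier event.

One tract per locus pair is assumed; mosaic or multiple disjoint tracts
are out of scope.

## Phylogenetics

Distances: p-distance; JC69 d = −(3/4)·ln(1 − 4p/3), with p ≥ 0.75
raising a saturation error; K2P from separate transition/transversion
proportions. Gapped/ambiguous columns are excluded pairwise.

Neighbor-joining is the standard Saitou–Nei agglomeration with two
reproducibility guarantees: Q-criterion ties are broken by taxon label
order (and flagged), and negative branch-length estimates are clamped
to zero (and flagged). On additive matrices the tree and its path
lengths are recovered to ≤ 1e−9.

Quartet maximum likelihood is JC69-only, by design: the claim this
package exists to reproduce is the topology *flip* between the
unconverted and converted partitions, which is robust to the
substitution model, so model selection machinery would add surface
without power. For each of the three unrooted topologies the five
branch lengths are optimized by coordinate ascent — bounded scalar
search per branch on [1e−8, 10] substitutions/site, sweeps until the
log-likelihood gain is below 1e−6 (max 100 sweeps) — over
pattern-compressed site likelihoods (Felsenstein pruning). Winners
within tolerance of the runner-up are called `mixed` (conservative);
alignments with no variable columns are flagged `no_signal`. Bootstrap
is nonparametric column resampling, seeded, with per-topology support
for quartets and per-bipartition support for NJ trees.

## Simulator

Time is abstract (substitution-clock units; published divergence-time
calibrations are documentation only, and none of the inference depends
on absolute time). The history is: ancestral sequence drawn uniformly →
duplication at T_d (two copies evolve independently) → speciation at
T_s < T_d (four lineages) → optional dated conversion events, each an
instantaneous perfect overwrite of the acceptor paralogue by the donor
tract within one lineage. Substitutions are a Poisson process with
per-region-kind rates (JC-style equal exchange to one of the three
other bases); optional 1-bp deletions are restricted to non-exonic
regions, so the CDS stays gap-free as in the real quartet. Every
applied mutation is logged (branch, position, time, from, to), and
`replay_truth` rebuilds the quartet from the ancestral sequence and
logs alone — byte-identical output is asserted in tests, which pins the
event ordering semantics (events applied in decreasing time; a
conversion copies the donor's *current* state).

The default preset is a 1,200-bp locus: three exons (1–180, 421–660,
781–900; CDS 540 bp) separated by introns, intergenic tail 901–1,200;
exon rate 0.02 and intron/intergenic rate 0.06 substitutions/site/unit
(introns and intergenic sequence drift visibly faster than exons, as in
real duplicate loci); T_d = 3, T_s = 1; donor-a conversions over tract
400–900 in species A at t = 0.1 and species B at t = 0.6. The tract
runs to the 3′ end of the gene body with only intergenic sequence
beyond, mirroring the geometry of the real locus (converted tract from
mid-gene to the gene end; unalignable intergenic flank); the asymmetric
times mirror the "very recent in one species, earlier in the other"
history. The expected number of paralogue-conserved tract sites under
this preset has a closed form from the branch structure (donor-lineage
substitutions accumulated between speciation and conversion, propagated
to both copies), which the test suite computes independently from JC
transition matrices and checks to within 3 standard errors over 200
replicates.

What the simulator does **not** emulate: selection, rate heterogeneity
within a region kind, insertions, mosaic conversion tracts,
between-site rate correlation, and alignment error (the truth alignment
is positional). Passing the recovery tests therefore shows the
estimators work when their structural assumptions hold — it does not
certify performance on real data with alignment uncertainty.

The F2 generator is a multinomial draw at (¼, ½, ¼). Peak ratios are
allele-dosage fractions plus truncated Gaussian noise, renormalized per
site; an optional expression-weight scalar (default 1 = symmetric)
models unequal baseline expression of the two paralogues.

## OMR model and metrics

The trajectory generator puts the fish on a circular orbit at 0.7 × the
tank radius. Protocol: 30 s acclimation, then stripes rotate clockwise
/ counter-clockwise / clockwise, 30 s each, at 30°/s by default. Per
phase the fish complies with probability `compliance` (Bernoulli per
phase — published observations are that fish sometimes ignore or oppose
the stripes for a whole stimulus); if complying it follows the stripe
direction at the stripe speed after a fixed `latency`, except during
lapse episodes (Poisson arrivals, exponential durations, merged if
overlapping). Positional noise is isotropic Gaussian, clamped to the
tank. Truth metrics are computed from the latent states by interval
arithmetic (exact, not frame-accumulated).

The metrics estimator converts coordinates to an unwrapped angle about
the tank centre (supplied, or else the trajectory centroid — supply it
when known: the centroid is biased when the fish is stationary for long
stretches). Per phase, displacement is signed by that phase's stripe
direction. Since a coordinate tracker defines no "start of OMR", onset
is operationalized as: the first time the cumulative same-direction
displacement in a trailing 2-s window exceeds 30°, **backdated** to the
start of the contiguous same-direction run that produced the crossing.
Plain threshold-crossing time is biased late by threshold/ω seconds;
backdating makes the noise-free estimate exact and keeps the latency
mean absolute error under 1 s at default noise. Duration is the
percentage of phase frames whose boxcar-smoothed (0.5 s, edge-
normalized, smoothed *within* phase so direction reversals do not bleed
across boundaries) same-direction angular velocity exceeds 5°/s,
averaged per phase (a pooled-over-phases mode is available). Distance
is the total positive same-direction displacement over all phases ÷
360. A phase with no onset contributes the full 30 s delay; delay is
capped at the phase length by construction. The noise-free closed forms
— perfect follower (0 s, 100%, 3·ω·30/360 rounds) and stationary fish
(30 s, 0%, 0) — are exact.

Thresholds (30° window displacement, 2-s window, 5°/s velocity, 0.5-s
smoothing) are operational choices exposed in `OMRParams`, selected so
the noise-free limits are exact; they are not published values.

## Group statistics

Student's t is pooled-variance and two-sided, reported per pair with no
multiple-testing correction (the study design this mirrors states the
comparison is uncorrected). One-way ANOVA and Tukey HSD come from
scipy; the compact letter display uses the insert-and-absorb algorithm
with alphabetical processing order, making the letter partition
invariant under group relabelling. Fully degenerate input (zero
variance in every group) is flagged rather than propagated as NaNs.

## Problem sizes

Replicate counts used by the test suite and acceptance script — 100
replicates for boundary/event/topology recovery, 50 for order recovery,
200 for the analytic shared-site check, 1,000 small-locus runs for the
Poisson goodness-of-fit — were chosen to give binomial/normal standard
errors comfortably inside the asserted margins while keeping a full run
in the tens of seconds.

## Known limitations

* Real-locus analyses require the user to retrieve the published
  sequences; no third-party data is redistributed.
* The boundary estimator assumes a single changepoint; a tract that
  ends before another informative region begins (two changepoints in
  one track) would need the analysis restricted to the gene body, which
  the intergenic exclusion performs for the default geometry.
* JC69-only likelihoods; distances saturate at p ≥ 0.75.
* `full_locus` alignment shells out to MAFFT; only the `cds_only` path
  (used by all quantitative results) is dependency-free.
* The residue-index mapper uses a fixed BLOSUM62 global alignment;
  curated structure-based numbering systems may disagree near indels.
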