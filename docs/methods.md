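# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `icna`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates

All internal genomic intervals are 0-based half-open. Probe positions
are ingested as 1-based point coordinates (the convention of array
annotation tables) and converted at the module boundary
(`ProbeGrid.pos0()`); the conversion is total and invertible. Breakpoint
confidence intervals are half-open `[ci_low, ci_high)` and always
contain the boundary point estimate.

## Segmentation (CBS)

Each sample × chromosome log2 sequence is segmented independently. The
split statistic for an arc `x[i:j]` of the circularized sequence against
its complement is the pooled-variance two-sample *t*:

```
T(i,j) = |mean(arc) − mean(comp)| / sqrt(s² (1/k + 1/m)),
s² = (SS_within) / (n − 2)
```

with `+inf` as a sentinel when the within-group variance is numerically
zero (relative tolerance 1e-9) but the means differ, and 0 for an
all-equal sequence. The identity `SS_within = SS_total − (km/n)·d²`
(`d` = difference of means) makes `T` monotone in the between-group sum
of squares at fixed arc length, so the permutation scan only evaluates
the extreme sliding-window sums per arc length; the arg-max scan used
for the actual split is exhaustive. Ties (an arc and its complement are
mathematically tied) keep the first-seen arc in (length, start) order,
with a 1e-9 relative epsilon so last-ulp differences between passes
cannot reorder them.

The best arc is accepted when the permutation p-value
`(1 + #{perm max ≥ observed}) / (n_perm + 1)` is `< alpha`; accepted
interior arcs split a piece into three, edge arcs into two, and the
recursion continues while pieces have at least `2·min_width` probes.

* `alpha = 0.01`, `n_perm = 1000`, `min_width = 3` by default — values
  in the range of common CBS practice; all are exposed in the config.
* No merge/"undo" post-processing: the downstream shift threshold
  (δ = 0.4) already suppresses small spurious steps, and an undo pass
  would complicate the exhaustive-oracle equivalence that the test
  suite asserts.
* Permutation streams are keyed by `(master seed, sample index,
  chromosome index, node start, node end)`. Consequences: results are
  independent of processing order; early stopping of a hopeless
  permutation loop (only ever triggered when rejection is already
  certain) cannot perturb any other node; and lowering alpha can only
  remove splits, never add them.
* Missing log2 values are dropped per sample before segmentation (count
  logged), not imputed. Segment indices refer to the finite-value probe
  subsequence.
* Segmentation is per-chromosome; a per-arm mode would only need a
  cytoband-keyed split of the input and was not needed for the
  synthetic studies.

## Breakpoint calls and location confidence

Adjacent segments with `|Δmean| ≥ δ` (default 0.4, inclusive) yield a
call. The boundary point estimate is the midpoint of the two flanking
probes; the flanking gap itself (`probes_gap_bp`) is the resolution
floor. The 95% location interval is a **residual bootstrap**: the
two-level step model is fitted in a window of up to 20 probes per side,
residuals are resampled with replacement onto the fixed probe
positions, and the best single changepoint is re-estimated per replicate
(200 by default); the CI is the 2.5–97.5 percentile range, widened to
include the flanking probes of the point estimate. A pairs bootstrap
(resampling probe/value pairs) was rejected because dropping a boundary
probe shifts the fitted changepoint even in noise-free data, so the
interval would not collapse to the flanking gap in the noiseless limit —
the behaviour that defines the resolution floor. With fewer than three
probes on a side the CI falls back to the flanking gap and the call is
low confidence.

"High confidence" is a dual condition: the CI lies within the local
probe window, **and** (at event level) the CI lies wholly inside the
assigned gene, so the intragenic assignment is invariant across the
interval. Both components can be toggled independently
(`conf_requires_window`, `conf_requires_gene_invariance`).

## Gene mapping and the break-enrichment statistic

A call produces one event per gene whose `[tx_start, tx_end)` contains
the boundary (overlapping genes each get an event); two same-sample
calls in one gene that share the intervening segment and shift in
opposite directions merge into a single `internal` event. Intergenic
calls are kept: they contribute to the genome-wide break rate.

The per-gene statistic uses gene size = genomic footprint
(`tx_end − tx_start`), genome length = probe-covered span (rate should
reflect observable territory), `observed` = number of samples with ≥ 1
break in the gene (recurrence; raw-count mode by flag), Poisson standard
error `sqrt(expected)`, and a one-sided upper-tail p-value — exact
Poisson below expectation 10, normal approximation above. The correction
is Benjamini–Hochberg by default (Bonferroni by flag). The upper-tail
p-value of a discrete count is super-uniform under the null, so for
calibration diagnostics the package exposes the randomized
probability-integral transform `P(X > obs) + U·P(X = obs)`, which is
exactly U(0,1) when the count model holds; the acceptance checks apply a
KS test to that transform and verify the BH discovery fraction directly
on the plain p-values.

## Filter funnel

Stage order is fixed: CNV-polymorphism overlap → normal subtraction →
significance (corrected p < 0.05, strict) → high confidence → probe
coverage. Independent filters commute on the retained set (asserted by
test), so the order only affects provenance attribution. Grouping key
for "a given aberration" is `(gene, direction)` — direction separates an
amplified flank from a deletion in the same gene. CNV exclusion uses
breakpoint-CI overlap of ≥ 1 bp by default (whole-gene mode by flag);
normal subtraction matches gene + direction (direction-agnostic by
flag). The coverage rule — exclude when the flanking gap exceeds 100 kb
or either flank has < 3 probes within 50 kb — is an automated proxy for
manual inspection of probe support and makes no claim to reproduce
subjective curation.

## Classification and fusion nomination

The aberrant flank of a single-break event is the one deviating more
from the sample baseline (median segment log2 of the sample); ties
prefer the higher flank, which keeps classification symmetric under
coordinate mirroring. The truncated gene end follows strand: a
minus-strand gene losing its genomically rightmost part loses its 5′
end. Fusion nomination pairs 5′-retaining with 3′-retaining amplified
fragments in one sample when both levels ≥ 0.8 log2, the level
difference is ≤ 0.3, both breakpoints are on one chromosome within
10 Mb, and every segment strictly between them is itself amplified (one
contiguous amplicon chain; co-amplification-only mode by flag).
`multi_amplicon` flags chains whose amplified segments sit at two or
more levels separated by more than the level tolerance. The 0.8 / 0.3
defaults separate high-level amplification from single-copy gain on a
log2 scale; both are flags. Orientation and inversions are not
modelled — nomination is copy-number geometry only — and interchromosomal
pairing is opt-in. Retained exons are those wholly on the kept side of
the breakpoint CI; exons overlapping the CI are reported ambiguous, and
a CI spanning the whole gene leaves the structure undetermined.

## Cohort analysis

Burden = final (post-funnel) events per tumour; groups are `none` (0),
`high` (strictly > 10) and `rest`. Two-group comparisons default to
Welch's *t* (Student's by flag); three or more use one-way ANOVA;
`unknown` covariate levels are excluded from comparisons but never
dropped from tables. Survival uses Kaplan–Meier per group (step-function
median convention; never-reached medians reported as infinity) and the
k-group log-rank test with k−1 degrees of freedom (lifelines).

## Synthetic cohort

The generator emulates a tumour/normal SNP-array cohort: 100 tumours,
26 matched normals, six 2.5 Mb chromosomes carrying 60 genes
(40–100 kb, 3–12 exons), probes every ~5 kb with ±10% jitter (regular
grids hide off-by-one errors), piecewise-constant log2 signal at 0
baseline plus iid N(0, 0.15) probe noise. Planted levels: amplicons
U[0.8, 2.5], deletions U[−2.0, −0.5] — bracketing single-copy to
high-level change; germline CNVs at ±1 copy (+0.58 / −1.0). Six
catalogued polymorphism regions (plus decoys) enter the interval set;
two further regions are deliberately left out of the catalogue so that
only normal subtraction can remove them. Somatic events are dealt
round-robin over small per-class driver-gene pools (≈ 10–13 samples per
driver), mirroring the recurrence structure that makes genes
significant in a real cohort — including the fusion pairs, which are
planted as a single amplified interval whose edges fall inside two
plus-strand genes (the left gene donates its 3′ portion, the right its
5′). Per-sample burden follows a three-group design (7% zero, 9% high
at 11–16 events, the rest around a median of ~3, near the subgroup
medians reported for paediatric high-grade glioma); survival times are
exponential with group hazard multipliers (0.55 / 1.0 / 1.69 around a
13-month baseline median) and independent exponential censoring tuned
to a 20% censor fraction.

What the generator does **not** emulate: tumour purity/ploidy mixtures,
allele-specific copy number, GC waves and other spatially correlated
array artifacts, probe-specific variances, and inversion/orientation
structure within amplicons. Passing tests therefore demonstrate
correctness of the algorithms under idealized piecewise-constant signal
with iid Gaussian noise — not performance on raw array data.

Genome and cohort sizes in tests and the acceptance script (six 2.5 Mb
chromosomes; a 12-tumour miniature for unit fixtures) are the package's
chosen study sizes: large enough that driver recurrence, germline
subtraction and survival stratification all operate, small enough that
the full cohort segments in a few minutes.

## Numerical choices

* Zero-variance sentinel: `T = +inf` when within-variance ≤ 1e-9
  (relative) and means differ; exact-tie arcs resolved first-seen.
* Permutation p-values use the add-one estimator and never return 0.
* Segment means are exact arithmetic means; the probe-weighted mean of
  segment means reproduces the chromosome mean to 1e-10 (asserted).
* SEG output prints seg_mean at 4 decimals; writers emit deterministic
  row order (sample, chromosome, start) and a `#` header with version
  and parameters, so byte-level reproducibility is testable.

## Known limitations

* The permutation test has little power to confirm noise-free steps
  shorter than ~3 probes (an arc isolating a 2-probe minority is easily
  reproduced by permutation), so such segments fall back to the parent
  segment; the synthetic generator plants events spanning ≥ 3 probes.
* The significance filter needs cohort-scale recurrence: in miniature
  cohorts (tens of events over a few megabases) expected counts per
  gene approach the observed ones and all events fail the corrected
  p < 0.05 rule. This mirrors the real-data regime, where expected
  rates per gene are far below 1 only because the genome is large.
* Breakpoint locations are never resolved below probe spacing; all
  downstream geometry (exon retention, CNV overlap) honours that floor
  through the CI.
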