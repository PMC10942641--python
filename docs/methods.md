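# Methods

This note documents the models, rules and numerical choices behind
`clonetrack`, in the spirit of a statistical-software methods appendix: what
is modelled, what the defaults mean, and what the simulation-based checks do
and do not demonstrate about real data.

## The experimental designs being modelled

Lentiviral barcoding tags individual hematopoietic stem cells (HSCs) with
short random DNA sequences so that each transduced founder cell and all of
its progeny — a *clone* — can be identified by amplicon sequencing. The
package models two labelling strategies used to study ex vivo HSC
expansion cultures:

* **Pre-culture labelling.** Five wells of 1,000 input HSCs are transduced
  at ~35% efficiency against an 8 bp library of 5,737 barcodes, expanded,
  and split: half of each well goes to one dedicated **parental** recipient
  (a one-to-one well-to-mouse map), the remaining halves are pooled and a
  fifth of the pool goes to each of five **daughter** recipients. A barcode
  shared between a parental and daughters identifies a clone whose culture
  expansion was large enough to populate multiple grafts; the number of
  daughters reached grows with clone size, which is the design's readout of
  per-cell expansion capacity.
* **Post-culture labelling.** A pool of 3,000 input HSCs is expanded first
  and transduced afterwards (~15% efficiency, 21 bp library of 10,090
  barcodes); four analysed recipients each receive a tenth of the pool. In
  the real experiment the clone-size spread then arises in vivo rather than
  in vitro; the simulator reuses the same founder → size → split machinery
  with one "well", which reproduces the observable structure (many small,
  more even clones across plain recipients) without modelling in vivo
  kinetics explicitly.

The bundled libraries are synthetic stand-ins: they match the real
libraries' sizes and barcode lengths but their sequences are generated from
fixed seeds.

## Generative model

For each founder clone, the cell count at harvest is drawn i.i.d.
lognormal(μ, σ), rounded to an integer. The lognormal is a deliberate
modelling choice: per-clone contributions in such experiments span more
than two orders of magnitude (heavy-tailed), and the two-parameter
lognormal gives closed-form moments for test oracles — e.g. the clone-size
CV is √(exp(σ²)−1). σ (`log_expansion_sd`) is the **heterogeneity
parameter**: σ = 0 makes all clones equal in expectation.

Downstream of harvest:

* **Splitting** is a multinomial allocation of each clone's cells over the
  design's per-well fractions (sequential conditional binomials), so cells
  are conserved and no clone can appear in a recipient it was not given to.
* **Engraftment** thins each allocation binomially at
  `engraftment_fraction`, modelling the small probability that a
  transplanted cell contributes progeny to the sampled bone-marrow myeloid
  compartment months later.
* **Sequencing** draws each recipient's read vector by giving every
  barcode a gamma-distributed amplification weight with mean equal to its
  engrafted cell count and squared CV `pcr_dispersion` (PCR jackpots), then
  sampling the fixed read budget multinomially. This is the standard
  gamma–Poisson (negative-binomial-like) overdispersion; `pcr_dispersion=0`
  recovers pure multinomial sampling.
* **FASTQ emission** writes each read as 5' anchor + barcode + 3' anchor,
  padded with a constant stuffer to 100 nt, with uniform per-base
  substitution errors at `seq_error_rate`; indels are not modelled because
  amplicon reads place the barcode at a fixed offset from the anchor.

All randomness flows from one integer seed through named substreams (clone
sizes, barcode draws, splitting, read sampling, per-recipient error
streams), so a model instance regenerates byte-identical FASTQ.

### Defaults and their rationale

| parameter | default | why |
|---|---|---|
| `n_wells`, `n_cells_per_well`, `transduction_efficiency` | 5 × 1000, 0.35 (pre) / 1 × 3000, 0.15 (post) | the two experimental designs |
| `log_expansion_mean` | ln 2×10⁴ | mean clone ≈ 2×10⁴ cells after ~3 weeks; consistent with multi-million-cell wells from 1,000 founders |
| `log_expansion_sd` | 1.0 | order-of-magnitude clone spread, matching the observed 0.1–26% contribution range in character |
| `engraftment_fraction` | 0.01 | few engrafting cells per transplanted clone; produces realistic clone dropout and detection sparsity |
| `reads_per_recipient` | 10⁶ | typical amplicon depth per sample |
| `pcr_dispersion` | 0.05 | moderate PCR jackpot noise (log-scale SD ≈ 0.22) |
| `seq_error_rate` | 0.001 | ~Q30 substitution rate |

What the generator does **not** emulate: in vivo differentiation and
lineage output per clone, homing/niche competition, index hopping, chimeric
reads, and real library sequence composition. Tests passing on simulated
data therefore validate the *analysis logic* (extraction, filtering,
normalization, inference) under a plausible noise model, not the biological
accuracy of any particular parameter value.

## Barcode extraction

The 5' anchor is searched exactly (first occurrence); the next L bases are
matched against the library at Hamming distance ≤ `max_mismatch` (0 or 1).
Distance-1 matching is O(1) per read via a precomputed neighbour index;
sequences reachable from two barcodes are ambiguous and left unassigned.
The default is exact matching: both libraries are designed sets and no
error-correction step is part of the documented protocol. Reads lacking
the anchor are unassigned rather than reverse-complement-rescued, because
primer orientation fixes the amplicon strand. Assigned + unassigned =
total, always.

## Filtering pipeline

Order is fixed: **background filter → multi-parental exclusion →
normalization.**

* The background rule zeroes a barcode in a recipient when its frequency
  among that recipient's *assigned* reads is strictly below the threshold
  (default 0.1%, an explicitly arbitrary cut-off). The denominator is the
  pre-filter assigned total of that recipient.
* A barcode surviving the filter in ≥ 2 parental recipients cannot be
  attributed to one well (independent transductions with the same barcode)
  and is removed from **all** recipients, with the parental ids logged.
  Exclusion is evaluated post-filter so that sub-threshold spillover in a
  second parental does not trigger it. Parental↔daughter sharing is the
  signal and is never excluded.
* Normalization rescales each recipient's surviving counts to sum to 10⁶
  (reads per million); values stay real-valued.

A subtlety worth knowing: the *filter stage* is monotone in the threshold
(raising it never rescues a barcode), but the composed pipeline is not —
a higher threshold can silence a barcode in a second parental recipient and
thereby exempt it from multi-parental exclusion. The monotonicity property
is therefore stated and tested at the filter stage.

## Clone statistics

Clone size is a barcode's normalized frequency within a recipient; when
conditions are compared, sizes are pooled across the condition's
recipients. Sharing analysis reports, per barcode detected in a parental,
its parental clone size, the number of daughters in which it survived the
background filter, and its summed daughter contribution; the regression of
daughter contribution on parental size is ordinary least squares. Two-sample
clone-size comparisons use the Mann–Whitney test — exact for untied samples
of ≤ 20, otherwise the tie-corrected normal approximation — verified in the
test suite against an exhaustive rank-permutation oracle.

## Heterogeneity inference

The target parameter is σ, the lognormal spread of clonal expansion
capacity. The raw statistic is the pooled within-recipient SD of log clone
sizes in the filtered table (within-recipient centring makes it
scale-invariant). That raw statistic is *biased* for σ: engraftment
subsampling and PCR dispersion put a noise floor under it (it cannot reach
0 when σ = 0), while the 0.1% background threshold left-truncates the size
distribution and shrinks it when σ is large.

`CloneHeterogeneity.fit()` therefore estimates σ by **indirect inference**:
the generative model is simulated over a σ grid (default 0–2, step 0.25,
8 replicates per point), the mean statistic curve is made monotone by
pool-adjacent-violators, and σ̂ is the pre-image of the observed statistic
under linear interpolation. The 95% interval is a percentile **parametric
bootstrap through the simulator** at σ̂, with the calibration curve's own
Monte-Carlo standard error propagated by re-jittering the curve in every
bootstrap replicate (omitting this measurably under-covers). Values of the
observed statistic below the simulated noise floor map to σ̂ = 0, so the
interval behaves correctly at the σ = 0 boundary.

The fit is parametric: the model passed in (design, depth, engraftment,
dispersion) is taken as known, exactly as in the parameter-recovery
experiments. On real data these nuisance parameters would have to be
supplied as assumptions, and the interval does not account for their
misspecification.

## Repopulating units

With test chimerism p (%) against C competitor whole-bone-marrow cells,
RU = p/(100−p) × C/10⁵; one RU is the mean activity of 10⁵ WBM cells.
The transform is strictly increasing in p, equals C/10⁵ at p = 50, and
diverges at p → 100: recipients at ≥ 99.9% are flagged saturated and
excluded from cohort means by default, since such signals fall outside the
assay's quantifiable range. Functional expansion folds are ratios of cohort
means of RU per input cell; arithmetic means are the default and geometric
means are an option, because a ratio of means and a mean of ratios differ
(the same reason the phenotypic fold computed from mean cell counts, e.g.
13.6×10⁶ cells × 0.1% / 50 input = 272, differs from a per-culture mean
fold).

## Division counting

A proliferation dye halves per division, so division number is a unit step
in log2 intensity below an undivided anchor (a co-transplanted
non-dividing CD4⁺ population; anchor = its median log2 intensity). Cells
get the nearest integer: d = ⌊anchor − log2(I) + 0.5⌋ clipped to
[0, d_max], half-up rounding so the "undivided" bin is exactly the ±0.5
window around the anchor. d_max defaults to 6 — a typical dye detection
limit, declared as an assumption — and cells at or below the unlabeled
negative-control floor report "≥ d_max". Nearest-bin assignment was chosen
over Gaussian-mixture fitting for transparency; with a measurement spread
of 0.2 log2 units, ≥ 95% of simulated cells are assigned their true
division count.

## Problem sizes used in the shipped checks

The acceptance tests run the pre-culture design at its stated scale
(5 × 1000 founders, 10⁶ reads/recipient) with 20 seeds per σ in
{0, 0.5, 1.0, 1.5}; `scripts/acceptance.py` reports a scaled-down recovery
experiment (2 σ values × 8 seeds, 60 bootstrap replicates) alongside the
single-experiment pipeline quantities, the RU grid and the division-counting
accuracy. These sizes are the package's chosen defaults for a reproducible
desk-scale run.

## Known limitations

* The simulator's σ is an *effective* spread absorbing all biological
  heterogeneity; it is not identified separately from unmodelled extra
  noise sources on real data.
* Post-culture experiments are modelled with the pre-culture machinery
  (one pool, plain recipients); in vivo clonal drift is not a separate
  process.
* Extraction assumes fixed-position barcodes; amplicons with indels
  upstream of the barcode would be dropped, not recovered.
* The multi-parental exclusion removes genuine clones that collide by
  chance in the library draw; with heavily used small libraries this is a
  designed trade-off, and the exclusion percentage is reported so it can be
  monitored.
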