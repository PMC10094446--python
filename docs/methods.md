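# Methods

This note documents the quantitative procedures implemented by
`dendroquant`, the assumptions behind them, and the design of the
synthetic-data generator that the test suite and the reproduction script
run against.

## Morphometrics

A reconstruction is a rooted tree of 3-D points with radii (SWC).  Each
parent→child edge is a *compartment* with Euclidean length and mean
endpoint diameter.  Per neuron we compute:

* **TDL** (total dendritic length, µm): sum of dendritic compartment
  lengths.  A compartment is dendritic when its child node is not
  soma-coded, so the edge leaving the soma into the arbor is counted and
  soma–soma edges are not.
* **TDB** (total dendritic branches): the number of maximal unbranched
  segments delimited by critical nodes (root, branch nodes, tips).  With
  this convention TDB = n_tips + n_branch_nodes, where a branch node is a
  non-root node with ≥ 2 children and a multifurcation counts once.  The
  field sometimes counts terminal tips instead; the segment convention is
  used here because it makes branch density interpretable (below), and the
  supporting counts are reported so either view can be reconstructed.
* **DBD** (dendritic branch density, branches/µm): TDB/TDL, the reciprocal
  of the mean branch length.  DBD separates arbor *complexity* from arbor
  *size*: a hypotrophy that removes growth and branching in equal
  proportion leaves DBD unchanged, whereas an effect that preferentially
  suppresses branching lowers it.

Cohort phenotypes are reported as percent change from control,
`100·(mean(case) − mean(control))/mean(control)`, computed on per-neuron
values first (never pooled compartments).  Hypothesis tests (one-way ANOVA
with Dunnett's post hoc, t-test, Mann–Whitney, Kruskal–Wallis with Dunn's
post hoc) delegate to scipy; Dunn's rank-z comparison is the one formula
written here because scipy does not ship it.

Degenerate single-node trees report TDL = 0 with DBD undefined (flagged,
not NaN).  If the root is not soma-coded the reconstruction is still
accepted; field SWC files vary.

## Compartment signal quantification

Multi-signal reconstructions carry, per compartment and channel, the
occupied volume fraction F ∈ [0, 1] and the average signal intensity
ASI ≥ 0.  The local quantity is

```
RQ = F × ASI × D
```

with D the local thickness, taken as the local diameter (mean of the
endpoint diameters, µm).  Arbor summaries: total RQ (unweighted sum over
compartments — RQ already carries local geometry through D; a
length-weighted variant is available), RQ per micrometre (total/TDL), the
branch-point mean (RQ averaged over the compartments incident to each
branch node), and fraction-of-max normalization across the neurons of an
analysis set (the set pools all genotypes by default; normalizing within
genotype is the caller's choice of input).

A branch point counts as signal-positive when its incident-compartment
mean RQ exceeds a threshold θ; no published threshold exists for this, so
θ defaults to 10 % of the neuron's maximum compartment RQ and is
configurable.

**Path-distance profiles.**  Compartments are assigned to contiguous
left-closed bins of width 20 µm (default) by the path distance of their
midpoint from the soma; bins are labeled by their distal edge.  The bin
statistic is the length-weighted mean of ASI or RQ (an unweighted mode is
provided).  Empty bins are missing, never zero, and the per-bin
compartment lengths always sum to TDL.  Case/control comparison takes,
per bin, the mean over neurons of the neuron's bin mean and reports
`100·(case − control)/control`; bins without control coverage propagate
as flagged missing cells rather than divisions by zero.

## qPCR, intensity ratios, enrichment

* **ddCt**: per condition, ΔCt = mean Ct(target) − mean Ct(reference);
  ΔΔCt = ΔCt(case) − ΔCt(control); fold = 2^(−ΔΔCt).  Replicate Ct values
  are averaged before differencing, making the point estimate invariant to
  any constant plate offset.  The estimator is unbiased on the cycle
  (log2) scale; the fold itself is log-normal under Ct noise.
* **Intensity ratios**: plain region ratios (nuclear/soma,
  target-neuron/reference-neuron), summarized over per-animal values.
  Both nuclear-to-whole-soma and nuclear-to-cytoplasmic denominators are
  supported since published usage is inconsistent between the two.
* **EASE enrichment**: for a hit list of size n in a background of size N
  and a category of size K with overlap k, fold enrichment is
  (k/n)/(K/N) and the EASE score is the right-tail hypergeometric
  probability with the overlap reduced by one (floored at zero, so a
  single-hit category scores p = 1).  EASE p ≥ classical Fisher p on
  every table.  Raw p-values with a 0.05 cutoff are the default;
  Benjamini–Hochberg adjustment is available as an option.

## The synthetic generator

### What it emulates

Class archetypes (CI, CIII, CIV) are calibrated *ordinally*: CI arbors are
small with few, long branches (defaults: 2 primaries, E[TDL] = 600 µm,
E[TDB] = 40, extent 200 µm); CIII arbors carry many short terminal
filopodia (3 primaries, 2200 µm, 800 branches, extent 300 µm); CIV arbors
are the largest and most complex (4 primaries, 3200 µm, 560 branches,
extent 560 µm).  The absolute values are package defaults of realistic
magnitude for larval da neurons, not measurements.

A condition effect multiplies expected TDL by `length_scale` and expected
TDB by `branch_scale`; packaged fixtures transcribe published effect sizes
into these scales (a branch-density change of d % combines with the size
change as `branch_scale = (1 + d/100)·length_scale`).  Channel effects are
per-channel baseline scales and a distance-dependent suppression curve
s(d) given as linear-interpolation anchors, flat beyond them.

### Construction

Each neuron draws a total length L ~ Gamma (CV 4 %) around its target and
a branch-density target with CV 0.8 %, then realizes both *exactly*:
trunks of jittered extent radiate from the soma, the required number of
bifurcations is split between trunk branch points and side-subtree
bifurcations (a side subtree is one terminal, or a stem plus two
terminals), side segment lengths are drawn as normalized gamma weights
over the remaining length budget, and all segments are subdivided into
≤ 4 µm compartments with angular wobble for quasi-planar 3-D geometry.
Radii taper linearly from the base value to a tip floor.

This construction was chosen over a continuous branching-process
simulation because its first moments are exact by design
(E[TDL] = L₀·length_scale, E[TDB] = B₀·branch_scale), whereas
supercritical growth processes have per-neuron dispersion of order one
per primary dendrite — far larger than what cohorts of n = 8–15 neurons
can average away, and larger than real cohorts of this kind exhibit.
The cost is that the generator is a *statistical* stand-in: it does not
model growth dynamics, self-avoidance, tiling, or realistic branch-order
statistics.

Signal channels per compartment: microtubule ASI with a gentle baseline
distance decay (λ = 2000 µm) times the condition's s(d); F-actin with a
distal-weighted profile; ribosome puncta as Poisson counts
(0.8 puncta/µm, ×3 at branch-incident compartments) converted to an
occupancy fraction 1 − exp(−0.15·count) and a per-µm intensity, so
zero-puncta compartments have RQ exactly 0; and a flat translation
channel.  Noise: 5 % multiplicative per-compartment intensity noise
(truncated at 0), a 3 % per-neuron gain, 0.02 additive fraction noise
clipped to [0, 1].

### Cohorts, pairing, determinism

`generate_cohort` derives per-neuron seeds deterministically from the
cohort seed and **shares the seed stream across conditions** (common
random numbers): the i-th neuron of each group is generated from the same
seed, so condition effects are applied to matched draws.  This is a
standard variance-reduction design for simulated case/control contrasts;
marginal cohort distributions are unchanged, and any single cohort is
indistinguishable from independent sampling.  Identical inputs and seed
give byte-identical SWC output (floats written at 6 significant digits).

Auxiliary generators construct qPCR Ct tables whose noiseless ddCt fold
equals the requested fold exactly (replicate noise in cycles is additive
Gaussian) and per-animal two-region intensity tables whose mean ratio is
unbiased for the requested enrichment factor (mean-one log-normal noise).

### What passing tests do and do not show

Recovery tests show that the *measurement pipeline* is a correct inverse
of the documented generative conventions at study-scale n — they validate
the arithmetic, the binning, the branch-counting convention, and the
effect parameterization.  They cannot validate the biology of the growth
model, reconstruction/segmentation error, or inter-animal variability
beyond the modest dispersions modeled here; real cohorts are noisier and
their group comparisons correspondingly less precise.

## Numerical choices and edge cases

* SWC floats are written at 6 significant digits; round-trips are exact at
  that precision and topology-exact always.
* Profile bins are `[k·w, (k+1)·w)` labeled by the distal edge `(k+1)·w`;
  the default w = 20 µm matches the granularity at which distance-resolved
  signal changes are conventionally reported.
* Fraction-of-max normalization rejects all-zero inputs instead of
  returning NaN.
* `percent_change` requires a non-zero control mean and non-empty groups.
* Degenerate zero-variance groups in hypothesis tests return flagged rows
  (`note` column), not exceptions; the t-test on identical constant groups
  reports p = 1.
* Cohort sizes in the reproduction script follow the study design they
  mirror (n = 9 per CIII/CIV group, n = 14–15 for CI and the
  profile cohorts); everything runs in seconds on one CPU.

## Known limitations

* The multi-signal SWC column layout is this package's own documented
  dialect (appended fraction/intensity pairs plus a `# channels:` header);
  deposited archive files may use a different layout and would need a
  thin import shim.
* The branch-counting convention (segments, not tips) is fixed but
  supporting counts are exported; analyses sensitive to the convention
  should state it.
* The generator's inter-neuron dispersion is deliberately modest (4 % CV
  in size, sub-1 % in density) so that study-scale cohorts resolve the
  transcribed effects; treat absolute variances as synthetic.
* EASE p-values are exact hypergeometric tails; very large backgrounds
  (genome-scale) are handled by scipy's implementation without special
  casing.
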