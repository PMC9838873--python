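# Methods

This note documents the models, numerical choices and open design decisions
behind gabatlas, in the order the pipeline runs them.

## Atlas primitives

A parcellation is a pair (annotation volume, region hierarchy). Voxels may
carry non-leaf labels, as real atlas releases do; the voxels labeled with a
parent's own id form its "own-voxel" part, distinct from its subtree.
Conventions, stated once: 0-based voxel indices; the world coordinate of a
voxel corner is index × voxel size; axis 0 is rostro-caudal; voxel sizes in
μm (cubic 25 μm by default, anisotropic supported per axis); densities in
cells/mm³; counts dimensionless.

The **alignment homogeneity metric** is the population standard deviation
of the per-region neuron-count distribution, computed by default over leaf
regions with nonzero annotated volume. Misalignment moves counts across
boundaries from dense into sparse regions, shrinking the spread, so a
larger value indicates a better-aligned reference pair. Leaves are used to
avoid double counting through the hierarchy; the population (not sample)
convention is a fixed choice since either is defensible.

## ISH processing

Expression arrives as aligned filtered slice stacks (one 25 μm section
every 200 μm in the emulated acquisition). Missing planes between sections
are filled by per-pixel linear interpolation; planes outside the sampled
range stay at 0 and are flagged uncovered. Uncovered voxels are *excluded*
from region means rather than treated as 0 — real experiments do not cover
the whole brain, and zero-filling would bias means downward.

Binarization uses Otsu's threshold (256 bins) computed per experiment over
in-brain, covered voxels only; restricting to in-brain voxels prevents the
background zeros from collapsing the threshold. Foreground is *strictly*
above the threshold (an arbitrary but fixed tie-break). Whether to
threshold per slice or per assembled volume is not determined by the data
model; per-volume was chosen because the slices of one experiment share
staining conditions. Multiple experiments for one marker are combined by
the voxelwise mean over the experiments covering each voxel (coverage
union).

Region mean intensities are hierarchical (subtree-based), so parents
without directly-labeled voxels still receive a predictor; own-voxel means
are kept alongside for the parents' own-voxel estimates.

## Literature normalization

The canonical internal unit is **counts per region**: the hierarchy
constraint is additive in counts, not densities. Densities convert via the
annotated subtree volume, percentages via the neuron (or cell) count of the
region; stds transform by the same linear factor.

Per (region, marker), a source is excluded iff its mean is at least 5×
larger than every other source's mean, or at least 5× smaller. With two
mutually conflicting sources the rule cannot identify the outlier, so both
are kept. Whole-source removal ("drop this citation everywhere") is
available as a separate toggle. The kept sources are summarized by the
arithmetic mean of their means and the arithmetic mean of their available
stds; if no source reports a std, σ = 0.1·η (configurable σ floor — the
optimization divides by σ, so it must not vanish).

Purely-inhibitory regions get a synthetic GAD67 record with count = nNeu
and are barred from transfer-function fitting. The striatum is *not*
forced inhibitory; where estimates overshoot the neuron count, the
optimization itself drives those regions fully inhibitory.

Coverage summaries report, per marker: distinct sources, regions covered,
and — over regions with ≥ 2 sources — the coefficient of variation of the
source means on the *density* scale (sample std, ddof = 1), its median,
and the moment skewness of the CV distribution,
s = (1/n)Σ((CV − mean)/std_pop)³ (scipy.stats.skew with bias=True).
Density scale and the std conventions are assumptions: published summaries
of between-source variability do not state them.

## Transfer functions

The predictor is the region mean binarized intensity x ∈ [0, 1]; the
response the literature density y. The model is through-origin,
y = α·x: no expression must imply no cells, and the fit report carries a
slope only. α = Σxy/Σx² with standard error
std_α = sqrt(Σ(y − αx)² / ((n−1)Σx²)); all points carry equal weight.
Fits are per marker × group (cerebellum / isocortex / rest, assigned by
subtree membership under configurable acronyms): cerebellar densities are
several-fold higher than elsewhere, and isocortical composition is similar
across its subregions.

Excluded from fitting: regions with zero mean intensity (coverage or
misalignment artifacts), purely-inhibitory regions, regions reported to
have no inhibitory neurons, and regions whose subtree straddles a group
boundary (their intensity mixes heterogeneous regimes; they are estimated
by aggregation instead). A group with fewer than two points falls back to
the marker's pooled fit, logged.

Goodness of fit is the explained-sum ratio
R² = S_model / (S_model + S_res) with S_model = Σ(f(xᵢ) − ȳ)² and
S_res = Σ(yᵢ − f(xᵢ))². This coincides with the textbook coefficient of
determination only when residuals are orthogonal to the fit; it is the
form reported next to the slopes and is used verbatim. Predictions for
literature-free regions are η = α·x·V and σ = std_α·x·V (V the subtree
volume in mm³); prediction uncertainty deliberately propagates only the
slope uncertainty.

## Estimate assembly and reconciliation

Every (region, type) pair receives exactly one (η, σ): literature where
available (including the purely-inhibitory rule), else transfer-function
prediction, else the children's aggregate plus the own-voxel prediction.
Parents with children additionally carry an own-voxel estimate (fitted
from own-voxel intensity, or 0 with σ = max(η_total, 1) when unobserved —
a weak prior that lets the LP move it freely). A σ floor of 0.1·max(η, 1)
applies before weighting.

The LP has one count variable per (region, type) — the 4·|R| "density
variables" — plus one own-voxel variable per (parent, type) and one slack
per variable. Constraints: bounds 0 ≤ x ≤ nNeu; the two-sided subtype-sum
inequality; the hierarchy equality (written as equality, the natural
reading); and the slack envelope −z ≤ x − η ≤ z. The subtype-sum and bound
constraints are imposed on parents' own-voxel blocks as well as on totals:
cell placement consumes own-voxel counts per region, and its nested label
assignment needs them valid there too. Objective: Σ z/σ. Degenerate
regions with nNeu = 0 are forced to 0 by their bounds.

The greedy pre-pass provides a feasible reference point. Algorithm 1
(cap-to-neurons) walks regions deepest-first: GAD67 clips to nNeu within
its η ± σ interval when possible; an excess of the subtype sum is removed
proportionally to the current PV:SST:VIP ratios, freezing any subtype at
its interval bottom and redistributing, with a logged below-interval
rescale only when the intervals are exhausted. Algorithm 2 (coherence)
finds the smallest q ∈ [0, 1] such that raising GAD67 by q·σ and lowering
each subtype by q·σ (clamped at interval edges) restores
GAD ≥ PV+SST+VIP, solving the one-dimensional gap equation by bisection;
if q = 1 is insufficient the subtypes rescale proportionally to GAD67,
logged. Applying the pre-pass to own-voxel blocks and aggregating yields a
feasible LP point (the constraints are preserved under summation), whose
objective upper-bounds the LP optimum — checked at solve time.

The LP is solved with HiGHS through scipy; the solver choice is
incidental, the contract is feasibility within 1e−7 relative tolerance and
exact optimality, both verified on every solve. x = 0 with z = η is always
feasible, so solver infeasibility raises. Corrections with |x − η| > σ are
flagged per estimate and summarized as the fraction of regions with any
flag. Residual populations follow by subtraction:
nRest = nGAD − (nPV+nSST+nVIP), nExcOther = nNeu − nGAD, both guaranteed
non-negative by the constraints.

## Cell placement

Per region, round(nNeu_own) cells are assigned to its own voxels by
multinomial draws proportional to the local cell density (no per-voxel
capacity — none is physically implied at 25 μm). The five label counts
(PV, SST, VIP, InhR, ExcOther) are rounded by largest remainder within the
region so they sum exactly to the placed total; labels are then assigned by
nested uniform selection and each cell jittered uniformly inside its voxel.
One master seed spawns independent substreams for placement, labeling and
jitter, so stages are reproducible in isolation.

## Synthetic fixtures

The generator's defaults are the standard study conditions: a depth-2,
branching-3 hierarchy (13 regions) on a 48×24×24 grid of 25 μm voxels;
neuron densities uniform in 20–80 ×10³ cells/mm³ (cerebellum ×3); GABAergic
fractions 0.15–0.45 of neurons; subtype shares Dirichlet-distributed
summing to 0.5–0.85 of GAD67 (so InhR stays positive); true slopes α of
order 10⁵ cells/mm³ per unit intensity, scaled per group; sections every 8
planes (200 μm at 25 μm); literature coverage 0.5 with between-source
log-normal noise of CV 0.2 (mean-preserving; multiplicative because
published densities are positive and spread over multiples), 1–3 records
per covered (region, marker), kinds mixed among density, count and
percentage-of-neurons.

Two generator design points make the noiseless fixture *exactly*
recoverable, which turns the end-to-end test into a sharp oracle:
foreground patterns are constant along the rostro-caudal axis within each
own-voxel block and a slice is emitted on both sides of every rostro-caudal
boundary, so linear interpolation is exact; and the true marker counts are
quantized to whole foreground pixels (with a repair pass that keeps
subtype sums under GAD67), so "mean intensity = density/α" holds without
rounding error. With all noise off, every fit recovers its true slope
exactly and the LP returns the truth with objective 0.

What the fixtures do *not* emulate: realistic anatomy (boxes, not brains),
partial brain coverage by default, heavy-tailed literature disagreement,
and intensity-dependent soma-size effects. Passing tests therefore
demonstrate correctness of the machinery under the stated statistical
model, not fidelity to any real atlas release.

The subsampling experiment reruns assembly + LP on random literature
subsets (fractions 0.70–0.95, 20 trials each, markers kept represented,
resampling logged) and reports the across-trial std of each region's
density; the extrapolation of σ to a full literature set uses a
least-squares line in the fraction, floored at 0 — a deliberate, simple
choice since no canonical method exists. The hold-out experiment keeps 90%
of records and compares reconciled densities to the withheld mean ± std.

## Known limitations

- The explained-sum R² can differ substantially from the textbook
  definition on poorly fitting groups; it is reported for comparability,
  not as a variance decomposition.
- Transfer functions are linear and unweighted; saturation at high
  expression and literature-confidence weighting are out of scope.
- The σ of aggregated parent estimates is the sum of child σs
  (conservative, linear); correlations between children are ignored.
- The two-source conflict case of the exclusion rule keeps both sources;
  identifying the outlier would need external information.
- Problem sizes in tests and the acceptance script use the standard
  13-region fixture (861 regions only for the structural LP check), chosen
  so the whole suite exercises every stage with sharp oracles.
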