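# Methods

## The feedback module

### Model structure

The model describes the canonical TNFα-responsive IKK–IκB–NF-κB signalling
module. Seventeen species: free NF-κB in cytoplasm and nucleus, and for each
IκB isoform (α, β, ε) free cytoplasmic protein, free nuclear protein,
cytoplasmic and nuclear IκB:NF-κB complex, and mRNA. Processes are mass-action
association/dissociation of NF-κB with IκB in both compartments; first-order
nuclear import/export of free NF-κB and free IκB and export-only of nuclear
complexes; translation of IκB from its mRNA; first-order mRNA turnover;
constitutive degradation of free and complexed IκB; and IKK-mediated
degradation of cytoplasmic IκB (free and complexed) proportional to the
instantaneous IKK activity. Degradation of complexed IκB releases NF-κB, so
total NF-κB is conserved: with cytoplasmic:nuclear volume ratio k_v, the
volume-weighted sum

    NF_c + NF_n/k_v + Σ_iso (C_c + C_n/k_v)

is constant along every trajectory by construction of the flux scheme (the
test suite checks drift < 1e−6 relative; in practice it is at rounding level).

Units: concentrations µM (nuclear species in nuclear-volume units; weighted
sums are cytoplasm-referenced), time minutes, IKK activity a dimensionless
fraction of its maximum.

IKK is not modelled mechanistically. It enters as a numerically defined curve
(time, activity) evaluated by linear interpolation, with the pre-stimulus
basal value before the first point and the last value held afterwards. The
shipped curve is a reconstruction of the canonical chronic-TNFα profile:
basal 0.005, rapid activation to the maximum near 10 min, adaptation to a
sustained plateau of 0.05 by 2 h.

### Transcription and the two scan knobs

IκBα and IκBε mRNA production uses an additive basal + saturable induced
term driven by free nuclear NF-κB N:

    v(N) = k_basal + s · k_ind · (N/K_half)^h / (1 + (N/K_half)^h)

with Hill coefficient h = 2 by default and K_half (1.5 µM) well above the
operating range of nuclear NF-κB, i.e. an effectively quadratic NF-κB
dependence as in the precursor model family. This choice is load-bearing: the
abundance-scan prediction — lower total NF-κB gives more sustained normalized
nuclear activity and less IκBα synthesis — requires the induced rate to fall
faster than linearly as the NF-κB pool shrinks. A first-order (h = 1)
saturable term produces the opposite ordering, because synthesis then
saturates at high abundance while the pool to be resequestered keeps growing.
IκBβ is constitutive (k_ind = 0).

The two experimental knobs are multipliers on this structure. `nfkb_scale`
multiplies total NF-κB (RelA expression level; scan grid 2, 1.5, 1, 0.5,
0.2). `kmrna_scale` multiplies only the NF-κB-induced IκBα production term —
not the basal term, and not IκBε (scan grid 1, 0.25, 0.125, 0.0625). It is
the model's proxy for transcriptional activation potential: a RelA mutant
that cannot engage the co-activator still binds DNA but produces IκBα mRNA
at a reduced rate.

### Parameter provenance

The shipped default file is a reconstruction following the published
precursor model family for this module, flagged
`provenance = precursor_default` in the file. Transport, binding and
degradation rates use the family's canonical values (e.g. NF-κB import
5.4 min⁻¹, complex export 0.83 min⁻¹, association 30 µM⁻¹min⁻¹, volume ratio
5, total NF-κB 0.1 µM); transcription and IKK-mediated degradation strengths
were chosen once so that the unperturbed model shows the canonical fibroblast
phenotype — IκBα degraded to ~⅓ of resting by ~10 min, nuclear NF-κB peaking
within the first half hour at >5× resting, IκBα regenerated to ≥90% of
resting and nuclear NF-κB largely cleared by 2 h. All property tests are
written against trends and invariants, not against specific rate values, and
any key can be overridden via the flat key–value parameter file.

The 1.8× increase of all IκB mRNA degradation rates (in line with direct
mRNA half-life measurements) is applied by `apply_model_adaptations`, which
refuses double application; the shipped file stores pre-adaptation rates.

Known structural simplification: the precursor family's transcriptional
delay for IκBε is omitted. The observables analysed here (nuclear NF-κB and
total IκBα over ≤ 2 h) are insensitive to it, and the ε arm contributes only
a small constitutive reservoir in this parameterization.

### Numerics

Integration uses LSODA (adaptive step, automatic stiff/non-stiff switching)
at rtol 1e−6 / atol 1e−9. The resting state is obtained by integrating under
basal IKK (horizon 4000 min, in chunks) and, once near-stationary,
Newton-polishing the state on the conservation manifold: the NF-κB
flux-balance equation — identically dependent on the others through
conservation — is replaced by the conservation constraint, which removes the
Jacobian's zero eigenvalue. Convergence criterion: max |dx/dt| < 1e−8
µM/min. Output states with components in (−1e−9, 0) are clipped to zero;
larger negative excursions raise an error, as does conservation drift beyond
1e−6 relative. The integrator is cross-checked in the tests against an
independent fixed-step classical Runge–Kutta integration (relative
disagreement < 1e−4).

## Normalization and RMSD scale selection

Nuclear NF-κB curves are normalized by the activation convention,
(x − x(0)) / (max x − x(0)): resting level 0, peak 1. Total IκBα by the
depletion convention, (x − min x) / (x(0) − min x): resting level 1,
post-stimulus minimum 0, values above 1 permitted (regeneration overshoot).
Flat series are degenerate and rejected. Model curves are normalized over the
same window as the data (baseline at stimulation onset), interpolated
linearly at the data times (output grid 1 min, so interpolation error is
negligible), and the squared residuals of both observables are pooled with
equal weight per point: RMSD = sqrt(mean over all points). Scale selection
returns the argmin of the per-scale RMSD; exact ties are broken toward the
larger (less-suppressed) scale and flagged.

Because the time courses are damped oscillations, "late-time" comparisons
between scan members are made on the mean normalized activity over the final
portion of the window (tests use the last 30 min of a 240-min run), not at a
single time point where oscillation phase can invert an otherwise robust
ordering. The abundance-scan IκBα trend is assessed on the absolute
(volume-weighted µM) post-recovery level: the depletion-normalized level
saturates at ~full recovery over the upper scales in this parameterization
and does not order reliably, whereas the absolute level — synthesis capacity
— orders strictly with abundance.

## One-site ITC

For a titration of ligand (syringe, total Xt) into macromolecule (cell, total
Mt, stoichiometry n) the bound-ligand concentration is the closed-form root

    [MX] = (A − sqrt(A² − 4 n Mt Xt)) / 2,   A = n·Mt + Xt + K_d,

and the cumulative heat after injection i is Q_i = [MX]_i · V0 · ΔH. Running
totals carry the standard perfusion correction for the displaced cell volume
(Mt and Xt diluted by the factor (1 ∓ v/2V0)/(1 + v/2V0) at cumulative
injected volume v), and the per-injection heat is
ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2. Units: µM, mL, µL,
kcal/mol, giving heats directly in µcal.

Fitting is nonlinear least squares (lmfit/MINPACK) over (n, log10 K_d, ΔH),
with asymptotic standard errors from the Jacobian (the K_d error delta-scaled
from the log-parameter). The first injection is excluded by default, the
universal calorimetric practice for the small diffusion-corrupted initial
injection. Flat (information-free) heat vectors are rejected. The default
schedule mirrors the instrument protocol of the experiments: 25 injections
(6 µL then 24 × 12 µL), 15 µM binder in a 1.4 mL cell, 175 µM titrant —
Wiseman c = n·[cell]/K_d between ~5 and ~500 over the measured affinity
range, the fittable regime. Round-trip accuracy is exact to ≪1% noiselessly
across that c range and the median K_d error is ~5–7% at 2% multiplicative
heat noise.

Thermodynamic linkage uses R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K
(all tabulated measurements were at 25 °C), standard state 1 M:
ΔG = RT ln K_d, TΔS = ΔH − ΔG. The packaged binding table transcribes the
measured constructs; consistency checking recomputes TΔS per row and compares
at a 0.1 kcal/mol tolerance. Fold changes are K_d ratios, reported at the
conventions used in the narrative (nearest integer for the large effects,
one decimal for the small ones).

## Helicity and backbone dynamics

Secondary chemical-shift deviations (CSDs; observed minus sequence-corrected
random-coil) of Cα and C′ are linear reporters of helical population, with
full-helix references 2.8 ppm (Cα) and 2.1 ppm (C′). The estimator averages
each nucleus's CSDs over the residue window, divides by its reference, then
averages the two per-nucleus estimates (order of operations: average before
ratio per nucleus, then combine). Residues missing one nucleus contribute to
the other only and are flagged; the estimate is clamped to [0, 1] with a
clamp flag (negative CSDs indicate extended propensity, not negative
helicity). The estimator is linear in the CSDs and invariant to residue order
within the window.

Heteronuclear NOE classification: NOE ≤ 0 disordered, 0 < NOE < 0.6 flexible,
NOE ≥ 0.6 rigid. The lower anchor is the physical one (zero or negative NOEs
mean large-amplitude sub-nanosecond motion); the 0.6 cut for "rigid" is the
conventional well-ordered-backbone threshold and is configurable.

## Fold induction and gene grouping

ΔΔCt fold induction: 2^−ΔΔCt with a reference gene for loading and each
genotype's own unstimulated (t = 0) sample as calibrator. A gene is
TNFα-activated when its mean wild-type fold induction at 1 h is ≥ 2
(boundary inclusive). For each activated gene and each mutant the expression
defect is a Welch (unequal-variance) comparison of log2 fold inductions:
defective when the wild-type-minus-mutant difference is positive and its
central 95% confidence interval excludes zero. This is a deliberate,
fully-specified reimplementation, not a replica of any external
differential-expression tool; "95% confidence" is read as a 95% confidence
interval on the difference, giving a directional false-positive rate of 2.5%
per call — a per-gene one-sided test at α = 0.05 would misclassify ~10% of
truly interaction-independent genes (two calls per gene) and cap attainable
grouping accuracy below any useful threshold on a gene set dominated by that
class. No multiple-testing correction is applied by default, matching the
per-gene confidence framing; the calls nest in the confidence level (every
95% defect is a 67% defect), and the optional 67% relabel pass records the
group each gene would move to under the relaxed limit. Groups: A defective
in both mutants, B in the TAZ1-binding mutant only, C in the Ser276 mutant
only, D in neither; output sorted by the wild-type − TA2 difference at 1 h.

## Synthetic data

The generators emulate the statistical structure, not the raw instrument
output, of each measurement:

* **Time courses** — the model simulated at a true scale, normalized per the
  conventions, sampled at the experimental time grid (0–120 min, 8 points),
  plus independent additive Gaussian noise on the normalized scale
  (default σ = 0.05, densitometry-like).
* **Isotherms** — forward heats with multiplicative Gaussian noise
  (default 2% relative, instrument-like).
* **Expression tables** — 99 planted activated genes in groups of 20/25/6/48
  (A/B/C/D), wild-type log2 fold inductions uniform on [1.3, 4.5], mutant
  means attenuated by 2.5 log2 units according to group membership, 3
  replicates with Gaussian log2 noise (default σ = 0.25, i.e. log-normal on
  the fold scale), plus empty-vector and calibrator rows.
* **Shift tables** — per-residue CSDs around helicity × reference with
  additive Gaussian noise (default σ = 0.05 ppm).

Every generator consumes an integer seed (one pseudo-random stream per call)
and is bit-for-bit reproducible. What passing tests on these data do show:
the estimators are unbiased and well-powered under their own noise models at
the study's sample sizes. What they do not show: robustness to systematic
error absent from the generators — baseline drift and integration error in
real thermograms, normalization error correlated across time points in
densitometry, count-overdispersion and library-size artefacts in real
RNA-seq, or random-coil reference error in CSDs.

## Problem sizes and runtimes

The default test and acceptance runs use: 120–360 min simulation windows at
1–2 min output spacing (seventeen-species ODE, ~0.3 s per simulation
including equilibration); 20 replicates for each stochastic recovery study
(k_mRNA selection, ITC noise, helicity); 10 planted expression tables of 99
genes × 4 genotypes × 3 replicates for the grouping benchmark. The full
suite runs in ~15 s and the acceptance script in ~10 s on one CPU.

## Known limitations

* IKK is an input, not a mechanism: receptor/adaptor dynamics and the A20
  (*tnfaip3*) feedback arm are out of scope by design, so the model cannot
  address stimuli whose IKK profile is unknown.
* The parameter file is a reconstruction (see provenance above); quantitative
  trajectory details (peak times, oscillation period) should not be
  over-interpreted, and figure-level agreement with any specific dataset
  requires user-supplied time courses.
* The one-site ITC model excludes multi-site, competitive and displacement
  schemes, and operates on integrated per-injection heats, not raw power
  traces.
* The defect call treats replicates as independent; batch structure in real
  expression data would require a paired or mixed design.
* Helicity estimation assumes pre-computed, sequence-corrected CSDs; no
  random-coil reference computation is performed.
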