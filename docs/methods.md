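# Methods

## Model structure

The pathway is a deterministic reaction network in two well-mixed
compartments, cytoplasm (relative volume 1.0) and nucleus (0.25), with
concentrations in nM and time in hours.  Reactions follow mass-action
kinetics except gene transcription, which uses the standard activating
Hill form V·Mⁿ/(Kⁿ + Mⁿ) driven by the nuclear STAT5 dimer as a
modifier.  Species amounts are assumed large enough that the
deterministic limit applies; no stochastic simulation is provided.

The canonical core: HER4 binds JAK2 reversibly (kfR01/krR01); NRG binds
and activates the complex; active receptor phosphorylates cytoplasmic
STAT5 (kR06); phospho-STAT5 dimerizes and is imported into the nucleus
(kR15); a nuclear phosphatase binds the dimer (kfR19) and releases
dephosphorylated monomers (kR20) that are exported back (kR21).  The
dimer drives Hill transcription of two genes: SOCS — whose protein binds
the active receptor complex (SOCS_Binding_Rate), recruits SHP (kfR29)
and disassembles the complex (kR30), closing the negative-feedback loop
— and β-casein, whose nuclear mRNA is exported (kR45), degraded (kR46)
and translated (kR47).  Cytoplasmic phosphatases SHP and PPX deactivate
the receptor (kR05) and STAT5 monomer (kR08).

Two extensions are added by `add_heterodimerization` and
`add_jak_independent_branch`, each exactly three reactions:

* R41 (ligand-dependent, third order), R42 (constitutive) and R43
  (ligand binding to the preformed dimer) move free HER4 into a
  heterodimer pool with a lumped HER2+HER3 partner species.  These are
  *reversible*: the heterodimer pool equilibrates with free HER4, so the
  free fraction scales roughly as 1/(1 + c·[NRG]).  An irreversible sink
  was tried first and rejected — it makes the s80 share of HER4
  dose-independent, which destroys the late-window agonism; the
  equilibrated pool is also what the biology suggests for non-covalent
  receptor dimers.
* R36 (NRG-stimulated cleavage to the s80/4ICD fragment), R37 (slow
  activation, kR37 = 0.05 h⁻¹, i.e. a ~14 h half-time that places the
  branch's output in the 24–48 h window) and R39 (direct STAT5
  phosphorylation by active s80).  The branch is not a substrate of the
  SOCS feedback reaction.  kR39 = 0.5·kR06: smaller than the
  JAK-dependent rate, as required mechanistically; a 0.1× ratio was
  tried and discarded because no parameterization at that ratio
  reproduced the late-window agonism.

Two further modeling choices:

* **NRG is a boundary species** (clamped concentration).  The ligand
  sits in the culture medium in effective excess; letting 10–50 nM of
  NRG deplete against ~100 nM of receptor inverts the early dose
  response and is not what the experiments do.
* **Basal casein transcription** (k_basal_cas = 1 nM/h in the nucleus)
  represents the hydrocortisone/GR-driven component present in the
  zero-NRG control.  The experimental readout is fold change against
  that control, which requires a positive control signal.  The basal
  term is dose-independent and therefore cannot affect any dose trend.

Volume handling: a reaction's rate law is evaluated in its (reactant
side) compartment and converted to substance flux by that compartment's
volume; each species' concentration derivative divides by its own
compartment volume.  Amounts, not concentrations, are therefore
conserved across transport steps, and conservation laws live in the left
null space of the (boundary-masked) stoichiometry matrix.  The total
STAT5 moiety (monomers weight 1, dimer-containing species weight 2,
amount-weighted by compartment volume) is conserved to ~1e−15 relative
along baseline trajectories.

## Baseline parameterization

No external parameter file ships with the package's inputs, so the
baseline in `data/parameters.yaml` is a reconstruction: canonical-core
magnitudes follow the published JAK-STAT modeling literature (binding
~0.1 nM⁻¹h⁻¹, transport 0.5–8 h⁻¹, catalysis 0.01 nM⁻¹h⁻¹), and the
extension constants were calibrated — as the original model was against
its experiments — to reproduce the observed behaviors: a falling early
(0–12 h) and rising late (24–48 h) dose response over 10/20/50 nM NRG,
loss of each half of the switch under the corresponding ablation, a
switch ratio near unity at baseline, and a ~2.8 h STAT5→mRNA peak delay
when casein mRNA export is reduced to 0.1×.  Heterodimerization is more
favorable than HER4–JAK binding in effective-rate terms:
kfR41·[NRG]·[ERBB] ≈ 12–60 h⁻¹ against kfR01·[JAK] ≈ 5 h⁻¹ at the assay
doses (kfR41 is third order, so comparing raw constants is not
meaningful).  Initial amounts (HER4 100, partner pool 120, JAK 50, STAT5
200, phosphatases 50–60 nM) are typical receptor-signaling abundances.

## Simulation

`run_timecourse` integrates with LSODA (stiff-capable) at rtol 1e−8,
atol 1e−10 nM, sampling a uniform output grid (default 0.01 h; peak
detection does not rely on the raw grid, see below).  Halving the
tolerances changes every readout by <0.1% relative.  Concentrations are
clipped to 0 on output; pre-clip negativity beyond 1e−6 nM or any
non-finite value raises an `IntegrationError` carrying the offending
parameter set.  Ensembles draw from a Latin hypercube over a
`ParameterSpace` (rate constants log10-scaled over [0.1×, 10×] baseline
by default, initial amounts linear over [0.5×, 2×]; both overridable per
entry).  Failed members are dropped and logged, never imputed; summary
statistics require the dropout fraction to stay below 5%.  The error
bars shown by the CLI are ensemble SDs; SEMs are also computed.

## Readouts

Interval integrals use trapezoidal quadrature with interpolated interval
endpoints.  The switch ratio is ∫₀¹² / ∫₁₂⁴⁸ of cytoplasmic β-casein
mRNA (the inverse convention is available via `invert=True`); a zero
denominator is an error, not a sentinel.  The transcription delay
subtracts peak times located as the *first* local maximum with
prominence ≥1% of the profile range, refined by a quadratic fit through
the three surrounding grid points.  First-peak (rather than global
argmax) localization matters because slowly accumulating draws can end
the 48 h window above the early response peak, which would park the
global argmax on the grid boundary and destroy the timing information;
the quadratic refinement keeps ~0.01 h precision on 0.05 h grids, well
below the ~2–3 h delays of interest.  Dose trends are the sign of the
Theil–Sen slope across ≥3 doses — robust to a non-monotone middle dose —
with a relative deadband of 1e−3 of the mean level per 10 nM mapping to
0.

## Sensitivity analysis

Saltelli designs draw A and B as disjoint column blocks of one
2k-dimensional unscrambled Sobol' sequence (Joe–Kuo direction numbers
via scipy), with burn-in `skip` defaulting to the next power of two ≥ N;
A_B^i and B_A^i are column swaps, N(2k+2) model evaluations in total.
The estimators are the product forms given in the README, with f0²
estimated as mean(fA)·mean(fB) and V(Y) as the pooled sample variance of
fA and fB — a pairing that reduces the bias of the product estimators.
Negative index estimates are reported raw (they are Monte Carlo noise
around small true values); clipping at zero is applied only for
ranking and plotting.  No bootstrap confidence intervals are computed by
default.  Second-order indices are not estimated.

Model GSA inputs default to twelve flagged quantities — four initial
amounts (HER4, ERBB, JAK, SHP) and eight rate constants (transcription
V/K/n, transport kR15/kR45, heterodimerization kfR41, s80 kfR36/kR37) —
at 20 nM NRG, with trajectories on a 0.05 h grid at rtol 1e−6 (the
readouts are tolerance-robust well beyond the Monte Carlo noise at these
N).  The delay output uses a narrower 2× box: the peak-to-peak delay is
only defined where both species peak inside the 48 h window, and wider
boxes push >20% of draws into peakless regimes.  Rows whose integration
fails are excluded pairwise per output; >20% failures abort the
analysis as a bounds problem.

## Validation oracles

All oracles live in code paths disjoint from what they check: the
Ishigami closed-form indices (a=7, b=0.1) and the additive-model
identities validate the Saltelli estimators; a brute-force double-loop
(conditioning) Monte Carlo estimator cross-checks them independently;
the two-step decay network with its closed-form solution validates the
integrator to 1e−6 relative; LHS stratification and Sobol' dyadic
equidistribution are property-tested.  The pseudo-experiment generator
multiplies model fold changes by lognormal noise (control row pinned at
1, noise multiplicative and positive to respect fold-change semantics);
with σ=0.1 the switch signature is recovered in ≥90% of replicates.

## What the synthetic benchmarks do and do not show

The pseudo-experimental tables emulate the *structure* of RT-PCR
fold-change data (three intervals × a dose series, multiplicative
noise), not its biology: real measurements add plate effects,
normalization error and biological replicate variance, and the real
control involves glucocorticoid signaling that this model deliberately
reduces to a basal transcription constant.  Passing the recovery test
shows the pipeline detects the switch under measurement-scale noise, not
that the model is validated against the original cell-line data, which
are not numerically available.

## Known limitations

* The baseline is a behavior-calibrated reconstruction, not a fitted
  parameter set; absolute concentrations and integrals are in arbitrary
  but internally consistent units.
* A single lumped HER2+HER3 partner pool and a single cleavable HER4
  (no JM-a/JM-b, CYT-1/CYT-2 isoforms) are modeled.
* Hill parameters are shared between the SOCS and β-casein genes.
* Glucocorticoid-receptor signaling is not mechanistic; it enters only
  as the basal control term.
* SBML import reconstructs rate laws from the package's own annotations;
  arbitrary MathML kinetic laws from other tools are rejected rather
  than guessed at.  Events, rules, function definitions and constraints
  are outside the supported subset.
* Sensitivity indices at the smoke-test N=128 are screening values with
  visible Monte Carlo noise; stable rankings need larger N.
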