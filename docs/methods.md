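# Methods

## The estimation problem

A titratable residue's pKa in a folded protein differs from the model-compound
value pKa° measured on a capped peptide (e.g. ACE-AXA-NH2) in solution. The
shift is fixed by the double free-energy difference of deprotonation,

    ΔΔG = ΔG_deprot(protein) − ΔG_deprot(peptide),
    pKa = pKa° + s · ΔΔG / (R T ln 10),

with s = +1 for carboxylic acids (ASP, GLU) and s = −1 for the amine base
(LYS), because for a base the measured equilibrium is the protonation of the
neutral form. The package estimates each vertical leg of this thermodynamic
cycle from nonequilibrium alchemical work values, closes the cycle, and
converts to pKa against the references ASP 3.94 ± 0.03, GLU 4.25 ± 0.05,
LYS 10.4 ± 0.08 (overridable via a YAML/JSON config). R T ln 10 is always
computed from R = 0.0083144621 kJ/(mol K); at 298.15 K it is ≈ 5.708 kJ/mol.

## Work values and sign conventions

Each fast-switching transition yields a work value by thermodynamic
integration of dH/dλ over λ ∈ [0, 1] (trapezoidal rule; exact for the
piecewise-linear output a discrete λ schedule produces, and invariant to
redundant collinear grid points; the grid need not be uniform). Reverse works
are recorded along the reverse transition in its own direction, so the Crooks
fluctuation theorem reads

    P_F(W) / P_R(−W) = exp(β (W − ΔG)),   β = 1/(R T).

All energies are kJ/mol; kcal input requires an explicit conversion flag
(×4.184). XVG files indexed by time rather than λ are supported by mapping
the time column linearly onto [0, 1] behind an explicit flag, since switching
protocols drive λ linearly in time.

## BAR as the Crooks maximum-likelihood estimator

Pooling n_F forward and n_R reverse samples and asking, for each pooled work
value, whether it came from the forward or the reverse protocol gives a
Bernoulli likelihood in the single unknown ΔG. With M = ln(n_F/n_R)/β and
f(x) = 1/(1+e^x),

    ln L(ΔG) = Σ_F ln f(−β(M + W_F − ΔG)) + Σ_R ln f(β(M − W_R − ΔG)),

whose stationary point is the Bennett acceptance-ratio condition

    Σ_F f(β(M + W_F − ΔG)) = Σ_R f(β(W_R + ΔG − M)),

equivalent to Bennett's ΔG = C + ln(n_F/n_R)/β with C the acceptance-ratio
crossing point. Three properties pin the sign/offset conventions and are
enforced by tests rather than asserted: (i) the dissipation-free limit
W_F = {c}, W_R = {−c} returns ΔG = c exactly; (ii) swapping the forward and
reverse sets negates ΔG even when n_F ≠ n_R; (iii) duplicating every sample
leaves the estimate unchanged. The log-likelihood is evaluated with
log1p/log-add-exp formulations, so it is overflow-safe far from the optimum,
and its exhaustive grid maximization serves as the independent oracle for the
root in the tests.

Numerics: the root is bracketed in ±(max|W| + 50/β) — widened geometrically
in the (rare) case the heuristic bracket fails — and solved by Brent's method
to 1e-8 kJ/mol. The one-sided Jarzynski estimators (log-sum-exp form, sign
flipped for the reverse direction) are retained purely as cross-checks: they
bracket BAR on average, and on Gaussian works converge to μ − βσ²/2.

## Uncertainties

Bootstrap is the production error estimate: forward and reverse lists are
resampled independently with replacement at their original sizes, the
estimator re-run, and the SD over B resamples reported (default B = 1000; a
deterministic RNG seed makes every SE reproducible). Independent rather than
joint F/R resampling was chosen because the two directions come from
independent equilibrium simulations; no analytic Bennett variance is
implemented since bootstrap is the stated route, and the calibration test
(SE within 30% of the true sampling SD, ≈68% one-SE coverage) shows it is
sufficient. Resamples on which the estimator fails are redrawn and counted,
with a warning above 1% failures; a fully degenerate (zero-variance) WorkSet
returns SE = 0 exactly. Leg SEs propagate to ΔΔG in quadrature, and to pKa
after division by R T ln 10; the reference-constant uncertainty is included
by default and can be excluded (`include_ref_error=False`) to propagate
bootstrap errors only, which is the convention the analysis scripts use.

A histogram-overlap diagnostic (summed bin-wise minimum of the forward and
negated-reverse probability masses on a shared 50-bin grid) flags poorly
overlapping work distributions; below 0.03 a warning — deliberately not an
error — is attached to the estimate.

## Consensus

Per-residue predictions from different force fields are combined as the
unweighted mean of pKa values with se = sqrt(Σ se_i²)/k; inverse-variance
weighting is available behind a flag. Averaging pKa and averaging ΔΔG are
identical whenever the inputs share a class reference, which is the only
situation consensus accepts (mixed residues or mixed prediction kinds raise).

## Coupled titratable sites

For two interacting sites the four microstates (HH, H−, −H, −−) get relative
free energies 0, g_b, g_a, g_a + g_b + w with g_x(pH) = R T ln10 (pk_x − pH),
where pk_x is the intrinsic pKa (partner protonated) and w the interaction
free energy between the two deprotonated forms (w > 0: mutually disfavoring,
the generic case for an acidic dyad). Boltzmann weights are computed after
subtracting the per-pH minimum free energy, so normalization is exact at any
coupling strength. This grand-canonical microstate model is the minimal
formalism consistent with the pipeline's conditional free energies: w is an
input, derivable from two conditional ΔΔG values as their second difference
(`interaction_energy`). The w = 0 limit reproduces the one-site
Henderson–Hasselbalch curve identically, which anchors the model to the
uncoupled pipeline: when calculations suggest no coupling, the coupled
estimate collapses to the standard one.

The apparent pKa of a site is the pH at which its protonated-fraction
marginal crosses 1/2, located by monotone PCHIP interpolation plus Brent
refinement (xtol 1e-8 pH; grids of step ≤ 0.01 keep interpolation error below
1e-5 pH). A curve that never crosses 1/2 raises an error advising a wider
grid. Triads are reduced by fixing the site with the lowest intrinsic pKa as
the first deprotonation event and shifting the remaining intrinsic pKas by
their coupling to that site divided by R T ln 10; a tie for the lowest pKa is
an explicit error rather than a silent choice, since the reduction is not
invariant under that choice. Conditional predictions (e.g. computed with a
neighboring histidine clamped doubly protonated) carry a mandatory condition
string and a `conditional` kind; the benchmark refuses to average them with
standard predictions unless explicitly allowed.

Henderson–Hasselbalch fitting (`hh_fit`) performs a one-parameter
least-squares fit of f(pH) = 1/(1+10^(pH−pKa)) via `scipy.optimize.curve_fit`
seeded at the grid point nearest half-protonation; a flat curve is an error
(no information).

## Benchmark statistics

AUE is the mean |predicted − experimental| pKa; Pearson r uses the sample
correlation and treats zero variance as an error rather than returning NaN.
SEs for both come from resampling residues with replacement (degenerate
resamples skipped and counted for Pearson). The per-class breakdown reports
each class separately and an overall AUE equal to the unweighted mean of the
class AUEs — the convention for heterogeneous benchmarks — with
residue-weighted pooling behind a flag; the overall Pearson is always pooled,
because a within-class correlation and a cross-class correlation answer
different questions. The null model predicts pKa° for every residue, so its
error equals the true |ΔpKa| by construction and its within-class Pearson is
undefined (zero predictor variance) — the error contract above applies.
The convergence utility subsamples n transitions per direction without
replacement, reps times per n, and reports the mean and SD of the BAR
estimate; the SD is exactly 0 at the full set size.

## The synthetic work generator

MD output is replaced by distributions satisfying the Crooks theorem exactly
at the density level: Gaussian forward works N(ΔG + βσ²/2, σ²) and reverse
works N(−ΔG + βσ²/2, σ²), so βσ²/2 is the mean dissipated work on each side.
Scale mixtures of such pairs at a common ΔG stay Crooks-consistent (the same
exponential factor multiplies every component) and provide right- and
heavy-tailed stress tests, since real nonequilibrium work distributions are
typically skewed. The residue-dataset generator draws classes at the 57:48:39
ASP:GLU:LYS composition of the experimental benchmark it emulates, true
shifts from Normal(0, 1.5 pK) truncated to ±5 pK (shifts in folded proteins
can reach about ±5 pK), anchors the peptide-leg deprotonation free energy at
pKa°·R T ln10, and generates 200 transitions per direction per leg at
σ = 5 kJ/mol by default — 200 transitions being the protocol scale of the
campaigns this pipeline targets, and σ = 5 kJ/mol (≈2 k_B T of dissipation
width) a moderate-dissipation regime where BAR is accurate but errors are
visibly non-zero. A configurable fraction of acidic residues is paired into
dyads with w ~ Uniform(2, 8) kJ/mol recorded in the truth table. Everything
is deterministic under a seed (child seeds spawned per leg), and every latent
value is written to the truth table for recovery scoring.

What the generator does not emulate: conformational-sampling error (slow
degrees of freedom making forward/reverse distributions inconsistent with any
single ΔG), force-field error (the synthetic "truth" is by construction the
quantity the estimator targets), correlated transitions spawned from a common
equilibrium trajectory, and charge-artifact corrections. Passing recovery
tests therefore demonstrates the statistical machinery — estimator, error
propagation, cycle arithmetic, coupling model, scoring — not the physical
accuracy of any force field; the headline accuracies of real campaigns
(AUE ≈ 0.7 pK per class) depend on MD sampling that is out of scope here.

## Problem sizes and numerical defaults

The analysis scripts use a 144-residue benchmark, 200 transitions per
direction per leg, σ = 5 kJ/mol, B = 200 bootstrap resamples per leg and
B = 2000 for benchmark metrics. The validation suite uses 100-replicate
recovery grids over ΔG ∈ [−20, 20] kJ/mol and σ ∈ {1, 5, 10} kJ/mol at
n = 1000/1000, 1e5-sample density-ratio regressions, 200 regenerations for
bootstrap calibration, and 50-seed averages for monotonicity checks — sizes
chosen so every statistical assertion has comfortable power at desk scale.
Root solves: Brent, xtol 1e-8 kJ/mol (BAR) and 1e-8 pH (apparent pKa).
CSV round-trips write shortest-repr floats and read with round-trip float
parsing, so work tables survive a write/read cycle bit-identically.

## Known limitations

- The coupling model enumerates at most two free sites (dyads; triads via
  reduction); larger clusters and within-residue tautomers are out of scope.
- The "most probable deprotonation event" of a triad is ranked by intrinsic
  pKa; if couplings are strong enough to reorder the first deprotonation,
  the reduction is an approximation.
- Histidine appears only as a clamped neighbor condition, never as a probed
  residue (the probed classes are ASP/GLU/LYS).
- The pH-dependent environment term is resolved only through the coupling
  module; standard predictions assume neighbors fixed in their pH ≈ 7
  states, i.e. pKa(protein) ≈ pK_int.
- Bootstrap SEs inherit the usual small-n downward bias; at the default
  protocol scale (200 transitions) this is within the calibration factor
  verified by the tests.
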