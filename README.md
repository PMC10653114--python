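# neqpka

Protein pKa prediction from nonequilibrium alchemical free-energy
calculations: a pipeline that takes forward/reverse work values from
fast-switching (de)protonation transitions, estimates free energies with
Bennett's acceptance ratio (BAR) under the Crooks fluctuation theorem,
closes the protein-vs-peptide thermodynamic cycle, converts ΔΔG to pKa,
resolves coupled titratable residues pH-dependently, and scores predictions
with benchmark statistics. A Crooks-consistent synthetic work generator
replaces molecular-dynamics output, so the entire statistical machinery is
testable against known ground truth.

It is aimed at practitioners of alchemical free-energy methods (pmx/GROMACS
style nonequilibrium protocols) and at anyone who wants a transparent,
tested reference implementation of the BAR/Crooks estimator and of the
microstate treatment of interacting titratable sites.

## The model

For a residue of class c with model-compound reference pKa° (ASP 3.94,
GLU 4.25, LYS 10.4),

    pKa = pKa° + s · ΔΔG / (R T ln 10),      s = +1 (ASP, GLU), −1 (LYS)

where ΔΔG = ΔG_deprot(protein) − ΔG_deprot(peptide) and each leg ΔG is the
root of the Bennett self-consistency equation for n_F forward and n_R
reverse work samples (f(x) = 1/(1+e^x), M = ln(n_F/n_R)/β):

    Σ_F f(β(M + W_F − ΔG)) = Σ_R f(β(W_R + ΔG − M))

— the maximum-likelihood estimator implied by the Crooks relation
P_F(W)/P_R(−W) = exp(β(W − ΔG)). Uncertainties are bootstrap SDs,
propagated in quadrature through the cycle. Coupled sites (e.g. acidic
dyads closer than ~0.5 nm) are handled by a four-microstate model with
interaction free energy w; apparent pKas are read off each site's
half-protonation point, and triads are reduced via the most probable first
deprotonation. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from neqpka import (
    GeneratorSpec, gaussian_cft_pair, bar_estimate,
    ddg_from_legs, pka_from_ddg, DEFAULT_REFERENCES,
)

# stand-in for MD output: 200 forward/reverse works per leg, Crooks-consistent
protein = gaussian_cft_pair(GeneratorSpec(dg_true=28.0, sigma=5.0, seed=1))
peptide = gaussian_cft_pair(GeneratorSpec(dg_true=22.5, sigma=5.0, seed=2))

leg_p = bar_estimate(protein, n_boot=1000, seed=0)
leg_s = bar_estimate(peptide, n_boot=1000, seed=0)
cyc = ddg_from_legs(leg_p, leg_s, temperature=298.15)
pred = pka_from_ddg(cyc, DEFAULT_REFERENCES["ASP"], include_ref_error=False)
print(f"ddG = {cyc.ddg:.2f} +/- {cyc.se:.2f} kJ/mol")
print(f"pKa = {pred.pka:.2f} +/- {pred.se:.2f}")
```

prints

```
ddG = 5.26 +/- 0.37 kJ/mol
pKa = 4.86 +/- 0.06
```

i.e. the deprotonation penalty of 5.26 kJ/mol (true value 5.5, within one
combined SE) shifts this aspartate 0.92 pK above its reference 3.94; the
0.06 pK uncertainty is the two bootstrap leg errors propagated through
R·T·ln10. The same flow works from files: `load_workset` ingests GROMACS
XVG dH/dλ directories (integrated by the trapezoidal rule) or CSV work
tables, and the `neqpka` CLI exposes `ingest`, `estimate`, `cycle`,
`couple`, `benchmark`, and `simulate` subcommands.

## Analysis scripts

`analysis/01...06` run the full synthetic study end to end and write their
tables under `results/`:

1. `01_simulate_benchmark.py` — 144-residue benchmark with known true pKas
2. `02_estimate_free_energies.py` — BAR + bootstrap on all 288 legs
3. `03_predict_pka.py` — cycle closure and pKa conversion
4. `04_benchmark_scoring.py` — AUE / Pearson r per class, null model
5. `05_coupling_analysis.py` — dyad/triad titration, apparent pKas
6. `06_convergence_analysis.py` — estimate vs number of transitions

On this synthetic benchmark the pipeline reaches AUE ≈ 0.05 pK per class
(null model: 1.02 pK) — the statistical floor of the 200-transition
protocol at σ = 5 kJ/mol dissipation width, absent any force-field or
sampling error.

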