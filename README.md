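# gpcrbias

Quantitative pharmacology toolkit for **ligand bias at G protein-coupled
receptors**, built around the Black–Leff operational model. It was written
for the common experimental setting in opioid pharmacology: a candidate
agonist is profiled at the mu (MOR) and kappa (KOR) opioid receptors in a
G-protein readout (e.g. cAMP inhibition, GTPγS, G-protein BRET) and a
β-arrestin-2 recruitment readout (Tango or arrestin BRET), and one wants a
defensible number for how strongly the ligand prefers one transducer over
the other — together with the companion measurements such programs produce:
competition radioligand binding, warm-water tail-withdrawal antinociception,
place preference, respiration/locomotion, and salt-bridge occupancy from MD
simulations of the ligand–receptor complex.

## The model

Concentration–response data for agonist A follow the operational model

```
E(A) = Em · (τ·A)ⁿ / ((A + K_A)ⁿ + (τ·A)ⁿ)
```

with system maximum `Em` (fixed to the reference agonist's fitted top),
efficacy `τ`, functional affinity `K_A`, and transducer slope `n = 1` by
default. The *transduction coefficient* `log10(τ/K_A)` summarises agonism in
one number; for `n = 1` the model is algebraically a logistic curve with
`Emax_obs = Em·τ/(1+τ)` and `EC50_obs = K_A/(1+τ)`, so
`log10(τ/K_A) = log10(Emax_obs/Em) − log10(EC50_obs)` — a closed form the
package uses as an internal cross-check of every fit.

Bias is quantified against a balanced reference agonist (DAMGO at MOR,
U50,488h at KOR):

```
Δlog(τ/K_A)  = log(τ/K_A)_ligand − log(τ/K_A)_reference     (per pathway)
ΔΔlog(τ/K_A) = Δlog(G protein) − Δlog(arrestin)
bias factor  = 10^ΔΔlog
```

A bias factor > 1 whose 95% CI excludes 1 is called G-protein biased, < 1
arrestin biased, otherwise unbiased; curves too weak to fit yield an
explicit `not_determined`, never a number.

Companion modules implement Cheng–Prusoff competition binding
(`Ki = IC50/(1+[hot]/Kd)`), tail-withdrawal `%MPE = 100·(test−baseline)/
(cutoff−baseline)` with a 15 s censoring cutoff and log-scale ED50 CIs,
place-preference difference scores with Welch's t, vehicle-normalised
20-minute binning, and contact occupancy (fraction of MD frames with a
donor–carboxylate distance ≤ 4.5 Å). A seeded synthetic-data module
generates every input with known ground truth.

## Worked example

```python
from gpcrbias import AssayDesign, TruthRecord, gen_bias_panel, run_bias_pipeline
from gpcrbias.simulate import BIAS_PANEL_CONCENTRATIONS

design = AssayDesign(concentrations=BIAS_PANEL_CONCENTRATIONS, seed=1)
reference = TruthRecord("DAMGO", "gprotein", tau=100.0, ka=1e-7)
panels = gen_bias_panel(reference, {"cmpdX": 22.0}, design=design, receptor="MOR")
results = run_bias_pipeline(panels, {"MOR": "DAMGO"})
print(results.summary())
```

prints

```
Ligand bias (operational model, ddlog(tau/K_A))

ligand receptor reference  dlog_g  dlog_g_se  dlog_arrestin  dlog_arrestin_se  ddlog  ddlog_se  bias_factor  ci_lo  ci_hi    class
 DAMGO      MOR     DAMGO   0.000      0.024          0.000             0.007  0.000     0.000        1.000  1.000  1.000 unbiased
 cmpdX      MOR     DAMGO  -0.015      0.017         -1.230             0.017  1.215     0.024       16.411 14.492 18.583 g_biased
```

The simulated test compound was generated with a true bias factor of 22
(ΔΔlog = 1.342): on this seed the pipeline estimates 16.4 with a 95% CI of
[14.5, 18.6] and classifies it G-protein biased (over many seeds the
geometric mean sits within a few percent of 22), while the reference ligand
is exactly unbiased (bias factor ≡ 1) by construction. The same pipeline is
exposed on the command line (`gpcrbias simulate`, `gpcrbias fit-bias`,
`gpcrbias binding`, `gpcrbias ed50`, `gpcrbias cpp`, `gpcrbias clams`,
`gpcrbias occupancy`).

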