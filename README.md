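# pr10flex

Millisecond backbone flexibility of PR-10 food allergens from CPMG
relaxation-dispersion (RD) NMR, with chemical-shift-perturbation (CSP)
binding analysis and ligand-observed off-rate kinetics.

PR-10 allergens (the Bet v 1 fold: a seven-stranded antiparallel β-sheet
plus three α-helices around an internal cavity) are conformationally mobile
on the millisecond timescale, and that mobility is protein-specific even
between near-identical isoforms. This package implements the quantitative
pipeline behind that kind of study, for NMR spectroscopists and structural
biologists who have per-residue CPMG peak-intensity tables (or want
realistic synthetic ones):

- **Rates** — effective transverse relaxation rates
  `R2,eff = −ln(I/I₀)/T_relax` per residue, per CPMG frequency
  `ν_CPMG = n/T_relax`, per static field, with rate uncertainties σ pooled
  from repeat experiments.
- **Dispersion model** — exact two-site exchange
  (A ⇌ B, total rate k_ex, minor population p_B, shift difference Δδ_ex):
  the per-cycle CPMG propagator is evaluated analytically and cross-checked
  against an independent matrix-exponential Bloch–McConnell oracle.
- **Amplitudes** — per-residue dispersion amplitudes
  `ΔR2,eff = R2,eff(ν→0) − R2,eff(ν→∞)` from single-curve fits gated by an
  F-test against the no-exchange model, binned at 1/5/10 s⁻¹ for
  flexibility profiling and binding-site enrichment statistics.
- **Subglobal fits** — residue clusters (β-sheet/loops vs α-helices) fitted
  jointly across 600 and 700 MHz with shared (k_ex, p_B), residue-specific
  |Δδ_ex| and free per-curve R2,0; uncertainties from 100
  parametric-bootstrap (Monte Carlo) datasets; one- vs two-process model
  comparison by AIC; exchange timescale 1/k_ex.
- **Binding** — combined CSPs `Δδ_obs = √((Δδ_H² + (Δδ_N/5)²)/2)` along a
  titration, DMSO-drift correction, and per-residue K_D from the exact
  1:1 quadratic isotherm (ligand depletion matters at 0.2 mM protein
  against a ~0.76 mM K_D).
- **Kinetics** — ligand-observed ¹H dispersion at 0–12 % saturation fitted
  globally for the release rate k_off and the bound-state residence time
  1/k_off.

The experimental spectra behind the original study are not public, so the
`synthetic` module generates every input from the exact dispersion model:
it is a first-class, tested part of the package, and the cluster presets
(`arah8_helix`: k_ex = 1060 s⁻¹, p_B = 7.9 %, 20 residues;
`arah8_sheet`: k_ex = 810 s⁻¹, p_B = 1.3 %, 26 residues) carry the
study's fitted central values as ground truth.

## Worked example

```python
from pr10flex import (ClusterSpec, curves_from_table, fit_subglobal,
                      monte_carlo_uncertainty)
from pr10flex.constants import ARAH8_HELIX_RESIDUES
from pr10flex.synthetic import (backbone_schedule, simulate_dispersion_dataset,
                                truth_presets)

sched = backbone_schedule()                      # 30 ms, 33.3-933.3 Hz, 600+700 MHz
truth = truth_presets("arah8_helix", seed=11)
table = simulate_dispersion_dataset(truth, sched, noise_sigma=0.3, seed=2)
curves = curves_from_table(table, sched.relax_time)

spec = ClusterSpec("helix", ARAH8_HELIX_RESIDUES)
fit = fit_subglobal(curves, spec)
fit = monte_carlo_uncertainty(fit, curves, spec, n_datasets=100, seed=0)
print(f"kex = {fit.kex:.0f} +- {fit.kex_sigma:.0f} s^-1, "
      f"p_B = {100 * fit.p_b:.1f} %, timescale {fit.timescale_ms} ms")
```

```
kex = 1068 +- 7 s^-1, p_B = 7.9 %, timescale 0.9 ms
```

i.e. the 20 helix residues share one exchange process a little faster than
a millisecond, with a ~8 % populated minor state; the quoted error is the
standard deviation over 100 refits of bootstrap datasets at the
experimental rate noise.

The numbered scripts under `analysis/` run the full narrative —
simulation (`01`), rates/amplitudes/flexibility summary (`02`), subglobal
cluster fits with model comparison (`03`), titration K_D (`04`), ligand
k_off (`05`), and the self-validation studies (`06`) — writing tables under
`results/`. The same stages are available as a CLI
(`pr10flex run --seed 1 --outdir out`).

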