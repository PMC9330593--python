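# Methods

## The two-site exchange model

A nucleus exchanging between a major state A (population p_A = 1 − p_B) and
a sparsely populated state B (p_B, chemical-shift offset Δω = 2π·Δδ·γX/γH·B₀)
evolves under the 2×2 complex Bloch–McConnell matrix

    L = [ −R2A − k_AB        k_BA          ]
        [  k_AB         −R2B − k_BA − iΔω ]

with k_AB = k_ex·p_B and k_BA = k_ex·p_A (detailed balance). One CPMG cycle
is τ–180°–2τ–180°–τ with τ = T_relax/(4n) for n cycles in the period
T_relax; an ideal 180° pulse conjugates the transverse magnetization, so
the cycle acts as the complex-linear map U = e^{Lτ}·conj(e^{2Lτ})·e^{Lτ}.

Two independent implementations are kept:

- `model_r2eff_closed` / `r2eff_exact` — the *closed form*: e^{Lτ} from the
  analytic 2×2 matrix-exponential identity, Uⁿ through the eigenvalues of U
  (Lagrange form), R2,eff from the magnitude of the major-state component
  starting at equilibrium (p_A, p_B). This is exact at all timescales and
  populations and fully vectorized, so joint fits evaluate hundreds of
  points per call.
- `model_r2eff_numeric` — the *oracle*: scipy's general `expm` plus
  repeated matrix multiplication through the explicit pulse sequence.

The test suite and the acceptance script verify agreement to ≤1 %
(in practice ~1e-12 relative) over k_ex ∈ [100, 6000] s⁻¹,
p_B ∈ [0.005, 0.2], Δδ ∈ [0.2, 4] ppm at both fields. The Carver–Richards
approximation was evaluated first and rejected: it deviates by up to ~13 %
from the propagator in slow exchange at large p_B, outside the 1 % band.

Conventions: only |Δδ| matters (a sign flip conjugates the propagator and
leaves the observed magnitude unchanged). The ppm→rad/s conversion uses the
γ-ratio table in `constants.py` (¹⁵N: 0.101329 of ¹H) — a single source of
truth. Dispersion curves are monotone non-increasing in ν_CPMG throughout
the intermediate-to-fast regime this study occupies (k_ex ≥ ~500 s⁻¹,
Δδ ≤ 3.5 ppm), and the property tests assert this there; in deep slow
exchange (k_ex ≲ 300 s⁻¹ with Δδ ~ 4 ppm) the exact solution genuinely
oscillates (slow-exchange resonance spikes), which is physics, not error.

## Rates and uncertainties

R2,eff = −ln(I/I₀)/T_relax; non-positive intensities give NaN (point
flagged unquantifiable, never clipped or dropped silently). Repeat
experiments give σ per pair as |ΔR|/√2, pooled root-mean-square. By default
the pairs of all residues at one field share a single pooled σ: each curve
has only two duplicated frequencies, and a per-residue two-pair estimate is
too noisy to weight a χ² fit reliably (it biased k_ex by several percent in
simulation, and made the bootstrap σ underestimate the true scatter).
Per-residue pooling remains available. A σ floor of 0.05 s⁻¹ prevents
zero-weight points.

## Per-residue amplitudes

ΔR2,eff is the fitted model's R2,eff(ν→0) − R2,eff(ν→∞): the zero-frequency
limit is −Re λ_slow(L) (the free-precession linewidth of the observed
line), the infinite-frequency limit the population-averaged intrinsic rate.
Single-curve fits use the full closed form with a multi-start grid
(k_ex ∈ {200, 500, 1000, 2000, 4000} s⁻¹ × p_B ∈ {0.01, 0.05, 0.15}, Δδ
seeded from the fast-exchange amplitude relation), candidates ranked by
initial misfit with the best few optimized; ties go to the smaller k_ex.
Because the extrapolation below the first measured frequency is
unconstrained, an exchange model can always absorb noise into a spurious
amplitude (pure-noise curves exceeded the 1 s⁻¹ threshold in ~18 % of
simulations); the exchange fit is therefore accepted only when it beats the
constant-rate fit in an F-test at α = 0.01, which brings the false-positive
rate below 1 % while amplitudes ≳1.5 s⁻¹ are still detected in most
replicates. The single-curve *parameters* are not interpreted — they sit in
a shallow χ² valley — only the amplitude is.

## Subglobal cluster fits

Each cluster (26 β-sheet/loop residues, 20 helix residues; packaged
constants) is fitted jointly over both fields: shared (k_ex, p_B),
residue-specific |Δδ_ex|, and a free R2,0 per residue per field (intrinsic
rates differ by residue and field; sharing them would bias k_ex). The
objective is Σ((data − model)/σ)² minimized by bounded trust-region least
squares; (k_ex, p_B) starts come from a grid
({200, 500, 800, 1200, 2000, 4000} × {0.01, 0.03, 0.08, 0.15}), ranked by
initial χ² with the best `max_starts` optimized — multi-start is what makes
these fits reproducible despite the known convergence problems of global
dispersion fitting. The low-p_B (p_B, Δδ) trade-off is broken by the field
dependence of Δω together with the exchange-regime information; noiseless
two-field fits recover truth to optimizer precision, which the tests
assert. Single-field fits are permitted with a warning.

Parameter errors are parametric bootstrap: `n_datasets` (default 100, the
standard choice) synthetic datasets from the fitted parameters with
Gaussian rate noise at the experimental σ, each refitted warm-started from
the fit; quoted σ are standard deviations over the refits. Coverage of the
1-σ interval is checked by simulation (~68 %). One- versus two-process
descriptions are compared by AIC (χ² + 2k with known σ); "two processes
preferred" requires ΔAIC > 10 — a fixed, testable stand-in for a visual
quality judgement. Timescale = 1000/k_ex ms, one decimal.

Fitted |Δδ_ex| can be compared against a user-supplied unfolding-shift
reference (|assigned − random coil|; computing random-coil shifts is out of
scope): Pearson correlation, fraction smaller, and a "smaller than
unfolding" flag at fraction > 0.8.

## Titration and K_D

Combined CSP: Δδ_obs = √((Δδ_H² + (Δδ_N/5)²)/2). The DMSO-only reference
shift is subtracted per dimension, scaled linearly by the co-solvent
fraction, *before* the CSP is formed. Binding uses the exact 1:1 quadratic
root [PL] = ((P+L+K_D) − √((P+L+K_D)² − 4PL))/2 — at 0.2 mM protein against
K_D ≈ 0.76 mM the hyperbolic (no-depletion) approximation is measurably
biased. Per-residue trajectories Δδ_obs = Δδ_max·f_bound are fitted over
(K_D, Δδ_max) by nonlinear least squares; only residues whose corrected
CSP exceeds 0.1 ppm enter the reported unweighted mean ± sd. Dilution by
titrant addition is tracked from the stated volumes (450 µL start, 90 mM
stock in DMSO): reaching protein:ligand ratio r takes r µL of stock for a
0.2 mM sample, giving a maximum co-solvent fraction of 30/480 ≈ 6.3 %.
The CSP trajectory is referenced to the zero-ligand spectrum.

## Ligand kinetics

The free ligand resonance at bound fraction p (saturation) exchanges with
the bound environment at k_ex = k_off/(1 − p). All saturation levels are
fitted simultaneously sharing (k_off, Δω_bound, R2,free, R2,bound), with p
fixed per sample from the composition. Saturation defaults to the
stoichiometric convention P_total/L_total (240 µM against 2 mM ⇒ 12 %,
matching the stated range); the K_D-based bound fraction is available as an
option. The zero-protein control must be flat (it anchors R2,free and
confirms the <2 Hz ⁴J_HH coupling is invisible on this schedule); an
all-flat series raises "insufficient dispersion". The transverse relaxation
filter only scales overall intensity, which cancels in I/I₀. Residence
time = 1000/k_off ms.

## Synthetic data

The generator emulates: two-field backbone ¹⁵N dispersion (30 ms period,
33.3–933.3 Hz with repeats at 66.7 and 600 Hz) from the cluster presets,
with per-residue |Δδ_ex| drawn uniformly from 0.3–3.5 ppm and intrinsic
rates from 12–18 s⁻¹ unless supplied; 17-point titrations with dilution,
DMSO drift and 0.005 ppm shift noise; and ligand ¹H dispersion (60 ms
period, 66.7–2000 Hz, repeats at 400/933.3/1600 Hz) at 0–12 % saturation.
Noise is applied on the rate scale (experimental σ is quoted on rates),
i.e. multiplicatively log-normal on intensities; the default
σ = 0.3 s⁻¹ is a documented choice — no experimental intensity noise level
is stated — picked so that detection against the 1 s⁻¹ amplitude threshold
behaves realistically. Repeat points get independent draws; identical
seeds give bit-identical tables.

Not emulated: lineshapes/peak overlap (intensities are taken as given
numbers; peak integration is upstream), off-resonance and pulse
imperfections, anti-phase relaxation (¹H decoupling during the ¹⁵N CPMG
justifies the in-phase model), three-site exchange, temperature effects.
Passing recovery tests therefore demonstrates the *estimator* is unbiased
and calibrated under the stated noise model, not that real spectra are this
clean.

## Problem sizes and numerics

The recovery studies use 10 synthetic datasets per cluster at σ = 0.3 s⁻¹,
100 bootstrap refits for errors, 3 titration/ligand replicates, and a
4×4×5-point parameter grid × both fields × the full schedule for the
model-vs-oracle comparison; the test suite scales the bootstrap-coverage
simulation down (3-residue cluster, 30 outer replicates, 25 refits each).
Optimizer bounds: k_ex ∈ [10, 2·10⁴] s⁻¹, p_B ∈ (10⁻⁴, 0.5] (state A is
always the major state), Δδ ∈ [0, 10] ppm, R2,0 ∈ [0.05, 100] s⁻¹.
Degenerate inputs: p_B = 0 or Δδ = 0 give exactly flat curves; repeated
eigenvalues in the propagator power fall back to the confluent (Jordan)
form; cosh overflow is avoided by the eigenvalue formulation. All
randomness flows through explicit integer seeds; the pipeline derives one
child seed per stage from a master seed via `numpy.random.SeedSequence`.

## Known limitations

- Cross-protein residue alignment is identity by default; a mapping table
  is accepted but no alignment is computed.
- The per-protein flexibility percentages of a real multi-allergen panel
  are not reproducible here — they require the unpublished experimental
  data; percentages are computed over evaluable residues only, with
  missing positions carrying explicit reasons (gap/overlap/proline/
  unassigned).
- The AIC > 10 two-process criterion and the F-test α = 0.01 amplitude
  gate are documented conventions, not measured properties of the original
  analysis.
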