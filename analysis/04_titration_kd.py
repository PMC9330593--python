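#!/usr/bin/env python
"""Chemical-shift-perturbation titration and K_D determination.

Simulates the 17-point epicatechin titration of a 0.2 mM protein sample
(molar ratios 0.5-30, dilution and DMSO drift tracked from the stated
volumes, 0.005 ppm shift noise), corrects the trajectories for the
co-solvent, and fits per-residue dissociation constants with the exact
1:1 quadratic isotherm.
"""

from pathlib import Path

from pr10flex.io import write_csv, write_json
from pr10flex.synthetic import simulate_titration_series
from pr10flex.titration import fit_kd

OUT = Path("results")
SEED = 22
KD_TRUTH = 0.76  # mM

if __name__ == "__main__":
    drift = {r: (0.02, -0.15) for r in range(1, 16)}  # mild DMSO drift
    series = simulate_titration_series(kd=KD_TRUTH, noise_ppm=0.005,
                                       dmso_drift=drift, seed=SEED)
    fit = fit_kd(series, threshold=0.1)
    write_csv(fit.per_residue, OUT / "titration_per_residue.csv")
    write_json({"mean_kd_mm": fit.mean_kd, "sd_kd_mm": fit.sd_kd,
                "threshold_ppm": fit.threshold,
                "residues_used": fit.residues_used,
                "kd_truth_mm": KD_TRUTH},
               OUT / "titration_kd.json")
    print(f"{len(fit.residues_used)} residues above the 0.1 ppm CSP threshold")
    print(f"mean K_D = {fit.mean_kd:.2f} +- {fit.sd_kd:.2f} mM "
          f"(ground truth {KD_TRUTH} mM)")
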