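#!/usr/bin/env python
"""Ligand-observed 1H dispersion and off-rate kinetics.

Simulates 600 MHz ligand-proton dispersion at 0-12% saturation (protein
0-240 uM against 2 mM ligand, 60 ms CPMG element), one series per aromatic
proton with its own ground-truth off-rate, and extracts k_off and the
bound-state residence time from a global two-site fit with parametric-
bootstrap errors.
"""

from pathlib import Path

from pr10flex.io import write_json
from pr10flex.ligand import fit_koff, saturation_levels
from pr10flex.synthetic import simulate_ligand_dispersion

OUT = Path("results")
SEED = 23
TRUTHS = {"H6": 1600.0, "H8": 1300.0}

if __name__ == "__main__":
    sats = saturation_levels([0, 40, 80, 120, 160, 200, 240], 2.0)
    print(f"saturation levels: {[f'{100 * s:.0f}%' for s in sats]}")
    for offset, (proton, koff) in enumerate(TRUTHS.items()):
        series = simulate_ligand_dispersion(koff, sats, noise_sigma=0.3,
                                            seed=SEED + offset, proton=proton)
        fit = fit_koff(series, mc_datasets=100, seed=SEED)
        write_json(fit.to_dict(), OUT / f"ligand_koff_{proton}.json")
        print(f"{proton}: k_off = {fit.koff:.0f} +- {fit.koff_sigma:.0f} s^-1 "
              f"-> residence {fit.residence_ms} ms (truth {koff:.0f} s^-1)")
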