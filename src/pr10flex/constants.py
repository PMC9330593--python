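"""Physical constants and packaged experimental layouts.

Single source of truth for the ppm -> rad/s conversion and for the Ara h 8
acquisition schedules and subglobal cluster memberships used throughout the
pipeline.
"""

from __future__ import annotations

import numpy as np

#: Gyromagnetic ratio of each nucleus relative to 1H.  The Larmor frequency of
#: nucleus X on a spectrometer whose 1H frequency is ``field_mhz`` is
#: ``GAMMA_RATIO[X] * field_mhz`` (in MHz).
GAMMA_RATIO: dict[str, float] = {
    "1H": 1.0,
    "15N": 0.101329,
}

SCHEMA_VERSION = "pr10flex-1"


def delta_ppm_to_rad_s(delta_ppm: float, field_mhz: float, nucleus: str) -> float:
    """Convert a chemical-shift difference (ppm) to angular frequency (rad/s).

    ``field_mhz`` is the spectrometer 1H frequency; the nucleus Larmor
    frequency is obtained through :data:`GAMMA_RATIO`.
    """
    try:
        ratio = GAMMA_RATIO[nucleus]
    except KeyError:
        raise ValueError(f"unknown nucleus {nucleus!r}; expected one of {sorted(GAMMA_RATIO)}")
    # ppm * (Larmor MHz) = Hz;  * 2 pi = rad/s
    return float(delta_ppm) * ratio * float(field_mhz) * 2.0 * np.pi


# --- Backbone amide 15N CPMG schedule -------------------------------------
# 30 ms relaxation period; nu_CPMG = n / T_relax gives the 33.3 ... 933.3 Hz
# series, with repeat experiments at 66.7 and 600.0 Hz.
BACKBONE_RELAX_TIME = 0.030  # s
BACKBONE_N_CYCLES = (1, 2, 3, 4, 5, 6, 8, 10, 14, 18, 22, 28)
BACKBONE_REPEAT_CYCLES = (2, 18)
BACKBONE_FIELDS = (600.0, 700.0)  # MHz (1H)

# --- Ligand-observed 1H CPMG schedule -------------------------------------
# 60 ms relaxation period, 66.7 ... 2000.0 Hz; repeats at 400, 933.3, 1600 Hz.
LIGAND_RELAX_TIME = 0.060  # s
LIGAND_N_CYCLES = (4, 8, 16, 24, 32, 40, 48, 56, 64, 72, 80, 88, 96, 104, 112, 120)
LIGAND_REPEAT_CYCLES = (24, 56, 96)
LIGAND_FIELD = 600.0  # MHz
LIGAND_FILTER_TIME = 0.060  # s, transverse-relaxation filter

# --- Ara h 8.0101 subglobal clusters --------------------------------------
# Residues with dispersion amplitude > 1 s^-1 at 700 MHz, grouped by
# secondary structure: central beta-sheet + loops L1/L3-L9 versus the three
# alpha-helices (incl. loop L2).
ARAH8_SHEET_RESIDUES: tuple[int, ...] = (
    37, 38, 39, 41, 43, 47, 50, 53, 55, 56, 66, 67, 73, 74,
    84, 87, 88, 89, 97, 98, 99, 100, 101, 102, 115, 118,
)
ARAH8_HELIX_RESIDUES: tuple[int, ...] = (
    16, 17, 20, 21, 22, 23, 24, 25, 27, 31, 33,
    123, 128, 134, 137, 138, 139, 145, 146, 156,
)

# Backbone amides with ligand-induced CSP > 0.1 ppm: the epicatechin
# binding site mapped in solution (helices a1-a3, strands b2-b6 lining the
# internal cavity).
ARAH8_BINDING_SITE_RESIDUES: tuple[int, ...] = (
    22, 25, 31, 33, 34, 36, 55, 56, 57, 87, 98, 138, 141, 145,
)

# Ara h 8.0101 resonance-assignment bookkeeping: 144 of 146 non-proline
# backbone amides assigned (N-terminal glycine excluded).
ARAH8_ASSIGNED_RESIDUES = 144
ARAH8_NONPROLINE_RESIDUES = 146
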