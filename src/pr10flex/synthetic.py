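"""Synthetic data generation for every stage of the pipeline.

All downstream analyses (rate extraction, subglobal exchange fits, K_D
titration, ligand kinetics) are exercised on data generated here from a
numerically exact two-site exchange model, so the whole pipeline is
testable end to end without experimental spectra.

Noise model: experimental uncertainty is quoted on the rate scale, so
Gaussian noise of standard deviation ``noise_sigma`` (s^-1) is added to the
model R2,eff before converting back to intensities (equivalently, a
multiplicative log-normal perturbation of the intensities).  Repeat points
receive independent noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import constants as C
from .dispersion import model_r2eff_closed

__all__ = [
    "TwoSiteTruth",
    "CpmgSchedule",
    "truth_presets",
    "simulate_dispersion_dataset",
    "simulate_titration_series",
    "simulate_ligand_dispersion",
    "TitrationSeries",
    "LigandRDSeries",
]

#: Default rate-scale noise (s^-1); chosen so that flat-curve detection
#: against the 1 s^-1 amplitude threshold behaves realistically.
DEFAULT_NOISE_SIGMA = 0.3

#: Default per-residue |ddelta_ex| sampling range (ppm, 15N) for presets.
DEFAULT_DELTA_RANGE = (0.3, 3.5)


@dataclass
class TwoSiteTruth:
    """Ground-truth two-site exchange parameters for a residue cluster."""

    kex: float  # s^-1, k_AB + k_BA
    p_b: float  # minor-state population
    delta_ppm: dict[int, float]  # residue -> |ddelta_ex| (ppm)
    r2_0: dict[tuple[int, float], float]  # (residue, field MHz) -> s^-1
    nucleus: str = "15N"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if not 0.0 <= self.p_b <= 0.5:
            raise ValueError("p_b must lie in [0, 0.5]")
        if any(d < 0 for d in self.delta_ppm.values()):
            raise ValueError("delta_ppm values must be non-negative")
        if any(r <= 0 for r in self.r2_0.values()):
            raise ValueError("r2_0 values must be positive")

    @property
    def residues(self) -> list[int]:
        return sorted(self.delta_ppm)


@dataclass
class CpmgSchedule:
    """CPMG acquisition layout: cycle counts, period, fields, repeats."""

    relax_time: float  # s
    n_cycles: tuple[int, ...]
    fields: tuple[float, ...]  # MHz (1H)
    repeats: tuple[int, ...] = ()
    nucleus: str = "15N"

    def __post_init__(self) -> None:
        if self.relax_time <= 0:
            raise ValueError("relax_time must be positive")
        if any(n < 1 for n in self.n_cycles):
            raise ValueError("n_cycles must all be >= 1")
        if not set(self.repeats) <= set(self.n_cycles):
            raise ValueError("repeats must be a subset of n_cycles")

    @property
    def nu_cpmg(self) -> np.ndarray:
        return np.asarray(self.n_cycles) / self.relax_time


def backbone_schedule() -> CpmgSchedule:
    """The 15N backbone schedule: 30 ms period, 33.3-933.3 Hz, 600+700 MHz."""
    return CpmgSchedule(
        relax_time=C.BACKBONE_RELAX_TIME,
        n_cycles=C.BACKBONE_N_CYCLES,
        fields=C.BACKBONE_FIELDS,
        repeats=C.BACKBONE_REPEAT_CYCLES,
        nucleus="15N",
    )


def ligand_schedule() -> CpmgSchedule:
    """The 1H ligand-observed schedule: 60 ms period, 66.7-2000 Hz, 600 MHz."""
    return CpmgSchedule(
        relax_time=C.LIGAND_RELAX_TIME,
        n_cycles=C.LIGAND_N_CYCLES,
        fields=(C.LIGAND_FIELD,),
        repeats=C.LIGAND_REPEAT_CYCLES,
        nucleus="1H",
    )


def truth_presets(name: str, delta_ppm: dict[int, float] | None = None,
                  seed: int = 0) -> TwoSiteTruth:
    """Ground-truth presets for the two Ara h 8.0101 subglobal clusters.

    ``arah8_helix``: kex = 1060 s^-1, p_B = 0.079, the 20 helix residues.
    ``arah8_sheet``: kex = 810 s^-1, p_B = 0.013, the 26 sheet/loop residues.

    Per-residue |ddelta_ex| values are drawn uniformly from
    ``DEFAULT_DELTA_RANGE`` (seeded) unless supplied; intrinsic rates are
    drawn in a realistic 12-18 s^-1 window per residue and field.
    """
    presets = {
        "arah8_helix": (1060.0, 0.079, C.ARAH8_HELIX_RESIDUES),
        "arah8_sheet": (810.0, 0.013, C.ARAH8_SHEET_RESIDUES),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(presets)}")
    kex, p_b, residues = presets[name]
    rng = np.random.default_rng(seed)
    if delta_ppm is None:
        lo, hi = DEFAULT_DELTA_RANGE
        delta_ppm = {r: float(d) for r, d in zip(residues, rng.uniform(lo, hi, len(residues)))}
    r2_0 = {}
    for r in residues:
        for f in C.BACKBONE_FIELDS:
            r2_0[(r, f)] = float(rng.uniform(12.0, 18.0))
    return TwoSiteTruth(kex=kex, p_b=p_b, delta_ppm=dict(delta_ppm), r2_0=r2_0,
                        nucleus="15N", seed=seed)


def simulate_dispersion_dataset(truth: TwoSiteTruth, schedule: CpmgSchedule,
                                noise_sigma: float = DEFAULT_NOISE_SIGMA,
                                seed: int | None = None,
                                i0: float = 1e6) -> pd.DataFrame:
    """Simulate a tidy intensity table from two-site exchange ground truth.

    Returns a DataFrame with columns (residue, field_mhz, nu_cpmg_hz,
    n_cycles, intensity, i0, replicate_id).  Intensities are
    I = I0 exp(-R2eff_model * T_relax) with rate-scale Gaussian noise of sd
    ``noise_sigma``; repeat cycle counts appear twice with independent
    noise (replicate_id 0 and 1).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for res in truth.residues:
        dppm = truth.delta_ppm[res]
        for f in schedule.fields:
            try:
                r2_0 = truth.r2_0[(res, f)]
            except KeyError:
                raise ValueError(f"truth has no r2_0 for residue {res} at {f} MHz")
            nus = schedule.nu_cpmg
            model = model_r2eff_closed(truth.kex, truth.p_b, dppm, r2_0, f,
                                       truth.nucleus, nus,
                                       relax_time=schedule.relax_time)
            for n, nu, r2 in zip(schedule.n_cycles, nus, np.atleast_1d(model)):
                n_rep = 2 if n in schedule.repeats else 1
                for rep in range(n_rep):
                    r2_noisy = r2 + rng.normal(0.0, noise_sigma)
                    rows.append({
                        "residue": res,
                        "field_mhz": f,
                        "nu_cpmg_hz": float(nu),
                        "n_cycles": int(n),
                        "intensity": i0 * np.exp(-r2_noisy * schedule.relax_time),
                        "i0": i0,
                        "replicate_id": rep,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------

#: The 17 protein:ligand molar ratios of the titration, in addition order.
TITRATION_RATIOS = (0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30)

TITRATION_START_VOLUME_UL = 450.0
TITRATION_STOCK_MM = 90.0
TITRATION_MAX_DMSO_UL = 30.0


@dataclass
class TitrationSeries:
    """Per-residue 1H/15N peak positions along a ligand titration."""

    table: pd.DataFrame  # residue, point_index, ratio, p_mm, l_mm, dmso_fraction, delta_h_ppm, delta_n_ppm
    protein_conc: float  # starting concentration, mM
    kd_truth: float | None = None
    dmso_reference: pd.DataFrame | None = None  # residue, dmso_h_ppm, dmso_n_ppm
    max_dmso_fraction: float = TITRATION_MAX_DMSO_UL / (TITRATION_START_VOLUME_UL + TITRATION_MAX_DMSO_UL)


def titration_concentrations(ratios=TITRATION_RATIOS,
                             protein_conc: float = 0.2,
                             start_volume_ul: float = TITRATION_START_VOLUME_UL,
                             stock_mm: float = TITRATION_STOCK_MM) -> pd.DataFrame:
    """Concentrations and DMSO fractions along the stepwise titration.

    Ligand is added from a concentrated DMSO stock; dilution of the protein
    and the accumulating co-solvent fraction are tracked from the stated
    volumes.  With a 0.2 mM / 450 uL sample and a 90 mM stock, reaching
    molar ratio r requires r microlitres of stock in total.
    """
    n_protein = protein_conc * start_volume_ul  # nmol
    rows = []
    for i, r in enumerate(ratios):
        added_ul = r * n_protein / stock_mm  # cumulative stock volume
        vol = start_volume_ul + added_ul
        rows.append({
            "point_index": i,
            "ratio": float(r),
            "p_mm": n_protein / vol,
            "l_mm": r * n_protein / vol,
            "dmso_fraction": added_ul / vol,
        })
    return pd.DataFrame(rows)


def simulate_titration_series(kd: float, protein_conc: float = 0.2,
                              ratios=TITRATION_RATIOS,
                              endpoint_shifts: dict[int, tuple[float, float]] | None = None,
                              dmso_drift: dict[int, tuple[float, float]] | None = None,
                              noise_ppm: float = 0.005,
                              seed: int = 0) -> TitrationSeries:
    """Simulate fast-exchange titration shift trajectories.

    Per point, each residue's (1H, 15N) position is the free-state value
    (0 ppm baseline; only differences matter) plus protein-bound-fraction x
    endpoint shift, plus a linear DMSO drift scaled by the co-solvent
    fraction, plus Gaussian noise of sd ``noise_ppm`` on each dimension.
    Binding uses the exact 1:1 quadratic isotherm with ligand depletion.
    """
    from .titration import bound_fraction

    if kd <= 0:
        raise ValueError("kd must be positive")
    if protein_conc < 0 or any(r <= 0 for r in ratios):
        raise ValueError("concentrations and ratios must be positive")
    rng = np.random.default_rng(seed)
    if endpoint_shifts is None:
        # 15 reporter residues with endpoint CSPs between 0.05 and 0.5 ppm
        endpoint_shifts = {
            res: (float(rng.uniform(0.05, 0.45)), float(rng.uniform(-2.0, 2.0)))
            for res in range(1, 16)
        }
    if dmso_drift is None:
        dmso_drift = {res: (0.0, 0.0) for res in endpoint_shifts}
    conc = titration_concentrations(ratios, protein_conc)
    max_dmso = TITRATION_MAX_DMSO_UL / (TITRATION_START_VOLUME_UL + TITRATION_MAX_DMSO_UL)
    rows = []
    for _, pt in conc.iterrows():
        fb_p, _ = bound_fraction(pt.p_mm, pt.l_mm, kd)
        for res, (eh, en) in endpoint_shifts.items():
            dh_drift, dn_drift = dmso_drift.get(res, (0.0, 0.0))
            scale = pt.dmso_fraction / max_dmso
            rows.append({
                "residue": res,
                "point_index": int(pt.point_index),
                "ratio": pt.ratio,
                "p_mm": pt.p_mm,
                "l_mm": pt.l_mm,
                "dmso_fraction": pt.dmso_fraction,
                "delta_h_ppm": fb_p * eh + scale * dh_drift + rng.normal(0, noise_ppm),
                "delta_n_ppm": fb_p * en + scale * dn_drift + rng.normal(0, noise_ppm),
            })
    dmso_ref = pd.DataFrame({
        "residue": list(endpoint_shifts),
        "dmso_h_ppm": [dmso_drift.get(r, (0.0, 0.0))[0] for r in endpoint_shifts],
        "dmso_n_ppm": [dmso_drift.get(r, (0.0, 0.0))[1] for r in endpoint_shifts],
    })
    return TitrationSeries(table=pd.DataFrame(rows), protein_conc=protein_conc,
                           kd_truth=kd, dmso_reference=dmso_ref,
                           max_dmso_fraction=max_dmso)


# ---------------------------------------------------------------------------
# Ligand-observed dispersion
# ---------------------------------------------------------------------------

@dataclass
class LigandRDSeries:
    """Ligand 1H dispersion profiles at a set of protein saturations."""

    table: pd.DataFrame  # sample_id, saturation, nu_cpmg_hz, n_cycles, r2_eff, sigma, replicate_id
    proton: str
    field: float
    relax_time: float
    filter_time: float = C.LIGAND_FILTER_TIME
    koff_truth: float | None = None


def simulate_ligand_dispersion(koff: float, saturations,
                               delta_omega_h: float = 1.0,
                               r2_free: float = 3.0, r2_bound: float = 40.0,
                               schedule: CpmgSchedule | None = None,
                               noise_sigma: float = DEFAULT_NOISE_SIGMA,
                               seed: int = 0, proton: str = "H6") -> LigandRDSeries:
    """Simulate ligand-observed 1H dispersion vs protein saturation.

    The ligand is a two-site free <-> bound exchanger with bound population
    p = saturation and release rate k_off; the total exchange rate is
    kex = k_off / (1 - p) by detailed balance.  R2,eff values come from the
    same exact propagator as the backbone simulation, on 1H, with distinct
    free/bound intrinsic rates, then carry rate-scale Gaussian noise.
    """
    if koff <= 0:
        raise ValueError("koff must be positive")
    saturations = list(saturations)
    if any(not (0.0 <= s < 0.5) for s in saturations):
        raise ValueError("saturations must lie in [0, 0.5)")
    if schedule is None:
        schedule = ligand_schedule()
    rng = np.random.default_rng(seed)
    f = schedule.fields[0]
    rows = []
    for sample_id, sat in enumerate(saturations):
        nus = schedule.nu_cpmg
        if sat == 0.0:
            model = np.full(len(nus), r2_free)
        else:
            kex = koff / (1.0 - sat)
            model = np.atleast_1d(model_r2eff_closed(
                kex, sat, delta_omega_h, r2_free, f, "1H", nus,
                r2_0_b=r2_bound, relax_time=schedule.relax_time))
        for n, nu, r2 in zip(schedule.n_cycles, nus, model):
            n_rep = 2 if n in schedule.repeats else 1
            for rep in range(n_rep):
                rows.append({
                    "sample_id": sample_id,
                    "saturation": float(sat),
                    "nu_cpmg_hz": float(nu),
                    "n_cycles": int(n),
                    "r2_eff": r2 + rng.normal(0.0, noise_sigma),
                    "sigma": max(noise_sigma, 0.05),
                    "replicate_id": rep,
                })
    return LigandRDSeries(table=pd.DataFrame(rows), proton=proton, field=f,
                          relax_time=schedule.relax_time, koff_truth=koff)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_intensity_table(table: pd.DataFrame, path, truth: TwoSiteTruth | None = None) -> None:
    """Write a tidy intensity CSV plus a JSON sidecar with ground truth."""
    import json
    from pathlib import Path

    path = Path(path)
    out = table.copy()
    out["is_reference"] = False
    out.to_csv(path, index=False)
    if truth is not None:
        sidecar = {
            "schema_version": C.SCHEMA_VERSION,
            "kex": truth.kex,
            "p_b": truth.p_b,
            "nucleus": truth.nucleus,
            "seed": truth.seed,
            "delta_ppm": {str(k): v for k, v in truth.delta_ppm.items()},
            "r2_0": {f"{r}@{f}": v for (r, f), v in truth.r2_0.items()},
        }
        path.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=1))
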