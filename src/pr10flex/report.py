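"""Per-protein flexibility summaries from dispersion amplitudes.

Aggregates per-residue Delta R2,eff values into threshold-bin percentages,
residue-by-protein heat-map matrices, and binding-site enrichment tables.
Percentages use residues with measurable dispersion data as the
denominator; positions without data keep an explicit missing reason
(gap / overlap / proline / unassigned) and are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dispersion import FLEX_BINS, classify_flexibility

__all__ = [
    "FlexibilityProfile",
    "ProteinSummary",
    "summarize_protein",
    "heatmap_matrix",
    "site_enrichment",
]

MISSING_REASONS = ("gap", "overlap", "proline", "unassigned")


@dataclass
class FlexibilityProfile:
    """Per-residue dispersion amplitudes for one protein at one field."""

    protein: str
    amplitudes: dict[int, float]  # residue -> Delta R2,eff (s^-1)
    missing: dict[int, str] = field(default_factory=dict)  # residue -> reason
    field_mhz: float = 700.0

    def __post_init__(self) -> None:
        bad = set(self.amplitudes) & set(self.missing)
        if bad:
            raise ValueError(f"residues both evaluable and missing: {sorted(bad)}")
        nonfinite = [r for r, a in self.amplitudes.items()
                     if a is None or not np.isfinite(a)]
        if nonfinite:
            raise ValueError(
                f"non-finite amplitudes for residues {sorted(nonfinite)}; "
                "list them under `missing` with a reason instead")
        unknown = set(self.missing.values()) - set(MISSING_REASONS)
        if unknown:
            raise ValueError(f"unknown missing reasons: {sorted(unknown)}")

    def bins(self) -> dict[int, str]:
        return {r: classify_flexibility(a) for r, a in self.amplitudes.items()}


@dataclass
class ProteinSummary:
    protein: str
    n_evaluable: int
    n_missing: int
    percent_nonflat: float  # Delta R2,eff > 1 s^-1
    percent_by_bin: dict[str, float]
    missing_reasons: dict[str, int]

    def to_row(self) -> dict:
        row = {
            "protein": self.protein,
            "n_evaluable": self.n_evaluable,
            "n_missing": self.n_missing,
            "percent_nonflat": self.percent_nonflat,
        }
        row.update({f"percent_{b}": v for b, v in self.percent_by_bin.items()})
        return row


def summarize_protein(profile: FlexibilityProfile,
                      nonflat_threshold: float = 1.0) -> ProteinSummary:
    """Bin percentages over evaluable residues, to one decimal.

    The nonflat percentage counts residues with amplitude above
    ``nonflat_threshold`` (s^-1); bin percentages sum to 100% of the
    evaluable residues.
    """
    amps = np.array(list(profile.amplitudes.values()), dtype=float)
    if len(amps) == 0:
        raise ValueError("profile has no evaluable residues")
    n = len(amps)
    bins = list(profile.bins().values())
    percent_by_bin = {b: round(100.0 * bins.count(b) / n, 1) for b in FLEX_BINS}
    reasons = {r: list(profile.missing.values()).count(r) for r in MISSING_REASONS
               if r in profile.missing.values()}
    return ProteinSummary(
        protein=profile.protein,
        n_evaluable=n,
        n_missing=len(profile.missing),
        percent_nonflat=round(100.0 * float(np.mean(amps > nonflat_threshold)), 1),
        percent_by_bin=percent_by_bin,
        missing_reasons=reasons,
    )


def heatmap_matrix(profiles, residue_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Protein x position amplitude matrix with explicit missing markers.

    ``residue_map`` optionally aligns each protein's native numbering to a
    common position scheme (columns: protein, residue, position); identity
    mapping by default.  Cells are the amplitude, or the missing reason
    for positions without data; positions absent from a protein's profile
    entirely are marked ``gap``.  Duplicate mapped positions are an error.
    """
    mapped = {}
    for prof in profiles:
        if residue_map is not None:
            sub = residue_map[residue_map.protein == prof.protein]
            m = dict(zip(sub.residue, sub.position))
        else:
            m = None
        cells = {}
        for r, a in prof.amplitudes.items():
            pos = m.get(r, None) if m is not None else r
            if pos is None:
                continue
            if pos in cells:
                raise ValueError(f"{prof.protein}: duplicate mapped position {pos}")
            cells[pos] = a
        for r, reason in prof.missing.items():
            pos = m.get(r, None) if m is not None else r
            if pos is None:
                continue
            if pos in cells:
                raise ValueError(f"{prof.protein}: duplicate mapped position {pos}")
            cells[pos] = reason
        mapped[prof.protein] = cells
    max_pos = max((max(c) for c in mapped.values() if c), default=0)
    positions = range(1, max_pos + 1)
    rows = {}
    for protein, cells in mapped.items():
        rows[protein] = [cells.get(p, "gap") for p in positions]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[str(p) for p in positions])


def heatmap_to_csv(matrix: pd.DataFrame, path) -> None:
    """Write a heat-map matrix so numeric cells round-trip bit-exactly.

    Floats are serialized with ``repr`` (shortest exact representation);
    missing-reason strings pass through unchanged.
    """
    from pathlib import Path

    def fmt(x):
        return repr(float(x)) if isinstance(x, (int, float, np.floating)) else str(x)

    lines = ["position," + ",".join(matrix.columns)]
    for protein, row in matrix.iterrows():
        lines.append(str(protein) + "," + ",".join(fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def heatmap_from_csv(path) -> pd.DataFrame:
    """Inverse of :func:`heatmap_to_csv`."""
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    columns = lines[0].split(",")[1:]
    index, rows = [], []
    for line in lines[1:]:
        parts = line.split(",")
        index.append(parts[0])
        row = []
        for v in parts[1:]:
            try:
                row.append(float(v))
            except ValueError:
                row.append(v)
        rows.append(row)
    return pd.DataFrame(rows, index=index, columns=columns)


def site_enrichment(profile: FlexibilityProfile, site_residues,
                    thresholds=(5.0, 10.0)) -> pd.DataFrame:
    """Flexibility enrichment of a residue set versus the remainder.

    For each amplitude threshold, the percentage of site residues whose
    Delta R2,eff exceeds it is compared with the percentage among all
    other evaluable residues.  Site residues without data are reported but
    excluded from the percentages.
    """
    site = set(int(r) for r in site_residues)
    if not site:
        raise ValueError("site residue list is empty")
    amps = profile.amplitudes
    site_eval = {r: a for r, a in amps.items() if r in site}
    other_eval = {r: a for r, a in amps.items() if r not in site}
    missing_site = sorted(site - set(amps))
    rows = []
    for t in thresholds:
        site_vals = np.array(list(site_eval.values()))
        other_vals = np.array(list(other_eval.values()))
        rows.append({
            "threshold": t,
            "site_percent": round(100.0 * float(np.mean(site_vals > t)), 1)
            if len(site_vals) else np.nan,
            "other_percent": round(100.0 * float(np.mean(other_vals > t)), 1)
            if len(other_vals) else np.nan,
            "site_n": len(site_vals),
            "other_n": len(other_vals),
            "site_exceeding": int(np.sum(site_vals > t)) if len(site_vals) else 0,
            "other_exceeding": int(np.sum(other_vals > t)) if len(other_vals) else 0,
            "site_missing": len(missing_site),
        })
    return pd.DataFrame(rows)
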