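"""Per-mRNA physiological initiation rate inference from ribosome densities.

The physiological initiation rate alpha_ph of a transcript is the value whose
simulated steady-state density matches the experimentally observed ribosome
density: rho_model(alpha_ph) = rho_exp.  The inversion runs on the smoothed,
piecewise-linearly interpolated density response curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import classify_curves, curve_features
from .response import ResponseCurve, gearing_factor, saturation_values

__all__ = [
    "DensityRecord",
    "InitiationEstimate",
    "infer_alpha",
    "infer_genomewide",
    "load_density_table",
    "compare_conditions",
    "per_mrna_to_per_codon",
]

OK = "OK"
SATURATED = "SATURATED"
BELOW_GRID = "BELOW_GRID"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class DensityRecord:
    """Experimental ribosome density for one gene (ribosomes per codon)."""

    gene_id: str
    rho_exp: float
    polysome_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.rho_exp > 0:
            raise ValueError(f"{self.gene_id}: rho_exp must be positive")
        if self.polysome_fraction is not None and not (
            0.0 <= self.polysome_fraction <= 1.0
        ):
            raise ValueError(f"{self.gene_id}: polysome fraction outside [0,1]")


@dataclass(frozen=True)
class InitiationEstimate:
    gene_id: str
    alpha_ph: float
    status: str  # OK | SATURATED | BELOW_GRID
    bracket: tuple[float, float]
    ambiguous: bool = False


def per_mrna_to_per_codon(ribosomes_per_mrna: float, length_codons: int) -> float:
    """Convert a ribosomes-per-mRNA measurement to the model's per-codon density."""
    if length_codons < 1:
        raise ValueError("length must be >= 1 codon")
    return ribosomes_per_mrna / length_codons


def load_density_table(path: str | Path) -> list[DensityRecord]:
    """Read a density TSV: gene_id, rho_exp and optionally a polysome fraction F."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "rho_exp"} <= set(df.columns):
        raise ValueError("density table needs gene_id and rho_exp columns")
    has_f = "F" in df.columns
    return [
        DensityRecord(
            gene_id=str(r.gene_id),
            rho_exp=float(r.rho_exp),
            polysome_fraction=float(r.F) if has_f and not pd.isna(r.F) else None,
        )
        for r in df.itertuples()
    ]


def infer_alpha(curve: ResponseCurve, record: DensityRecord) -> InitiationEstimate:
    """Invert the smoothed density curve at rho_exp.

    Out-of-range densities are flagged rather than extrapolated: above every
    smoothed value -> SATURATED at the grid maximum (the density data cannot
    constrain alpha there); below the smallest -> BELOW_GRID at the grid
    minimum.  If Monte-Carlo noise leaves several crossings after smoothing,
    the smallest root is returned and the gene flagged ambiguous.
    """
    if curve.gene_id and record.gene_id and curve.gene_id != record.gene_id:
        raise ValueError(
            f"gene id mismatch: curve {curve.gene_id} vs record {record.gene_id}"
        )
    grid = curve.alpha_grid
    rho = curve.rho_smooth
    target = record.rho_exp

    if target > rho.max():
        return InitiationEstimate(
            record.gene_id, float(grid[-1]), SATURATED, (float(grid[-1]),) * 2
        )
    if target < rho.min():
        return InitiationEstimate(
            record.gene_id, float(grid[0]), BELOW_GRID, (float(grid[0]),) * 2
        )

    roots: list[tuple[float, float, float]] = []
    for i in range(grid.size - 1):
        lo, hi = rho[i], rho[i + 1]
        if (lo <= target <= hi) or (hi <= target <= lo):
            if hi == lo:
                a = grid[i]
            else:
                a = grid[i] + (target - lo) / (hi - lo) * (grid[i + 1] - grid[i])
            if not roots or a > roots[-1][0] + 0:
                roots.append((a, grid[i], grid[i + 1]))
    if not roots:  # numerically possible only at exact endpoints
        idx = int(np.argmin(np.abs(rho - target)))
        roots = [(grid[idx], grid[max(idx - 1, 0)], grid[min(idx + 1, grid.size - 1)])]

    # distinct crossing segments (ignore contiguous segments sharing a knot)
    distinct = [roots[0]]
    for r in roots[1:]:
        if r[1] > distinct[-1][2]:
            distinct.append(r)
    a, blo, bhi = distinct[0]
    return InitiationEstimate(
        record.gene_id,
        float(a),
        OK,
        (float(blo), float(bhi)),
        ambiguous=len(distinct) > 1,
    )


def infer_genomewide(
    curves: Iterable[ResponseCurve],
    records: Iterable[DensityRecord],
    classify_seed: int = 0,
    hybrid_band: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One TranscriptSummary row per gene joined on gene id.

    Returns (summary frame, unmatched report).  The summary combines the
    inverted initiation rate, the translation efficiency Te = J(alpha_ph),
    the gearing K, the saturation values and the smooth/abrupt/hybrid class
    label.  Genes present on one side only are reported, never dropped
    silently.
    """
    curve_map = {c.gene_id: c for c in curves}
    record_map = {r.gene_id: r for r in records}
    joined = sorted(set(curve_map) & set(record_map))
    unmatched = {
        "curves_without_density": sorted(set(curve_map) - set(record_map)),
        "density_without_curve": sorted(set(record_map) - set(curve_map)),
    }
    if not joined:
        raise ValueError("no gene ids shared between curves and density records")

    feats = []
    rows = []
    for gid in joined:
        curve = curve_map[gid]
        sat = saturation_values(curve)
        est = infer_alpha(curve, record_map[gid])
        K = gearing_factor(curve, est.alpha_ph)
        Te = curve.interp_J(est.alpha_ph)
        feats.append(curve_features(curve, sat))
        rows.append(
            {
                "gene_id": gid,
                "alpha_ph": est.alpha_ph,
                "status": est.status,
                "qc": AMBIGUOUS if est.ambiguous else "",
                "Te": Te,
                "K": K,
                "J_max": sat.J_max,
                "rho_max": sat.rho_max,
            }
        )
    labels = classify_curves(feats, seed=classify_seed, hybrid_band=hybrid_band)
    df = pd.DataFrame(rows)
    df["class_label"] = [labels[gid] for gid in df["gene_id"]]
    return df, unmatched


def compare_conditions(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene change in the inferred initiation rate between two conditions.

    Mirrors re-running the inference on a second (e.g. perturbed-condition)
    density table: genes whose observed density is unchanged give
    delta_alpha_ph ~ 0.
    """
    merged = summary_a.merge(
        summary_b, on="gene_id", suffixes=("_a", "_b"), how="inner"
    )
    merged["delta_alpha_ph"] = merged["alpha_ph_b"] - merged["alpha_ph_a"]
    return merged[["gene_id", "alpha_ph_a", "alpha_ph_b", "delta_alpha_ph"]]
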