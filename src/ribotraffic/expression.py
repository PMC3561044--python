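"""Translation efficiency, protein-abundance prediction, and the CAI comparator.

Te is the protein production rate J evaluated at the physiological initiation
rate; Te * m (mRNA copies per cell), optionally scaled by the polysome-loaded
fraction F, estimates steady-state protein abundance.  CAI (Sharp & Li style)
is the geometric mean of relative synonymous codon weights from a highly
expressed reference set, provided as the usage-only comparator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_rates import GENETIC_CODE, SENSE_CODONS
from .response import ResponseCurve

__all__ = [
    "CaiWeights",
    "translation_efficiency",
    "predict_abundance",
    "cai_weights",
    "cai",
]

# single-codon amino acids and stops excluded from CAI by the standard definition
_EXCLUDED_CODONS = frozenset({"AUG", "UGG"})

_SYNONYM_FAMILIES: dict[str, list[str]] = {}
for _c, _aa in GENETIC_CODE.items():
    _SYNONYM_FAMILIES.setdefault(_aa, []).append(_c)


@dataclass
class CaiWeights:
    """Relative adaptiveness w_c in (0,1]; the best synonym of each amino acid has w=1."""

    w: dict[str, float]
    reference_set_id: str = ""

    def __post_init__(self) -> None:
        for aa, fam in _SYNONYM_FAMILIES.items():
            best = max(self.w.get(c, 0.0) for c in fam)
            if abs(best - 1.0) > 1e-9:
                raise ValueError(f"no synonym of {aa} has weight 1")
        for c, v in self.w.items():
            if not 0 < v <= 1:
                raise ValueError(f"weight for {c} outside (0,1]")


def translation_efficiency(curve: ResponseCurve, alpha_ph: float) -> float:
    """Te = smoothed current interpolated at the physiological initiation rate."""
    return curve.interp_J(alpha_ph)


def predict_abundance(
    records: pd.DataFrame, use_polysome_fraction: bool = False
) -> pd.DataFrame:
    """P_est = Te * m, or Te * m * F when the polysome-loaded fraction is used.

    ``records`` needs columns gene_id, Te, m (mRNA copies per cell) and, when
    requested, F in [0,1].  The returned frame adds P_est and a rank column
    for external correlation analyses.
    """
    required = {"gene_id", "Te", "m"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if (records["m"] < 0).any():
        raise ValueError("mRNA abundances must be non-negative")
    out = records.copy()
    if use_polysome_fraction:
        if "F" not in out.columns or out["F"].isna().any():
            raise ValueError("polysome fraction F requested but absent")
        if ((out["F"] < 0) | (out["F"] > 1)).any():
            raise ValueError("polysome fraction outside [0,1]")
        out["P_est"] = out["Te"] * out["m"] * out["F"]
    else:
        out["P_est"] = out["Te"] * out["m"]
    out["rank"] = out["P_est"].rank(ascending=False, method="min").astype(int)
    return out


def cai_weights(
    reference_orfs: list[list[str]],
    pseudo_count: float = 0.5,
    reference_set_id: str = "",
) -> CaiWeights:
    """Relative adaptiveness from codon counts in a highly expressed reference set.

    w_c = f_c / max over synonyms of f; codons unseen in the reference receive
    a pseudo-count floor (0.5 counts) before normalization so no weight is
    exactly zero; observed counts are used as-is.
    """
    if not reference_orfs:
        raise ValueError("empty reference set")
    counts: Counter[str] = Counter()
    for orf in reference_orfs:
        counts.update(c for c in orf if c in GENETIC_CODE)
    w: dict[str, float] = {}
    for fam in _SYNONYM_FAMILIES.values():
        fam_counts = {
            c: counts[c] if counts.get(c, 0) > 0 else pseudo_count for c in fam
        }
        best = max(fam_counts.values())
        for c in fam:
            w[c] = fam_counts[c] / best
    return CaiWeights(w=w, reference_set_id=reference_set_id)


def cai(codons: list[str], weights: CaiWeights) -> float:
    """Geometric mean of weights over positions, excluding AUG, UGG and stops."""
    included = [c for c in codons if c in GENETIC_CODE and c not in _EXCLUDED_CODONS]
    if not included:
        raise ValueError("no includable codons for CAI")
    logs = np.log([weights.w[c] for c in included])
    return float(np.exp(logs.mean()))
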