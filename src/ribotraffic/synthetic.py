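"""Synthetic fixtures: designed ORFs, rate tables, tRNA tables and density data.

Everything here is SYNTHETIC test scaffolding — designed sequences with known
ground truth, not organism data.  The constructions mirror the biological
scenarios of interest: a homogeneous fast background with an optional cluster
of slow (rare) codons placed either at the 5' edge or in the body of the ORF,
and forward-simulated ribosome densities with known initiation rates so the
inversion can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_rates import SENSE_CODONS, RateProfile, RateTable, TrnaCopyTable, TrnaEntry
from .codon_rates import GENETIC_CODE, reverse_complement
from .response import derive_seeds
from .traffic import SimConfig, simulate_steady_state

__all__ = [
    "SyntheticOrfSpec",
    "synthetic_rate_table",
    "synthetic_trna_table",
    "make_synthetic_orf",
    "make_synthetic_density",
]

#: fast background codons (distinct amino acids) used by the ORF generator
FAST_CODONS = ("GCU", "GAA", "AAA", "CCA", "GGU", "UCU")
#: the designated slow codon — synonymous with GCU (both alanine), so
#: synonymous shuffling can relocate a bottleneck
SLOW_CODON = "GCC"


@dataclass(frozen=True)
class SyntheticOrfSpec:
    """A designed ORF: fast background with an optional slow-codon cluster."""

    length: int  # L, in codons (stop codon not counted)
    k_fast: float = 20.0
    bottleneck: tuple[int, int, float] | None = None  # (position, width, k_slow), 1-based
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.bottleneck is not None:
            pos, width, k_slow = self.bottleneck
            if not (2 <= pos and pos + width - 1 <= self.length):
                raise ValueError("bottleneck must fit within [2, L]")
            if not k_slow < self.k_fast:
                raise ValueError("k_slow must be below k_fast")


def synthetic_rate_table(
    k_fast: float = 20.0, k_slow: float = 1.0, slow_codons: tuple[str, ...] = (SLOW_CODON,)
) -> RateTable:
    """Designed rate table: every sense codon at k_fast except the slow set."""
    rates = {c: k_fast for c in SENSE_CODONS}
    for c in slow_codons:
        rates[c] = k_slow
    return RateTable(rates=rates, scaling_constant=1.0)


def synthetic_trna_table(seed: int = 0, copy_range: tuple[int, int] = (1, 16)) -> TrnaCopyTable:
    """SYNTHETIC tRNA table: one Watson-Crick anticodon per sense codon.

    Copy numbers are drawn uniformly from ``copy_range`` (deterministic given
    ``seed``).  Guarantees every sense codon is decodable regardless of the
    wobble rule set.  Not organism data.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for codon in SENSE_CODONS:
        entries.append(
            TrnaEntry(
                anticodon=reverse_complement(codon),
                amino_acid=GENETIC_CODE[codon],
                copy_number=int(rng.integers(copy_range[0], copy_range[1] + 1)),
            )
        )
    return TrnaCopyTable(entries=entries)


def write_trna_table(table: TrnaCopyTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"anticodon": e.anticodon, "amino_acid": e.amino_acid, "copy_number": e.copy_number}
            for e in table.entries
        ]
    ).to_csv(path, sep="\t", index=False)


def make_synthetic_orf(
    spec: SyntheticOrfSpec, table: RateTable | None = None, gene_id: str = "synth"
) -> tuple[list[str], RateProfile]:
    """Codon sequence whose rate profile is k_fast except over the bottleneck.

    The background is drawn from ``FAST_CODONS`` (all at k_fast in the
    synthetic rate table); bottleneck positions carry the slow alanine codon.
    Deterministic given ``spec.seed``.
    """
    k_slow = spec.bottleneck[2] if spec.bottleneck else 1.0
    if table is None:
        table = synthetic_rate_table(k_fast=spec.k_fast, k_slow=k_slow)
    rng = np.random.default_rng(spec.seed)
    codons = ["AUG"] + [
        FAST_CODONS[i] for i in rng.integers(0, len(FAST_CODONS), spec.length - 1)
    ]
    if spec.bottleneck is not None:
        pos, width, _ = spec.bottleneck
        for i in range(pos - 1, pos - 1 + width):
            codons[i] = SLOW_CODON
    k = np.array([table[c] for c in codons])
    profile = RateProfile(gene_id=gene_id, codons=codons, k=k)
    return codons, profile


def make_synthetic_density(
    profiles: list[RateProfile],
    alpha_true: dict[str, float],
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulated density table plus the ground-truth initiation rates.

    Returns (density frame: gene_id, rho_exp, usable; truth frame: gene_id,
    alpha_true).  Genes simulated at alpha = 0 produce rho = 0 and are flagged
    unusable for inversion.
    """
    seeds = derive_seeds(config.seed, len(profiles), salt="density")
    dens_rows, truth_rows = [], []
    for profile, seed in zip(profiles, seeds):
        a = alpha_true[profile.gene_id]
        if a < 0:
            raise ValueError(f"{profile.gene_id}: alpha_true must be >= 0")
        est = simulate_steady_state(profile, a, config.with_seed(seed))
        dens_rows.append(
            {
                "gene_id": profile.gene_id,
                "rho_exp": est.rho,
                "usable": est.rho > 0,
            }
        )
        truth_rows.append({"gene_id": profile.gene_id, "alpha_true": a})
    return pd.DataFrame(dens_rows), pd.DataFrame(truth_rows)


def write_density_table(density: pd.DataFrame, path: str | Path) -> None:
    density[density["usable"]][["gene_id", "rho_exp"]].to_csv(
        path, sep="\t", index=False
    )
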