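"""Synonymous codon-arrangement randomization at fixed composition.

Shuffling permutes, independently for each amino acid, the multiset of its
codons across that amino acid's positions.  The amino-acid sequence and the
overall codon composition (hence any composition index: CAI, mean k) are
exactly conserved; only the arrangement — and therefore the ribosome traffic
— changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_rates import GENETIC_CODE, RateProfile, RateTable
from .response import derive_seeds
from .traffic import SimConfig, simulate_steady_state

__all__ = ["ShuffleEnsemble", "shuffle_synonymous", "shuffle_ensemble_currents"]


def shuffle_synonymous(codons: list[str], seed: int | np.random.Generator) -> list[str]:
    """Permute each amino acid's codon multiset over its own positions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_aa: dict[str, list[int]] = {}
    for i, c in enumerate(codons):
        by_aa.setdefault(GENETIC_CODE[c], []).append(i)
    out = list(codons)
    for positions in by_aa.values():
        if len(positions) < 2:
            continue
        perm = rng.permutation(len(positions))
        fam = [codons[p] for p in positions]
        for p, j in zip(positions, perm):
            out[p] = fam[j]
    return out


@dataclass
class ShuffleEnsemble:
    """Simulated currents of synonymous-arrangement variants at one fixed alpha."""

    gene_id: str
    alpha: float
    currents: np.ndarray
    current_stderrs: np.ndarray
    seed: int
    variants: list[list[str]]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": np.arange(self.n_variants),
                "J": self.currents,
                "J_stderr": self.current_stderrs,
            }
        )

    def histogram(self, bins: int = 20) -> pd.DataFrame:
        counts, edges = np.histogram(self.currents, bins=bins, density=True)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "density": counts}
        )


def shuffle_ensemble_currents(
    codons: list[str],
    table: RateTable,
    n: int,
    alpha: float,
    config: SimConfig,
    gene_id: str = "",
    include_original: bool = False,
) -> ShuffleEnsemble:
    """Simulate ``n`` independent synonymous shuffles at fixed ``alpha``.

    Each variant keeps the amino-acid sequence and codon multiset of the
    input; the resulting spread of currents isolates the effect of codon
    arrangement from codon usage.
    """
    if n < 1:
        raise ValueError("need at least one variant")
    rng = np.random.default_rng(int(config.seed) % 2**31)
    sim_seeds = derive_seeds(config.seed, n, salt=f"shuffle:{gene_id}")
    variants: list[list[str]] = []
    J = np.empty(n)
    Je = np.empty(n)
    for i in range(n):
        var = list(codons) if (include_original and i == 0) else shuffle_synonymous(codons, rng)
        k = np.array([table[c] for c in var])
        profile = RateProfile(gene_id=f"{gene_id}|v{i}", codons=var, k=k)
        est = simulate_steady_state(profile, alpha, config.with_seed(sim_seeds[i]))
        variants.append(var)
        J[i], Je[i] = est.J, est.J_stderr
    return ShuffleEnsemble(
        gene_id=gene_id,
        alpha=alpha,
        currents=J,
        current_stderrs=Je,
        seed=config.seed,
        variants=variants,
    )
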