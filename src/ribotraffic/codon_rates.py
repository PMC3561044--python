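"""Codon-specific tRNA-capture rates from tRNA gene-copy numbers.

tRNA abundances are taken to be proportional to gene copy numbers; a codon's
capture rate k_c is the scaled sum over all anticodons that can decode it,
weighted by a wobble-pairing efficiency factor.  Watson-Crick third-position
pairs count at full weight; non-canonical (wobble) pairs at a configurable
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_rna_table

RNA_BASES = frozenset("ACGU")

#: codon -> one-letter amino acid, sense codons only (RNA alphabet)
GENETIC_CODE: dict[str, str] = dict(standard_rna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_rna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(triplet: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(triplet))


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_BASES
    if bad:
        raise ValueError(f"invalid nucleotide(s): {sorted(bad)}")
    return s


@dataclass(frozen=True)
class TrnaEntry:
    anticodon: str  # RNA triplet, 5'->3'
    amino_acid: str  # 1-letter code
    copy_number: int


@dataclass
class TrnaCopyTable:
    """Anticodon -> gene copy number mapping (proxy for tRNA abundance)."""

    entries: list[TrnaEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if len(e.anticodon) != 3 or set(e.anticodon) - RNA_BASES:
                raise ValueError(f"malformed anticodon {e.anticodon!r}")
            if e.anticodon in seen:
                raise ValueError(f"duplicate anticodon {e.anticodon}")
            if e.copy_number < 0:
                raise ValueError(
                    f"negative copy number for anticodon {e.anticodon}"
                )
            seen.add(e.anticodon)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class WobbleRules:
    """Third-position decoding rules.

    ``pairings`` maps (codon 3rd base, anticodon 1st base) to an efficiency
    factor in [0, 1].  Watson-Crick pairs always carry ``watson_crick_factor``
    (1.0).  Anticodons beginning with A may be treated as inosine-modified
    (``inosine_from_a``), in which case they read codon-third U, C and A.
    """

    pairings: dict[tuple[str, str], float] = field(default_factory=dict)
    watson_crick_factor: float = 1.0
    inosine_from_a: bool = True

    WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

    def __post_init__(self) -> None:
        if self.watson_crick_factor != 1.0:
            raise ValueError("Watson-Crick factor must be 1.0")
        for pair, f in self.pairings.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"pairing factor {f} for {pair} outside [0,1]")

    @classmethod
    def default(cls, wobble_penalty: float = 0.5) -> "WobbleRules":
        """Standard eukaryotic rules with a single wobble penalty.

        G at the anticodon wobble position reads U (in addition to the
        canonical C); U reads G (in addition to A); inosine (from A-starting
        anticodons) reads U at full efficiency and C/A at the penalty.
        """
        pairings = {
            ("U", "G"): wobble_penalty,  # codon ...U : anticodon G..
            ("G", "U"): wobble_penalty,  # codon ...G : anticodon U..
            ("C", "A"): wobble_penalty,  # inosine reading C
            ("A", "A"): wobble_penalty,  # inosine reading A
            ("U", "A"): 1.0,             # inosine reading U (WC partner of A)
        }
        return cls(pairings=pairings, inosine_from_a=True)

    def factor(self, codon_third: str, anticodon_first: str) -> float:
        """Efficiency of the (codon 3rd base, anticodon 1st base) pair; 0 = no pairing."""
        if (codon_third, anticodon_first) in self.WATSON_CRICK:
            return self.watson_crick_factor
        if anticodon_first == "A" and not self.inosine_from_a:
            return 0.0
        return self.pairings.get((codon_third, anticodon_first), 0.0)


@dataclass
class RateTable:
    """Per-codon tRNA-capture rates k_c (s^-1) for the 61 sense codons."""

    rates: dict[str, float]
    scaling_constant: float = 1.0

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.rates)
        if missing:
            raise ValueError(f"undecodable sense codon(s): {sorted(missing)}")
        stops = set(self.rates) & STOP_CODONS
        if stops:
            raise ValueError(f"stop codon(s) in rate table: {sorted(stops)}")
        for c, k in self.rates.items():
            if not k > 0:
                raise ValueError(f"non-positive rate for codon {c}")

    def __getitem__(self, codon: str) -> float:
        return self.rates[codon]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.rates.items()), columns=["codon", "k"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RateTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"codon", "k"} <= set(df.columns):
            raise ValueError("rate table TSV needs codon and k columns")
        rates = {normalize_rna(str(r.codon)): float(r.k) for r in df.itertuples()}
        return cls(rates=rates)


@dataclass
class RateProfile:
    """Per-position capture rates k_i (s^-1) along one ORF, stop stripped."""

    gene_id: str
    codons: list[str]
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if len(self.codons) < 1 or len(self.codons) != len(self.k):
            raise ValueError("profile length mismatch or empty profile")
        if not np.all(self.k > 0):
            raise ValueError("all capture rates must be positive")

    @property
    def L(self) -> int:
        return len(self.codons)


def load_trna_table(path: str | Path) -> TrnaCopyTable:
    """Read a 3-column TSV (anticodon, amino_acid, copy_number); T normalised to U."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"anticodon", "amino_acid", "copy_number"}
    if not required <= set(df.columns):
        raise ValueError(f"tRNA table must have columns {sorted(required)}")
    entries = [
        TrnaEntry(
            anticodon=normalize_rna(str(r.anticodon)),
            amino_acid=str(r.amino_acid),
            copy_number=int(r.copy_number),
        )
        for r in df.itertuples()
    ]
    for e in entries:
        if e.copy_number < 0:
            raise ValueError(f"negative copy number for {e.anticodon}")
    return TrnaCopyTable(entries=entries)


def decoding_anticodons(
    codon: str, anticodons: Iterable[str], wobble: WobbleRules
) -> list[tuple[str, float]]:
    """Anticodons able to read ``codon`` with their pairing factors.

    Positions 1 and 2 of the codon must pair Watson-Crick with anticodon
    positions 3 and 2; the third codon base pairs with the anticodon's first
    (wobble) base under ``wobble``.
    """
    out = []
    for ac in anticodons:
        if ac[2] != _COMPLEMENT[codon[0]] or ac[1] != _COMPLEMENT[codon[1]]:
            continue
        f = wobble.factor(codon[2], ac[0])
        if f > 0:
            out.append((ac, f))
    return out


def codon_capture_rates(
    trna: TrnaCopyTable,
    wobble: WobbleRules | None = None,
    scaling: float = 1.0,
) -> dict[str, float]:
    """Capture rates for whichever sense codons the table can decode.

    Unlike :func:`build_rate_table` this accepts incomplete (toy) tables and
    simply omits undecodable codons.
    """
    wobble = wobble if wobble is not None else WobbleRules.default()
    acs = {e.anticodon: e.copy_number for e in trna.entries}
    out: dict[str, float] = {}
    for codon in SENSE_CODONS:
        total = sum(
            acs[ac] * f for ac, f in decoding_anticodons(codon, acs, wobble)
        )
        if total > 0:
            out[codon] = scaling * total
    return out


def build_rate_table(
    trna: TrnaCopyTable,
    wobble: WobbleRules | None = None,
    scaling: float = 1.0,
) -> RateTable:
    """k_c = scaling * sum over decoding anticodons of copy_number * pairing factor.

    Raises if any sense codon is left undecodable under the rules.
    """
    rates = codon_capture_rates(trna, wobble, scaling)
    undecodable = sorted(set(SENSE_CODONS) - set(rates))
    if undecodable:
        raise ValueError(f"undecodable codon(s): {undecodable}")
    return RateTable(rates=rates, scaling_constant=scaling)


def calibrate_scaling(
    trna: TrnaCopyTable,
    wobble: WobbleRules | None = None,
    target_mean: float = 10.0,
    usage: Mapping[str, float] | None = None,
) -> float:
    """Scaling constant giving a usage-weighted mean capture rate of ``target_mean`` s^-1.

    With no usage table, all 61 sense codons are weighted equally.
    """
    raw = build_rate_table(trna, wobble, scaling=1.0)
    if usage is None:
        weights = {c: 1.0 for c in SENSE_CODONS}
    else:
        weights = {c: float(usage.get(c, 0.0)) for c in SENSE_CODONS}
    wsum = sum(weights.values())
    mean_raw = sum(raw[c] * w for c, w in weights.items()) / wsum
    return target_mean / mean_raw


def split_codons(orf: str) -> list[str]:
    """Split an in-frame coding sequence into codons; validates frame/start/stops.

    A terminal stop codon is allowed and stripped; internal stops are errors.
    """
    s = normalize_rna(orf)
    if len(s) % 3 != 0:
        raise ValueError(f"sequence length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons[0] != "AUG":
        raise ValueError("ORF must start with AUG")
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    internal = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    if internal:
        raise ValueError(f"internal stop codon at codon position(s) {internal}")
    return codons


def rate_profile(orf: str | list[str], table: RateTable, gene_id: str = "") -> RateProfile:
    """Map an ORF to its per-position capture-rate vector (stop codon stripped)."""
    codons = split_codons(orf) if isinstance(orf, str) else list(orf)
    k = np.array([table[c] for c in codons], dtype=float)
    return RateProfile(gene_id=gene_id, codons=codons, k=k)
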