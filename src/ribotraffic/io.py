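"""File IO: ORF FASTA reading, run configuration and output manifests.

Codon positions are 1-based and inclusive throughout; all internal sequences
use the RNA alphabet (T normalised to U on read).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .codon_rates import split_codons
from .traffic import SimConfig

__all__ = ["read_orf_fasta", "RunConfig", "write_manifest"]


def read_orf_fasta(path: str | Path) -> dict[str, list[str]]:
    """Read in-frame coding-strand ORFs into a gene_id -> codon-list mapping.

    Validation per record: length divisible by 3, AUG start, no internal stop
    (a terminal stop is stripped).  Mixed case and DNA alphabet are accepted
    and normalised.
    """
    out: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate record id {rec.id}")
        try:
            out[rec.id] = split_codons(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"record {rec.id}: {exc}") from exc
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_orf_fasta(orfs: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, codons in orfs.items():
            fh.write(f">{gid}\n{''.join(codons)}\n")


@dataclass
class RunConfig:
    """YAML-backed run configuration shared by all CLI subcommands."""

    orf_fasta: str | None = None
    trna_table: str | None = None
    density_table: str | None = None
    abundance_table: str | None = None
    output_dir: str = "ribotraffic_out"
    sim: SimConfig = field(default_factory=SimConfig)
    alpha_grid: dict = field(
        default_factory=lambda: {"n_log": 60, "n_linear": 20, "alpha_min": 1e-3, "alpha_max": 5.0}
    )
    classification: dict = field(default_factory=lambda: {"hybrid_band": 0.2})
    master_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate_paths(self, required: tuple[str, ...]) -> None:
        for name in required:
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"config is missing required path '{name}'")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Record the full configuration, package version and master seed alongside outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "ribotraffic",
        "version": __version__,
        "master_seed": config.master_seed,
        "config": asdict(config),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
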