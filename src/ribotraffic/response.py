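"""Response curves J(alpha), rho(alpha): sweeps, smoothing, saturation, gearing."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_rates import RateProfile
from .traffic import SimConfig, simulate_steady_state

__all__ = [
    "ResponseCurve",
    "SaturationSummary",
    "default_alpha_grid",
    "sweep_alpha",
    "smooth_curve",
    "saturation_values",
    "gearing_factor",
]

SMOOTH_WINDOW = 10  # running-average window for J(alpha), rho(alpha)


def default_alpha_grid(
    n_log: int = 60,
    n_linear: int = 20,
    alpha_min: float = 1e-3,
    alpha_max: float = 5.0,
    dense_range: tuple[float, float] = (0.01, 1.0),
) -> np.ndarray:
    """Log-spaced grid over [alpha_min, alpha_max] densified where physiological
    initiation rates concentrate."""
    grid = np.geomspace(alpha_min, alpha_max, n_log)
    dense = np.linspace(*dense_range, n_linear)
    return np.unique(np.concatenate([grid, dense]))


def smooth_curve(series: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered running average, length-preserving.

    For an even window w the stencil is [i - (w/2 - 1), i + w/2]; near the
    boundaries the window shrinks symmetrically to radius min(i, n-1-i), so
    endpoints are left untouched and a series shorter than the window gets the
    overall mean at its fully truncated centre.
    """
    s = np.asarray(series, dtype=float)
    n = s.size
    if n < 1:
        raise ValueError("series must be non-empty")
    left = (window - 1) // 2
    right = window // 2
    out = np.empty(n)
    for i in range(n):
        if i - left < 0 or i + right >= n:
            r = min(i, n - 1 - i)
            out[i] = s[i - r : i + r + 1].mean()
        else:
            out[i] = s[i - left : i + right + 1].mean()
    return out


@dataclass
class ResponseCurve:
    """Steady-state current and density of one transcript over an alpha grid."""

    gene_id: str
    alpha_grid: np.ndarray
    J_raw: np.ndarray
    rho_raw: np.ndarray
    J_stderr: np.ndarray
    rho_stderr: np.ndarray
    J_smooth: np.ndarray = field(default=None)  # type: ignore[assignment]
    rho_smooth: np.ndarray = field(default=None)  # type: ignore[assignment]
    smooth_window: int = SMOOTH_WINDOW

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        if self.alpha_grid.size == 0:
            raise ValueError("empty alpha grid")
        if not np.all(np.diff(self.alpha_grid) > 0):
            raise ValueError("alpha grid must be strictly increasing")
        for name in ("J_raw", "rho_raw", "J_stderr", "rho_stderr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.alpha_grid.shape:
                raise ValueError(f"{name} does not match the grid")
            setattr(self, name, arr)
        if self.J_smooth is None:
            self.J_smooth = smooth_curve(self.J_raw, self.smooth_window)
        if self.rho_smooth is None:
            self.rho_smooth = smooth_curve(self.rho_raw, self.smooth_window)

    def interp_J(self, alpha: float) -> float:
        self._check_range(alpha)
        return float(np.interp(alpha, self.alpha_grid, self.J_smooth))

    def interp_rho(self, alpha: float) -> float:
        self._check_range(alpha)
        return float(np.interp(alpha, self.alpha_grid, self.rho_smooth))

    def _check_range(self, alpha: float) -> None:
        if not self.alpha_grid[0] <= alpha <= self.alpha_grid[-1]:
            raise ValueError(
                f"alpha {alpha} outside grid range "
                f"[{self.alpha_grid[0]}, {self.alpha_grid[-1]}]"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha_grid,
                "J_raw": self.J_raw,
                "J_stderr": self.J_stderr,
                "rho_raw": self.rho_raw,
                "rho_stderr": self.rho_stderr,
                "J_smooth": self.J_smooth,
                "rho_smooth": self.rho_smooth,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# gene_id={self.gene_id}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResponseCurve":
        gene_id = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# gene_id="):
                gene_id = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(
            gene_id=gene_id,
            alpha_grid=df["alpha"].to_numpy(),
            J_raw=df["J_raw"].to_numpy(),
            rho_raw=df["rho_raw"].to_numpy(),
            J_stderr=df["J_stderr"].to_numpy(),
            rho_stderr=df["rho_stderr"].to_numpy(),
            J_smooth=df["J_smooth"].to_numpy(),
            rho_smooth=df["rho_smooth"].to_numpy(),
        )


@dataclass(frozen=True)
class SaturationSummary:
    """Elongation-limited saturation values (mean of the last five grid points)."""

    J_max: float
    rho_max: float


def derive_seeds(master_seed: int, n: int, salt: str = "") -> np.ndarray:
    """Deterministic per-run child seeds (< 2^31) from a master seed and label."""
    entropy = [int(master_seed) % 2**31]
    if salt:
        entropy.append(zlib.crc32(salt.encode()) % 2**31)
    ss = np.random.SeedSequence(entropy)
    return ss.generate_state(n) % 2**31


def sweep_alpha(
    profile: RateProfile,
    grid: np.ndarray,
    config: SimConfig,
    one_state: bool = False,
) -> ResponseCurve:
    """One steady-state simulation per grid point, with per-point derived seeds."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty alpha grid")
    seeds = derive_seeds(config.seed, grid.size, salt=profile.gene_id)
    J = np.empty(grid.size)
    rho = np.empty(grid.size)
    Je = np.empty(grid.size)
    rhoe = np.empty(grid.size)
    for i, (a, seed) in enumerate(zip(grid, seeds)):
        est = simulate_steady_state(
            profile, a, config.with_seed(seed), one_state=one_state
        )
        J[i], rho[i] = est.J, est.rho
        Je[i], rhoe[i] = est.J_stderr, est.rho_stderr
    return ResponseCurve(
        gene_id=profile.gene_id,
        alpha_grid=grid,
        J_raw=J,
        rho_raw=rho,
        J_stderr=Je,
        rho_stderr=rhoe,
    )


def saturation_values(curve: ResponseCurve, n_last: int = 5) -> SaturationSummary:
    """Saturation current/density: mean of the last ``n_last`` raw grid points."""
    if curve.alpha_grid.size < n_last:
        raise ValueError(f"need at least {n_last} grid points")
    return SaturationSummary(
        J_max=float(curve.J_raw[-n_last:].mean()),
        rho_max=float(curve.rho_raw[-n_last:].mean()),
    )


def gearing_factor(curve: ResponseCurve, alpha_ph: float) -> float:
    """Gearing K = dJ/dalpha of the smoothed curve at the physiological rate.

    Central finite difference on the piecewise-linear interpolant; one-sided
    at the grid edges.  Dimensionless: extra proteins produced per extra
    initiating ribosome.
    """
    grid = curve.alpha_grid
    curve._check_range(alpha_ph)
    # half the local grid spacing keeps the stencil inside adjacent segments
    idx = np.searchsorted(grid, alpha_ph)
    idx = min(max(idx, 1), grid.size - 1)
    h = 0.5 * (grid[idx] - grid[idx - 1])
    lo = max(alpha_ph - h, grid[0])
    hi = min(alpha_ph + h, grid[-1])
    if hi <= lo:
        raise ValueError("degenerate grid spacing at alpha_ph")
    return float((curve.interp_J(hi) - curve.interp_J(lo)) / (hi - lo))
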