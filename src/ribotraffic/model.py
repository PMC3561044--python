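"""Model/Results interface for single-transcript ribosome traffic.

``TranscriptTrafficModel`` wraps one ORF's rate profile and kinetic constants;
``fit`` inverts the simulated density response against an observed ribosome
density and returns a ``TranscriptTrafficResults`` carrying the estimated
physiological initiation rate, its propagated uncertainty, the translation
efficiency, gearing, saturation values and diagnostics, with a ``summary()``
table in the style of statistical modelling packages.
"""

from __future__ import annotations

import numpy as np

from .classify import ABRUPT, HYBRID, SMOOTH, classify_curves, curve_features
from .codon_rates import RateProfile, RateTable, rate_profile
from .inference import DensityRecord, infer_alpha
from .response import (
    ResponseCurve,
    default_alpha_grid,
    gearing_factor,
    saturation_values,
    sweep_alpha,
)
from .traffic import SimConfig, SteadyStateEstimate, simulate_steady_state

__all__ = ["TranscriptTrafficModel", "TranscriptTrafficResults"]


class TranscriptTrafficModel:
    """Two-state ribosome traffic model for one transcript.

    Parameters
    ----------
    profile
        Per-codon tRNA-capture rates for the ORF (stop codon stripped).
    config
        Kinetic constants (translocation, termination, footprint) and the
        Gillespie sampling plan.
    alpha_grid
        Initiation-rate grid for the response sweep; defaults to a log-spaced
        grid over [1e-3, 5] s^-1 densified in the physiological range.
    """

    def __init__(
        self,
        profile: RateProfile,
        config: SimConfig | None = None,
        alpha_grid: np.ndarray | None = None,
    ) -> None:
        self.profile = profile
        self.config = config if config is not None else SimConfig()
        self.alpha_grid = (
            np.asarray(alpha_grid, float) if alpha_grid is not None else default_alpha_grid()
        )
        self._curve: ResponseCurve | None = None

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        rate_table: RateTable,
        gene_id: str = "",
        config: SimConfig | None = None,
        alpha_grid: np.ndarray | None = None,
    ) -> "TranscriptTrafficModel":
        return cls(rate_profile(sequence, rate_table, gene_id=gene_id), config, alpha_grid)

    def simulate(self, alpha: float, seed: int | None = None) -> SteadyStateEstimate:
        cfg = self.config if seed is None else self.config.with_seed(seed)
        return simulate_steady_state(self.profile, alpha, cfg)

    def sweep(self, seed: int | None = None, force: bool = False) -> ResponseCurve:
        """Response curve over the alpha grid (cached after the first call)."""
        if self._curve is None or force:
            cfg = self.config if seed is None else self.config.with_seed(seed)
            self._curve = sweep_alpha(self.profile, self.alpha_grid, cfg)
        return self._curve

    def fit(
        self, rho_exp: float, seed: int | None = None, polysome_fraction: float | None = None
    ) -> "TranscriptTrafficResults":
        """Estimate alpha_ph from an observed ribosome density (per codon)."""
        curve = self.sweep(seed=seed)
        record = DensityRecord(
            gene_id=self.profile.gene_id,
            rho_exp=rho_exp,
            polysome_fraction=polysome_fraction,
        )
        est = infer_alpha(curve, record)
        return TranscriptTrafficResults(self, curve, record, est)


class TranscriptTrafficResults:
    """Estimates and diagnostics from fitting one transcript's density."""

    def __init__(self, model, curve, record, estimate) -> None:
        self.model = model
        self.curve = curve
        self.record = record
        self.estimate = estimate

        self.alpha_ph = estimate.alpha_ph
        self.status = estimate.status
        sat = saturation_values(curve)
        self.J_max = sat.J_max
        self.rho_max = sat.rho_max
        self.K = gearing_factor(curve, self.alpha_ph)
        self.Te = curve.interp_J(self.alpha_ph)
        feats = curve_features(curve, sat)
        self.class_label = classify_curves([feats])[curve.gene_id or feats.gene_id]
        self.features = feats
        self.alpha_ph_stderr = self._propagate_alpha_stderr()

    def _propagate_alpha_stderr(self) -> float:
        """Local density stderr divided by the local slope d(rho)/d(alpha)."""
        grid = self.curve.alpha_grid
        i = int(np.clip(np.searchsorted(grid, self.alpha_ph), 1, grid.size - 1))
        slope = (self.curve.rho_smooth[i] - self.curve.rho_smooth[i - 1]) / (
            grid[i] - grid[i - 1]
        )
        local_err = 0.5 * (self.curve.rho_stderr[i] + self.curve.rho_stderr[i - 1])
        if slope <= 0:
            return float("inf")
        return float(local_err / slope)

    def predict(self, alpha: float) -> dict[str, float]:
        """Interpolated (J, rho) of the fitted response at an initiation rate."""
        return {"J": self.curve.interp_J(alpha), "rho": self.curve.interp_rho(alpha)}

    def predict_abundance(self, m: float, use_polysome_fraction: bool = False) -> float:
        f = 1.0
        if use_polysome_fraction:
            if self.record.polysome_fraction is None:
                raise ValueError("polysome fraction requested but absent")
            f = self.record.polysome_fraction
        return self.Te * m * f

    def summary(self) -> str:
        gid = self.curve.gene_id or "<unnamed>"
        lines = [
            "Transcript ribosome-traffic fit",
            "=" * 46,
            f"gene id            {gid}",
            f"L (codons)         {self.model.profile.L}",
            f"observed density   {self.record.rho_exp:.5g} ribosomes/codon",
            "-" * 46,
            f"alpha_ph           {self.alpha_ph:.5g} s^-1  (status {self.status})",
            f"alpha_ph stderr    {self.alpha_ph_stderr:.3g} s^-1",
            f"Te = J(alpha_ph)   {self.Te:.5g} s^-1",
            f"gearing K          {self.K:.4g}",
            f"J_max              {self.J_max:.5g} s^-1",
            f"rho_max            {self.rho_max:.5g} ribosomes/codon",
            f"response class     {self.class_label}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_response(self, ax=None):
        """J(alpha) and rho(alpha) with the fitted alpha_ph marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.curve.alpha_grid
        ax.plot(g, self.curve.J_smooth, label="J(alpha)")
        ax2 = ax.twinx()
        ax2.plot(g, self.curve.rho_smooth, color="C1", label="rho(alpha)")
        ax.axvline(self.alpha_ph, color="k", ls="--", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("initiation rate alpha (1/s)")
        ax.set_ylabel("current J (1/s)")
        ax2.set_ylabel("density rho (ribosomes/codon)")
        return ax
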