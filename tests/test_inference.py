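"""Inversion of density response curves to physiological initiation rates."""

import numpy as np
import pandas as pd
import pytest

from ribotraffic import (
    DensityRecord,
    SimConfig,
    SyntheticOrfSpec,
    compare_conditions,
    infer_alpha,
    infer_genomewide,
    load_density_table,
    make_synthetic_density,
    make_synthetic_orf,
    sweep_alpha,
)
from ribotraffic.inference import BELOW_GRID, OK, SATURATED, per_mrna_to_per_codon


@pytest.fixture
def hyperbolic_curve(analytic_curve):
    # rho(alpha) = alpha / (1 + alpha); includes alpha = 1 as a grid node
    grid = np.unique(np.concatenate([np.geomspace(0.01, 4, 60), [1.0]]))
    return analytic_curve(grid, lambda a: a, lambda a: a / (1 + a), gene_id="h")


class TestInferAlpha:
    def test_analytic_inverse(self, hyperbolic_curve):
        est = infer_alpha(hyperbolic_curve, DensityRecord("h", rho_exp=0.5))
        assert est.status == OK
        assert est.alpha_ph == pytest.approx(1.0, rel=1e-9)

    def test_saturated_when_density_above_curve(self, hyperbolic_curve):
        est = infer_alpha(hyperbolic_curve, DensityRecord("h", rho_exp=0.999))
        assert est.status == SATURATED
        assert est.alpha_ph == hyperbolic_curve.alpha_grid[-1]

    def test_below_grid_when_density_under_curve(self, hyperbolic_curve):
        est = infer_alpha(hyperbolic_curve, DensityRecord("h", rho_exp=1e-5))
        assert est.status == BELOW_GRID
        assert est.alpha_ph == hyperbolic_curve.alpha_grid[0]

    def test_gene_id_mismatch_rejected(self, hyperbolic_curve):
        with pytest.raises(ValueError):
            infer_alpha(hyperbolic_curve, DensityRecord("other", rho_exp=0.5))

    def test_monotone_in_density(self, hyperbolic_curve):
        targets = np.linspace(0.05, 0.7, 12)
        alphas = [
            infer_alpha(hyperbolic_curve, DensityRecord("h", rho_exp=t)).alpha_ph
            for t in targets
        ]
        assert np.all(np.diff(alphas) >= 0)

    def test_inversion_is_length_blind(self, analytic_curve):
        # two identical curves differing only in gene id give identical alpha
        grid = np.geomspace(0.01, 2, 40)
        c1 = analytic_curve(grid, lambda a: a, lambda a: a / (1 + a), gene_id="a")
        c2 = analytic_curve(grid, lambda a: a, lambda a: a / (1 + a), gene_id="b")
        e1 = infer_alpha(c1, DensityRecord("a", rho_exp=0.3))
        e2 = infer_alpha(c2, DensityRecord("b", rho_exp=0.3))
        assert e1.alpha_ph == e2.alpha_ph

    def test_non_monotone_curve_flags_ambiguous_smallest_root(self, analytic_curve):
        grid = np.linspace(0.1, 1.0, 10)
        c = analytic_curve(grid, lambda a: a, lambda a: a, gene_id="w")
        # dip below the target and rise again -> two distinct crossings
        c.rho_smooth = np.array([0.0, 0.2, 0.4, 0.3, 0.1, 0.2, 0.4, 0.5, 0.6, 0.7])
        est = infer_alpha(c, DensityRecord("w", rho_exp=0.35))
        assert est.ambiguous
        assert est.alpha_ph < 0.35  # the first (smallest) crossing

    def test_unit_converter(self):
        assert per_mrna_to_per_codon(6.0, 300) == pytest.approx(0.02)


class TestGenomewide:
    def test_recovery_of_three_known_rates(self):
        # forward-simulate three genes at known alpha*, invert, recover
        alpha_star = {"G0": 0.03, "G1": 0.1, "G2": 0.5}
        profiles = []
        for i, gid in enumerate(alpha_star):
            _, p = make_synthetic_orf(
                SyntheticOrfSpec(length=150, seed=40 + i), gene_id=gid
            )
            profiles.append(p)
        fw = SimConfig(burn_in_time=400.0, measure_time=3000.0, seed=60)
        sw = SimConfig(burn_in_time=300.0, measure_time=1200.0, seed=61)
        density, truth = make_synthetic_density(profiles, alpha_star, fw)
        records = [
            DensityRecord(r.gene_id, r.rho_exp) for r in density.itertuples()
        ]
        grid = np.geomspace(1e-3, 5, 110)
        curves = [sweep_alpha(p, grid, sw) for p in profiles]
        summary, unmatched = infer_genomewide(curves, records)
        assert len(summary) == 3
        assert not unmatched["curves_without_density"]
        for gid, a_true in alpha_star.items():
            a_hat = float(summary.loc[summary.gene_id == gid, "alpha_ph"].iloc[0])
            assert a_hat == pytest.approx(a_true, rel=0.25)
        # summary carries the full per-transcript characterisation
        assert {"Te", "K", "J_max", "rho_max", "class_label", "status"} <= set(
            summary.columns
        )
        assert (summary["Te"] <= summary["J_max"] * 1.05).all()

    def test_unmatched_ids_reported(self, analytic_curve):
        grid = np.geomspace(0.01, 2, 40)
        curves = [
            analytic_curve(grid, lambda a: a, lambda a: a / (1 + a), gene_id=g)
            for g in ("a", "b")
        ]
        records = [DensityRecord("b", 0.3), DensityRecord("zzz", 0.2)]
        summary, unmatched = infer_genomewide(curves, records)
        assert unmatched["curves_without_density"] == ["a"]
        assert unmatched["density_without_curve"] == ["zzz"]
        assert list(summary.gene_id) == ["b"]

    def test_empty_join_rejected(self, analytic_curve):
        grid = np.geomspace(0.01, 2, 40)
        curves = [analytic_curve(grid, lambda a: a, lambda a: a, gene_id="a")]
        with pytest.raises(ValueError):
            infer_genomewide(curves, [DensityRecord("b", 0.3)])

    def test_identical_conditions_give_zero_delta(self, analytic_curve):
        grid = np.geomspace(0.01, 2, 40)
        curves = [
            analytic_curve(grid, lambda a: a, lambda a: a / (1 + a), gene_id=g)
            for g in ("a", "b")
        ]
        records = [DensityRecord("a", 0.3), DensityRecord("b", 0.5)]
        s1, _ = infer_genomewide(curves, records)
        s2, _ = infer_genomewide(curves, records)
        delta = compare_conditions(s1, s2)
        assert delta["delta_alpha_ph"].to_numpy() == pytest.approx([0.0, 0.0])


class TestDensityIO:
    def test_roundtrip_with_polysome_fraction(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene_id\trho_exp\tF\ng1\t0.05\t0.8\ng2\t0.02\t\n")
        recs = load_density_table(p)
        assert recs[0].polysome_fraction == 0.8
        assert recs[1].polysome_fraction is None

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            DensityRecord("g", rho_exp=0.0)
        with pytest.raises(ValueError):
            DensityRecord("g", rho_exp=0.1, polysome_fraction=1.5)
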