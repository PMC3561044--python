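"""Gillespie simulator vs closed forms, the exact master-equation oracle,
and the two-state/one-state dynamical distinction."""

import numpy as np
import pytest

from ribotraffic import RateProfile, SimConfig, exact_steady_state, simulate_steady_state
from ribotraffic.exact import enumerate_states, exact_entry_flux
from ribotraffic.traffic import simulate_trajectory


def uniform_profile(L, k, gene_id="u"):
    return RateProfile(gene_id=gene_id, codons=["AUG"] * L, k=np.full(L, float(k)))


class TestSimulator:
    def test_alpha_zero_gives_empty_lattice(self, quick_cfg):
        est = simulate_steady_state(uniform_profile(5, 10.0), 0.0, quick_cfg)
        assert est.J == 0.0
        assert est.rho == 0.0

    def test_negative_alpha_rejected(self, quick_cfg):
        with pytest.raises(ValueError):
            simulate_steady_state(uniform_profile(3, 10.0), -0.1, quick_cfg)

    def test_single_site_renewal_closed_form(self):
        # one codon, one ribosome at a time: the cycle is initiation, capture,
        # termination, so J = (1/alpha + 1/k + 1/beta)^-1
        cfg = SimConfig(
            gamma=35.0, beta=35.0, footprint=1,
            burn_in_time=200.0, measure_time=4000.0, seed=12,
        )
        prof = uniform_profile(1, 10.0)
        J_expected = 1.0 / (1.0 / 1.0 + 1.0 / 10.0 + 1.0 / 35.0)
        est = simulate_steady_state(prof, 1.0, cfg)
        assert est.J == pytest.approx(J_expected, abs=3 * est.J_stderr)

    def test_determinism_given_seed(self, quick_cfg):
        prof = uniform_profile(20, 5.0)
        a = simulate_steady_state(prof, 0.5, quick_cfg)
        b = simulate_steady_state(prof, 0.5, quick_cfg)
        assert a == b

    def test_five_site_uniform_matches_oracle(self):
        cfg = SimConfig(
            gamma=1.0, beta=1.0, footprint=1,
            burn_in_time=500.0, measure_time=6000.0, seed=8,
        )
        prof = uniform_profile(5, 1.0)
        J_exact, rho_exact = exact_steady_state(prof, 0.3, cfg)
        est = simulate_steady_state(prof, 0.3, cfg)
        assert est.J == pytest.approx(J_exact, abs=3 * est.J_stderr)
        assert est.rho == pytest.approx(rho_exact, abs=3 * est.rho_stderr)

    def test_two_state_differs_from_collapsed_tasep(self):
        # with a queue standing on slow codons, tRNA capture during blocking
        # raises the current relative to the memoryless one-step model
        cfg = SimConfig(burn_in_time=500.0, measure_time=6000.0, seed=4)
        prof = uniform_profile(200, 1.0)
        two = simulate_steady_state(prof, 2.0, cfg)
        one = simulate_steady_state(prof, 2.0, cfg.with_seed(99), one_state=True)
        z = abs(two.J - one.J) / np.hypot(two.J_stderr, one.J_stderr)
        assert two.J > one.J
        assert z > 3.0


class TestExactOracle:
    def test_single_site_closed_form_exact(self):
        cfg = SimConfig(gamma=35.0, beta=35.0, footprint=1)
        J, rho = exact_steady_state(uniform_profile(1, 10.0), 1.0, cfg)
        assert J == pytest.approx(1.0 / (1.0 + 0.1 + 1.0 / 35.0), abs=1e-12)

    def test_alpha_zero_exact(self):
        cfg = SimConfig(footprint=1)
        J, rho = exact_steady_state(uniform_profile(3, 5.0), 0.0, cfg)
        assert J == pytest.approx(0.0, abs=1e-12)
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_flux_conservation_entry_equals_exit(self):
        cfg = SimConfig(gamma=2.0, beta=2.0, footprint=1)
        prof = uniform_profile(3, 2.0)
        J_exit, _ = exact_steady_state(prof, 0.7, cfg)
        J_entry = exact_entry_flux(prof, 0.7, cfg)
        assert J_entry == pytest.approx(J_exit, rel=1e-10)

    def test_state_space_cap_enforced(self):
        cfg = SimConfig(footprint=1)
        with pytest.raises(ValueError, match="cap"):
            exact_steady_state(uniform_profile(8, 1.0), 1.0, cfg, cap=10)

    def test_enumeration_counts_min_gap(self):
        # L=2, ell=1: empty, 2 singles x 2 states, 1 pair x 4 states -> 9
        assert len(enumerate_states(2, 1)) == 9
        # L=3, ell=3: empty + 3 singles x 2 states -> 7
        assert len(enumerate_states(3, 3)) == 7

    @pytest.mark.parametrize("case", range(8))
    def test_gillespie_matches_oracle_random_instances(self, case):
        rng = np.random.default_rng(300 + case)
        L = int(rng.integers(2, 7))
        ell = int(rng.integers(1, 3))
        prof = RateProfile(
            gene_id=f"r{case}", codons=["AUG"] * L, k=rng.uniform(0.1, 35.0, L)
        )
        cfg = SimConfig(
            gamma=float(rng.uniform(1, 35)),
            beta=float(rng.uniform(1, 35)),
            footprint=ell,
            burn_in_time=500.0,
            measure_time=5000.0,
            seed=700 + case,
        )
        alpha = float(rng.uniform(0.05, 5.0))
        J_x, rho_x = exact_steady_state(prof, alpha, cfg)
        est = simulate_steady_state(prof, alpha, cfg)
        # 4-sigma guard per instance; the 3-sigma 95% coverage statement is
        # the acceptance-level ensemble check
        assert est.J == pytest.approx(J_x, abs=max(4 * est.J_stderr, 1e-6))
        assert est.rho == pytest.approx(rho_x, abs=max(4 * est.rho_stderr, 1e-6))


class TestTrajectoryInvariants:
    def test_exclusion_never_violated_on_full_trajectory(self):
        # validate=True asserts ordering, bounds and the footprint gap after
        # every single event
        prof = RateProfile(
            gene_id="t", codons=["AUG"] * 12,
            k=np.full(12, 3.0),
        )
        cfg = SimConfig(gamma=10.0, beta=10.0, footprint=3, seed=42)
        events = simulate_trajectory(prof, 2.0, cfg, t_max=200.0, validate=True)
        kinds = {e[1] for e in events}
        assert {"init", "capture", "hop", "terminate"} <= kinds

    def test_trajectory_current_agrees_with_kernel(self):
        # independent pure-Python implementation vs compiled kernel
        prof = RateProfile(gene_id="t", codons=["AUG"] * 6, k=np.full(6, 2.0))
        cfg = SimConfig(
            gamma=5.0, beta=5.0, footprint=2,
            burn_in_time=300.0, measure_time=4000.0, seed=17,
        )
        events = simulate_trajectory(prof, 1.0, cfg, t_max=4300.0)
        terms = [t for t, e, _ in events if e == "terminate" and t > 300.0]
        J_ref = len(terms) / 4000.0
        est = simulate_steady_state(prof, 1.0, cfg)
        # both are Monte Carlo; compare within combined error
        se = np.hypot(est.J_stderr, np.sqrt(len(terms)) / 4000.0)
        assert est.J == pytest.approx(J_ref, abs=4 * se)
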