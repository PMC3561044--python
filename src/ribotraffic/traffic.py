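"""Continuous-time stochastic simulation of two-state ribosome traffic.

The mRNA is a 1D lattice of L codons.  A ribosome is labelled by its A-site
codon a (1-based) and occupies a footprint of ell codons, enforced as a
minimum A-site gap: the next ribosome's A-site must be >= a + ell.  Dynamics:

* initiation: a new ribosome enters with A-site at codon 1 at rate alpha,
  provided the 5'-most ribosome's A-site is > ell;
* tRNA capture: a ribosome awaiting its tRNA on codon i captures it at the
  codon-specific rate k_i;
* translocation: a tRNA-bound ribosome advances one codon at rate gamma,
  blocked if the gap to the ribosome ahead equals ell.  Crucially, a blocked
  ribosome KEEPS its captured tRNA and translocates immediately (rate gamma)
  once the road clears — this distinguishes the model from a plain TASEP;
* termination: a tRNA-bound ribosome on the last codon detaches at rate beta.

Exact Gillespie event selection (exponential waiting times, rate-proportional
choice); no approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .codon_rates import RateProfile

__all__ = [
    "SimConfig",
    "SteadyStateEstimate",
    "simulate_steady_state",
    "one_state_rates",
]


@dataclass(frozen=True)
class SimConfig:
    """Kinetic constants and sampling plan for one steady-state run.

    gamma is the codon-independent translocation rate (35 s^-1); termination
    beta is taken comparably fast (= gamma by default).  The footprint is 9
    codons.  Times are in seconds of simulated time.
    """

    gamma: float = 35.0
    beta: float = 35.0
    footprint: int = 9
    burn_in_time: float = 2000.0
    measure_time: float = 8000.0
    sample_interval: float = 1.0
    n_batches: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if self.burn_in_time < 0 or self.measure_time <= 0:
            raise ValueError("invalid burn-in/measure times")
        if self.sample_interval <= 0 or self.n_batches < 2:
            raise ValueError("invalid sampling plan")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SteadyStateEstimate:
    """Time-averaged current J and density rho with batch-based standard errors."""

    J: float
    rho: float
    J_stderr: float
    rho_stderr: float
    n_terminations: int
    simulated_time: float

    def __post_init__(self) -> None:
        if self.J < 0 or self.rho < 0:
            raise ValueError("J and rho must be non-negative")


@njit(cache=True)
def _gillespie_kernel(
    k, alpha, gamma, beta, ell, burn_in, measure_time,
    sample_interval, n_batches, seed, one_state,
):  # pragma: no cover - exercised through simulate_steady_state
    L = k.shape[0]
    cap = L // ell + 2
    pos = np.zeros(cap, dtype=np.int64)
    st = np.zeros(cap, dtype=np.int64)  # 0 = awaiting tRNA, 1 = tRNA bound
    rr = np.zeros(cap, dtype=np.float64)
    n = 0

    np.random.seed(seed)
    t = 0.0
    t_end = burn_in + measure_time
    batch_len = measure_time / n_batches
    next_sample = burn_in + sample_interval

    term_counts = np.zeros(n_batches, dtype=np.int64)
    dens_sum = np.zeros(n_batches, dtype=np.float64)
    dens_cnt = np.zeros(n_batches, dtype=np.int64)

    while t < t_end:
        # rebuild the event-rate list (n is small: at most L/ell + 1)
        r_init = alpha if (n == 0 or pos[0] > ell) else 0.0
        total = r_init
        for i in range(n):
            if one_state:
                if pos[i] == L:
                    r = k[L - 1]  # caller folds termination into k_eff[L-1]
                elif i == n - 1 or pos[i + 1] - pos[i] > ell:
                    r = k[pos[i] - 1]
                else:
                    r = 0.0
            else:
                if st[i] == 0:
                    r = k[pos[i] - 1]
                elif pos[i] == L:
                    r = beta
                elif i == n - 1 or pos[i + 1] - pos[i] > ell:
                    r = gamma
                else:
                    r = 0.0
            rr[i] = r
            total += r

        if total <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t + np.random.exponential(1.0 / total)

        # density samples are taken from the state holding over (t, t_next]
        while next_sample <= t_next and next_sample <= t_end:
            b = int((next_sample - burn_in) / batch_len)
            if b >= n_batches:
                b = n_batches - 1
            dens_sum[b] += n
            dens_cnt[b] += 1
            next_sample += sample_interval

        if t_next > t_end:
            break
        t = t_next

        u = np.random.random() * total
        if u < r_init:
            # initiation: insert at the 5' end
            for j in range(n, 0, -1):
                pos[j] = pos[j - 1]
                st[j] = st[j - 1]
            pos[0] = 1
            st[0] = 0
            n += 1
            continue
        u -= r_init
        for i in range(n):
            if u < rr[i]:
                if one_state:
                    if pos[i] == L:
                        n -= 1  # i == n-1 by ordering
                        if t >= burn_in:
                            b = int((t - burn_in) / batch_len)
                            if b >= n_batches:
                                b = n_batches - 1
                            term_counts[b] += 1
                    else:
                        pos[i] += 1
                elif st[i] == 0:
                    st[i] = 1
                elif pos[i] == L:
                    n -= 1
                    if t >= burn_in:
                        b = int((t - burn_in) / batch_len)
                        if b >= n_batches:
                            b = n_batches - 1
                        term_counts[b] += 1
                else:
                    pos[i] += 1
                    st[i] = 0
                break
            u -= rr[i]

    return term_counts, dens_sum, dens_cnt


def simulate_trajectory(
    profile: RateProfile,
    alpha: float,
    config: SimConfig,
    t_max: float,
    validate: bool = True,
):
    """Pure-Python reference Gillespie yielding every event (debug mode).

    Returns a list of (time, event, a_site) tuples with event one of
    ``init``, ``capture``, ``hop``, ``terminate``.  With ``validate`` the
    lattice invariants (A-sites strictly increasing, gaps >= footprint, all
    within [1, L]) are asserted after every event.  Independent of the
    compiled kernel; intended for small systems only.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    L, ell = profile.L, config.footprint
    k, gamma, beta = profile.k, config.gamma, config.beta
    rng = np.random.default_rng(int(config.seed) % 2**31)
    ribs: list[list[int]] = []  # [a_site, state]
    t = 0.0
    events = []
    while True:
        rates = []
        if alpha > 0 and (not ribs or ribs[0][0] > ell):
            rates.append(("init", -1, alpha))
        for i, (a, s) in enumerate(ribs):
            if s == 0:
                rates.append(("capture", i, k[a - 1]))
            elif a == L:
                rates.append(("terminate", i, beta))
            elif i == len(ribs) - 1 or ribs[i + 1][0] - a > ell:
                rates.append(("hop", i, gamma))
        total = sum(r for _, _, r in rates)
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        u = rng.uniform(0, total)
        for name, i, r in rates:
            if u < r:
                break
            u -= r
        if name == "init":
            ribs.insert(0, [1, 0])
            events.append((t, "init", 1))
        elif name == "capture":
            ribs[i][1] = 1
            events.append((t, "capture", ribs[i][0]))
        elif name == "terminate":
            events.append((t, "terminate", ribs[i][0]))
            ribs.pop(i)
        else:
            ribs[i][0] += 1
            ribs[i][1] = 0
            events.append((t, "hop", ribs[i][0]))
        if validate:
            positions = [a for a, _ in ribs]
            assert all(1 <= a <= L for a in positions), "A-site out of lattice"
            assert all(
                b - a >= ell for a, b in zip(positions, positions[1:])
            ), "footprint exclusion violated"
    return events


def one_state_rates(profile: RateProfile, config: SimConfig) -> np.ndarray:
    """Collapsed single-exponential step rates for the plain-TASEP comparator.

    Capture and translocation merge into one step of mean 1/k_i + 1/gamma
    (1/k_L + 1/beta on the last codon).
    """
    k = profile.k
    k_eff = 1.0 / (1.0 / k + 1.0 / config.gamma)
    k_eff[-1] = 1.0 / (1.0 / k[-1] + 1.0 / config.beta)
    return k_eff


def simulate_steady_state(
    profile: RateProfile,
    alpha: float,
    config: SimConfig,
    one_state: bool = False,
) -> SteadyStateEstimate:
    """Gillespie estimate of the steady-state current and density.

    After ``burn_in_time``, J is the termination count divided by
    ``measure_time`` and rho the time average of N/L sampled every
    ``sample_interval``.  Standard errors come from splitting the measurement
    window into ``n_batches`` batches.  Reproducible given ``config.seed``.

    ``one_state=True`` runs the collapsed plain-TASEP comparator in which a
    blocked ribosome loses its progress towards the next hop.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    L = profile.L
    if L < 1:
        raise ValueError("profile must have at least one codon")

    k = one_state_rates(profile, config) if one_state else np.ascontiguousarray(profile.k)
    term_counts, dens_sum, dens_cnt = _gillespie_kernel(
        k,
        float(alpha),
        float(config.gamma),
        float(config.beta),
        int(config.footprint),
        float(config.burn_in_time),
        float(config.measure_time),
        float(config.sample_interval),
        int(config.n_batches),
        int(config.seed) % 2**31,
        one_state,
    )

    nb = config.n_batches
    batch_len = config.measure_time / nb
    batch_J = term_counts / batch_len
    J = float(batch_J.mean())
    J_stderr = float(batch_J.std(ddof=1) / np.sqrt(nb))

    with np.errstate(invalid="ignore"):
        batch_rho = np.where(dens_cnt > 0, dens_sum / np.maximum(dens_cnt, 1), 0.0) / L
    rho = float(batch_rho.mean())
    rho_stderr = float(batch_rho.std(ddof=1) / np.sqrt(nb))

    return SteadyStateEstimate(
        J=J,
        rho=rho,
        J_stderr=J_stderr,
        rho_stderr=rho_stderr,
        n_terminations=int(term_counts.sum()),
        simulated_time=config.burn_in_time + config.measure_time,
    )
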