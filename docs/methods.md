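# Methods

## The two-state exclusion process

A transcript is a lattice of L codons (the stop codon is stripped; L counts
sense codons only, positions 1..L, 1-based and inclusive everywhere). A
ribosome is labelled by its A-site codon *a* and excludes others through a
minimum A-site gap ℓ (default 9 codons, the measured footprint). Dynamics are
a continuous-time Markov chain with four transition types:

| transition | rate | condition |
| --- | --- | --- |
| initiation (new ribosome at a=1, awaiting tRNA) | α | no ribosome with a ≤ ℓ |
| tRNA capture on codon i | kᵢ | ribosome awaiting tRNA |
| translocation a → a+1 (tRNA released) | γ = 35 s⁻¹ | tRNA bound, gap to leader > ℓ |
| termination from a = L | β = 35 s⁻¹ | tRNA bound |

A blocked ribosome keeps its captured tRNA; on unblocking it needs only the
fast γ step. Collapsing capture+translocation into one exponential step of
mean 1/kᵢ + 1/γ (the `one_state` comparator) changes the dynamics measurably
whenever queued ribosomes sit on slow codons; with queues standing on fast
codons the two models coincide within error, which is why the dynamical
distinction is exercised on a uniformly slow lattice rather than on a narrow
bottleneck.

The A-site's placement within the physical footprint does not enter the
dynamics; ribosomes near the 3′ end need no downstream clearance beyond other
ribosomes. Termination requires the tRNA-bound state at codon L (i.e. the
last codon is elongated before release); this is a modelling choice — the
alternative (termination regardless of internal state) shifts J by at most
one fast step per cycle and does not change any qualitative behaviour.

## Simulation and error bars

The Gillespie kernel (numba-compiled) draws exponential waiting times from
the total rate and picks events rate-proportionally; no tau-leaping. After a
burn-in (default 2000 s simulated time) the current J is terminations per
second over the measurement window (default 8000 s) and ρ is the time average
of N/L sampled every 1 s. Standard errors come from 10 equal-time batches
(standard deviation of batch means / √10). Batch means are close to
independent because density autocorrelation times (≈ L/elongation speed,
seconds to tens of seconds) are far below the batch length. The stderr
estimate itself carries t₉ noise, so individual "within 3 stderr" checks
carry ≈1–2% false-alarm rates; ensemble checks use a 95% coverage criterion.
Tests and the acceptance pipeline shorten burn-in/measurement to 300–500 s /
1200–5000 s, which keeps every assertion comfortably inside its tolerance at
desk scale.

All stochastic entry points take explicit seeds; genome-scale sweeps derive
per-gene, per-grid-point seeds from the master seed plus a CRC of the gene id
(stable across processes), so results are independent of scheduling order.

## Exact oracle

For small systems the stationary distribution is solved exactly: all
configurations of A-site positions with gap ≥ ℓ, each ribosome in 2 internal
states, are enumerated (feasible to a few thousand states; hard cap 2×10⁵);
the generator's transpose is solved with one row replaced by the
normalization. J is the stationary flux through the termination transition
and equals the entry flux (flux conservation is asserted to machine
precision). The L = 1 renewal cycle J = (1/α + 1/k + 1/β)⁻¹ is reproduced to
1e-12.

## Capture rates from tRNA copy numbers

kᵢ = scaling × Σ over decoding anticodons (copy number × pairing factor).
Codon positions 1–2 must pair Watson–Crick; the codon's third base pairs with
the anticodon's first (wobble) base under a configurable factor table.
Defaults: Watson–Crick 1.0; G:U pairs (either orientation) 0.5; anticodons
beginning with A are treated as inosine-modified, reading U at 1.0 and C/A at
0.5. These factors are data, not code — the supplementary calibration behind
the published rates is not recoverable, so the table ships as configuration
with a single wobble-penalty knob. The scaling constant defaults to the value
making the (uniform- or usage-weighted) mean capture rate equal 10 s⁻¹; with
published absolute rates available, set `scaling` directly.

## Response curves and inversion

J(α) and ρ(α) are swept over a log-spaced α grid in [10⁻³, 5] s⁻¹ and
smoothed with a 10-point running average (window shrinks symmetrically at the
boundaries, so endpoints are preserved and short series get their overall
mean at the centre). Saturation values J_max/ρ_max are the mean of the last
five raw grid points; the gearing K is a central finite difference of the
smoothed, piecewise-linearly interpolated J at α_ph.

α_ph solves ρ_smooth(α) = ρ_exp on the piecewise-linear interpolant,
taking the smallest root and flagging the gene AMBIGUOUS if Monte-Carlo
noise leaves several distinct crossings. Densities above every smoothed value
return SATURATED at the grid maximum (the data cannot constrain α there —
the identifiability limit of the inversion); below the smallest value,
BELOW_GRID at the grid minimum.

A numerical caveat found during validation: a running *mean* over a
log-spaced window of an increasing curve sits above the window-centre value
(arithmetic vs geometric mean of the abscissae), biasing the inversion low by
roughly (ln r)²·Var(j)/2 per window, with r the grid ratio. On a 10-point
window this is ≈15% for a 40-point grid but ≈2% for a 110-point grid, so
recovery experiments and the acceptance pipeline use 110 log-spaced points.
Grid density is configuration; the smoothing itself is kept as the plain
running average.

## Curve classification

Features per gene, computed on the smoothed current (plus a confirmatory
density feature):

- `kink_score` = J_max / α₉₅, the knee-sharpness ratio, where α₉₅ is the α at
  which J first reaches 95% of J_max. Abrupt transcripts ride the
  initiation-limited line J = α until a mid-body queue caps them, giving a
  ratio near 1; smooth transcripts need α ≫ J_max, giving a small ratio. (A
  direct discrete second difference is unusable on a log grid: tiny spacings
  amplify Monte-Carlo noise into false kinks.) Curves already saturated at
  the grid start have no knee and score 0.
- `sat_sharpness` = (α₉₅ − α₅₀)/α₉₅, the relative width of the 50→95% rise.
- `rho_jump` = max single-step increase of ρ_smooth / ρ_max (queue formation
  jumps the density to its high branch).

Standardized features are clustered with 2-means (scikit-learn, fixed seed,
n_init=10); the cluster with the larger mean kink score is ABRUPT. Genes
whose relative margin between the two centroid distances is below 0.2
(a silhouette-style band fixed a priori, never tuned to outcome fractions)
are HYBRID. Labels are invariant to input order and stable across clustering
seeds; identical features for all genes degrade to all-HYBRID with a warning.

## Synonymous shuffling

For each amino acid independently, the multiset of its codons is permuted
across that amino acid's positions (Fisher–Yates per family). Amino-acid
sequence, codon multiset, CAI and mean capture rate are exactly invariant;
only the arrangement — and hence J — changes. Default ensemble size 2000;
tests use 25–50.

## CAI

Sharp–Li relative adaptiveness from a reference codon count: w_c = f_c / max
over synonyms; codons unseen in the reference get a 0.5-count floor (observed
counts are used unmodified); AUG, UGG and stops are excluded from the
geometric mean.

## Synthetic data

The generator emulates the constructions used throughout: a fast background
(k_fast = 20 s⁻¹, drawn over six amino-acid families) with an optional slow
cluster (k_slow = 1 s⁻¹, width 5 unless stated) placed mid-body or at the 5′
edge; the slow codon (GCC) is synonymous with a background codon (GCU) so
shuffling can relocate bottlenecks. Ground-truth initiation rates are drawn
log-uniform in [0.01, 1] s⁻¹, the physiological range where inversion is
well-conditioned. Forward-simulated densities carry realistic Monte-Carlo
noise but none of the systematic uncertainties of real density data
(normalization between genes, unloaded-mRNA fractions, measurement bias), so
a green recovery test establishes correctness of the inversion given the
model, not accuracy of the model for any organism. Genome-scale fractions of
smooth/abrupt/hybrid transcripts depend on real sequences and densities and
are outside what the synthetic panel can establish.

## Known limitations

- No near-/non-cognate tRNA competition, drop-off, recycling/reinitiation,
  finite ribosome pools, or 5′UTR structure: initiation heterogeneity is
  condensed into α.
- Wobble factors and the absolute rate calibration are configurable defaults,
  not fitted constants.
- The exact solver is restricted to small lattices (state space grows
  exponentially); it is an oracle, not a production path.
- SATURATED genes have no recoverable α (any sufficiently large α matches);
  they are flagged rather than estimated.
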