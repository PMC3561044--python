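# ribotraffic

Stochastic simulation of ribosome traffic on mRNAs and genome-wide inference
of translation initiation rates from ribosome-density data.

## The problem

How much protein an mRNA produces depends on two coupled stages: how fast
ribosomes *initiate* (load onto the start codon, rate α, s⁻¹) and how fast
they *elongate* through the codon field, where rare codons — served by scarce
tRNAs — act as bottlenecks that form ribosome queues. Neither stage can be
read off the sequence alone: the observable in experiments is the ribosome
density ρ (ribosomes per codon, i.e. normalized polysome size), which mixes
both. `ribotraffic` is for quantitative/systems biologists who want to turn
per-gene density measurements into per-gene initiation-rate estimates, and to
ask how a transcript's *codon arrangement* (not just its codon usage) shapes
its translational response.

## The model

An mRNA of L codons is a one-dimensional lattice. Ribosomes occupy ℓ = 9
codons (enforced as a minimum A-site gap) and follow a **two-state** cycle at
each codon *i*:

1. capture of the cognate tRNA at a codon-specific rate *k*ᵢ (proportional to
   tRNA gene copy number, with wobble-pairing corrections), then
2. translocation to codon *i*+1 at γ = 35 s⁻¹, blocked if the next position
   is occupied.

Crucially, a sterically blocked ribosome **keeps** its captured tRNA, so it
translocates immediately once the road clears — unlike a plain TASEP
(totally asymmetric simple exclusion process), where the whole step would
restart. Ribosomes enter at rate α when the first ℓ codons are clear and
terminate from the last codon at β = 35 s⁻¹. Exact (Gillespie) continuous-time
Monte Carlo gives the steady-state current J(α) (proteins · s⁻¹) and density
ρ(α); an exact master-equation solver provides the oracle on small lattices.

Per transcript, the package derives:

- **α_ph** — the physiological initiation rate, solving ρ_model(α_ph) = ρ_exp;
- **Te = J(α_ph)** — translation efficiency; **Te·m** (m = mRNA copies/cell,
  optionally × polysome-loaded fraction F) predicts protein abundance;
- **K = dJ/dα at α_ph** — "gearing", the responsiveness of protein output to
  initiation changes;
- **J_max, ρ_max** — elongation-limited saturation values;
- a **SMOOTH / ABRUPT / HYBRID** class from the shape of J(α): abrupt curves
  kink when a mid-body bottleneck starts queuing ribosomes, smooth curves
  (bottleneck at the 5′ edge, or none) saturate gradually;
- **synonymous-shuffle ensembles** that hold amino-acid sequence and codon
  composition (hence CAI) fixed while randomizing arrangement, isolating the
  arrangement effect on J.

## Worked example

```python
import numpy as np
from ribotraffic import (SimConfig, SyntheticOrfSpec, TranscriptTrafficModel,
                         make_synthetic_orf)

# a designed 300-codon ORF with a 5-codon slow cluster mid-body
_, profile = make_synthetic_orf(
    SyntheticOrfSpec(length=300, bottleneck=(150, 5, 1.0), seed=3),
    gene_id="YDEMO001")

model = TranscriptTrafficModel(
    profile,
    config=SimConfig(burn_in_time=500, measure_time=2000, seed=12),
    alpha_grid=np.geomspace(1e-3, 5, 110))
results = model.fit(rho_exp=0.035)   # observed ribosomes per codon
print(results.summary())
```

```
Transcript ribosome-traffic fit
==============================================
gene id            YDEMO001
L (codons)         300
observed density   0.035 ribosomes/codon
----------------------------------------------
alpha_ph           0.18413 s^-1  (status OK)
alpha_ph stderr    0.0102 s^-1
Te = J(alpha_ph)   0.15851 s^-1
gearing K          0.3714
J_max              0.181 s^-1
rho_max            0.063745 ribosomes/codon
response class     ABRUPT
==============================================
```

Reading: the observed density of 0.035 ribosomes/codon is reproduced at an
initiation rate of ≈ 0.18 s⁻¹; the transcript already produces 0.159
proteins/s, close to its elongation-limited ceiling J_max ≈ 0.18 s⁻¹, so its
gearing is low (a further α increase buys little) and its response curve is
ABRUPT — the mid-body slow cluster queues ribosomes once initiation outpaces
it.

The same analysis runs genome-wide from files via the CLI
(`ribotraffic fixtures | rates | sweep | infer | classify | shuffle |
predict`); inputs are an ORF FASTA, a tRNA gene-copy TSV and a density TSV,
outputs are per-gene curve TSVs plus a summary table
(gene_id, alpha_ph, status, Te, K, J_max, rho_max, class_label) and a YAML
manifest that makes every stochastic output reproducible.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
exercises the whole pipeline on a self-generated synthetic panel with known
ground truth: it forward-simulates densities at known α*, re-infers them from
the response sweeps, classifies the curves, runs a 50-variant synonymous
shuffle of a bottlenecked gene and predicts abundances, writing intermediate
tables to `results/acceptance_work/` and the target JSON to `--out`. All
randomness derives from `--seed`.
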