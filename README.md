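# ecdsb

Stochastic modeling of CRISPR–Cas9 double-strand breaks (DSBs) on multicopy
extrachromosomal DNA (ecDNA), for researchers studying genome editing of
amplified oncogenes in cancer cells.

ecDNA-positive tumor cells carry an oncogene amplicon on tens to hundreds of
extrachromosomal circles per cell. Cutting such a target with Cas9 is unlike
cutting a two-allele chromosomal locus: every copy is a cleavage site, so
guide activity translates into a *dose* of simultaneous DSBs that drives
cytotoxicity, micronucleus expulsion of damaged ecDNA, and poor editing of
the survivors. Attenuated "safeguard" guides (5′-cytosine-extended, [5C]–[20C])
lower the binding frequency and spread cleavage events out in time, which
this package models end to end:

1. **DSB placement** (`ecdsb.dsb`) — each ecDNA copy receives *f* Cas9
   binding events placed uniformly over 10 000 discrete time frames; the
   first event on a copy is its DSB. Statistics are taken over the sampling
   window of frames 1–100, where the per-copy hit probability has the closed
   form `P = 1 − (1 − w/T)^f`.
2. **Survival and fitting** (`ecdsb.survival`) — a cell with total DSB count
   `cp1` survives with probability

   `P(cp1) = 1 − cp1/Mt` for `0 ≤ cp1 ≤ Mt`, else `0`,

   with lethal threshold `Mt = 33`. `CleavageSelectionModel.fit()` recovers
   `(Mt, f)` from post-selection copy-number histograms by a two-stage
   sum-of-squared-residuals grid search (statsmodels-style model/results
   pair). The shipped per-condition frequencies are
   `{[0C]: 770, [5C]: 170, [10C]: 40, [15C]: 30, [20C]: 3}`.
3. **Temporal patterns** (`ecdsb.temporal`) — clustered DSBs (sliding
   5-frame window maxima, linked to micronucleus formation) versus
   temporally isolated single DSBs (no other DSB within ±2 frames, linked
   to small indels and HDR).
4. **Knock-in dynamics** (`ecdsb.knockin`) — 20.6% of isolated-single
   copies convert to TetO knock-in ecDNA; populations then cycle through
   uneven segregation (each copy class doubled to 2n and split
   `Binomial(2n, ½)`) and blasticidin-S-like selection

   `P(cp2) = 0.45 + cp2/30` (cp2 ≤ 6), `0.6 + cp2/120` (6 < cp2 ≤ 30),
   `0.85` (cp2 > 30),

   where `cp2` is the knock-in copy number.
5. **Synthetic populations** (`ecdsb.population`) — a calibrated
   negative-binomial generator for CORL23-like untreated populations
   (median 86 copies) plus pseudo-experiments with known ground truth for
   validating the fit.

A pipeline (`ecdsb.pipeline` / the `ecdsb` CLI) chains the stages with a
validated YAML config, deterministic seeding, and a checksummed manifest.

## Worked example

```python
import numpy as np
from ecdsb import (
    SimulationConfig, apply_survival, convert_isolated_to_knockin,
    generate_untreated_population, simulate_population,
)
from ecdsb.knockin import DynamicsConfig, run_dynamics
from ecdsb.temporal import windowed_max_dsb

pop = generate_untreated_population(10_000, seed=1)
print(f"untreated median copy number: {pop.median:.0f}")

records = simulate_population(pop, SimulationConfig(binding_frequency=770, seed=2))
survivors = apply_survival(records, Mt=33, mode="bernoulli",
                           rng=np.random.default_rng(3))
print(f"surviving fraction at f=770: {len(survivors.records) / len(records):.3f}")
print(f"mean survivor copy number: {survivors.copy_numbers.mean():.1f}")
winmax = [windowed_max_dsb(r, 5) for r in survivors.records]
print(f"median max DSBs per 5-frame window: {np.median(winmax):.0f}")

records10C = simulate_population(pop, SimulationConfig(binding_frequency=40, seed=4))
surv10C = apply_survival(records10C, Mt=33, mode="bernoulli",
                         rng=np.random.default_rng(5))
conv = convert_isolated_to_knockin(surv10C.records, rng=np.random.default_rng(6))
print(f"isolated-single copies at f=40: {conv.n_eligible}, "
      f"converted: {conv.n_converted} ({100 * conv.realized_rate:.1f}%)")

dyn = run_dynamics(conv.population, DynamicsConfig(runs=10, seed=7))
g4 = dyn.group_fraction("four", 4).mean(axis=1)
print(f"high-copy/high-KI fraction, iteration 0 -> 10: "
      f"{g4.iloc[0]:.3f} -> {g4.iloc[-1]:.3f}")
```

Output:

```text
untreated median copy number: 84
surviving fraction at f=770: 0.038
mean survivor copy number: 16.4
median max DSBs per 5-frame window: 6
isolated-single copies at f=40: 16127, converted: 3324 (20.6%)
high-copy/high-KI fraction, iteration 0 -> 10: 0.018 -> 0.405
```

Reading: the standard-activity guide (f = 770) kills 96% of the population
and leaves only low-copy survivors whose remaining breaks arrive in tight
clusters (~6 per 5-frame window); at safeguard activity (f = 40), a quarter
of cells survive with their amplification largely intact, one in seven
copies carries a temporally isolated DSB, 20.6% of those convert to
knock-ins, and ten cycles of uneven segregation under blasticidin-like
selection expand the high-copy/high-knock-in compartment from 2% to 40% of
cells.

The same sweep from a shell:

```sh
ecdsb run-all --seed 1 --out results/run1
ecdsb knockin --f 40 --selection eq --runs 50 --seed 1 --out results/ki40
```

## Documentation

`docs/methods.md` describes the model assumptions, the calibration of the
synthetic population generator, numerical choices, and known limitations.
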