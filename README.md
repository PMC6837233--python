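# humpback

A Bayesian stock assessment of the western South Atlantic (WSA) humpback
whale population (*Megaptera novaeangliae*, IWC breeding stock A), built as a
tested, reusable pipeline.  The population was hunted from about 1830 to
1972, first by shore-based and pelagic pre-modern whaling off Brazil and then
by modern whaling around South Georgia and the Scotia Sea; this package
reconstructs that removal history under uncertainty, fits a density-dependent
population model to modern survey data, and reports how far the population
has recovered toward its pre-exploitation size — together with the krill
consumption a recovered population implies.

It is intended for quantitative ecologists and stock-assessment scientists
who want to reproduce, perturb or extend the assessment: every input table is
packaged and checksum-validated, every scenario of the sensitivity grid is a
named, runnable object, and a synthetic-data module generates datasets with
the exact statistical structure the model assumes for parameter-recovery
studies.

## Model

Population dynamics are a deterministic generalized logistic
(Pella–Tomlinson) model,

    N_{t+1} = N_t + N_t r_max [1 − (N_t/K)^z] − C_t · SLR_p(t),

with the population at carrying capacity `K` in 1830.  `C_t` is the landed
catch in year `t` and `SLR_p(t)` an era-specific struck-and-lost rate factor
converting landings into total kills.  Pre-modern landings are known only as
a min–max envelope, interpolated by a single estimable parameter
`θ ∈ [0, 1]`: `C_t = C_t,min + θ(C_t,max − C_t,min)`.  The shape parameter
`z` fixes the maximum-sustainable-yield level at `(1+z)^(−1/z)` of `K`
(z = 2.39 → 60% of K).

`K` carries no prior.  Instead a uniform prior is placed on a recent
abundance (`N_2008 ~ U[500, 40 000]` in the reference case) and `K` is found
by bisection so the forward projection passes through the sampled value (the
"backwards" approach).  Likelihoods are lognormal for two absolute abundance
estimates (2008, 2012) and for relative indices from feeding (FG) and
breeding grounds (BG1, BG2), whose unknown catchabilities are integrated out
analytically under a flat prior on log-catchability.  Posteriors come from
sampling–importance–resampling (SIR): 2×10⁵ prior draws weighted by
likelihood and resampled to 10⁴ posterior draws.  Nineteen scenarios vary the
data, priors, catch allocation (Core / +Falkland / Fringe / Overlap),
struck-and-lost treatment, a genetic floor on minimum abundance (3× the
surviving mtDNA haplotype count), and `z`; nine comparable scenarios are
combined by Bayes-factor model averaging.

## Worked example

```python
import numpy as np
import humpback as hb

results, averaged = hb.run_assessment(seed=1)
print(hb.summarize(averaged.draws).to_string(index=False))
```

prints (about three minutes on one core; medians move by roughly a percent
with the seed):

```
     quantity         mean       median       pi_2_5      pi_97_5
        r_max     0.087902     0.088929     0.052920     0.115947
            K 28597.174331 28461.311685 23814.198995 34719.018237
        n_min   519.378250   423.651533   193.813109  1334.676214
       N_2019 25567.952523 25632.548973 23051.787061 27583.866574
  status_2019     0.900629     0.911257     0.717271     1.000000
```

(abridged).  Read: the pre-exploitation population was about 28 000 whales
(95% PI ≈ 24 000–35 000), whaling reduced it to a minimum of roughly 400–500
individuals in the late 1950s, the maximum population growth rate is about
8.9%/yr, and by 2019 the population had recovered to about 91% of carrying
capacity.  The scenario grid is available one name at a time:

```python
rc = hb.run_scenario("RC", np.random.default_rng(42))
```

A recovered population eats a lot of krill.  From the command line:

```
$ assess krill --population 24925
24925 whales x 497.23 kg/d x 120 d = 1.49 M tonnes (2.5% of biomass)
24925 whales x 874.33 kg/d x 120 d = 2.62 M tonnes (4.3% of biomass)
```

i.e. a 120-day feeding season at published per-whale daily ingestion rates
implies 1.49–2.62 million tonnes of Antarctic krill, 2.5–4.3% of the 60.3 M
tonne CCAMLR Area 48 biomass estimate.

The CLI also provides `assess run --scenario RC --seed 42 --out DIR`,
`assess average --out DIR`, `assess validate` (table checksums) and
`assess simulate` (synthetic datasets); outputs are `summary.csv`,
`trajectory_envelope.csv`, `draws.csv` and a `manifest.json` with seeds and
run metadata.

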