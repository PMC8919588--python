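# petrelmig

Migratory-consistency analysis for geolocator-tracked pelagic seabirds.

Tropical petrels that breed year-round and migrate across an entire ocean
basin pose a sharp question for movement ecology: when the environment is
weakly seasonal and resources unpredictable, are individuals flexible
migrants, or do they repeat their own route and schedule year after year?
Answering it from light-level geolocator (GLS) tags requires a long chain of
inference, and `petrelmig` implements that chain end to end for
biologging researchers:

1. **Geolocation** — threshold positions from twilight times (longitude from
   the twilight midpoint, latitude from day length at a calibrated zenith
   angle), refined by MCMC under a one-sided log-normal twilight-error model
   (meanlog 2.2, sdlog 1.0 log-minutes), a gamma(2.0, 0.1) flight-speed
   prior, a land mask, and an SST likelihood against a gridded weekly field;
   tracks are summarised as twice-daily medians with 95 % credible
   intervals.
2. **Segmentation** — daily light-interference, immersion and
   colony-distance features feed a two-state hidden Markov model
   (ashore / at-sea); migrations are ≥ 90-day at-sea runs, giving departure
   day, arrival day (days from 1 June) and duration.
3. **Similarity** — earth mover's distance (EMD, km: exact optimal transport
   with great-circle ground cost) between whole migrations and between
   matched 30-day periods / six equal stages, plus Bhattacharyya's affinity
   of 200-km-bandwidth kernel utilisation distributions as a scale-free
   counterpart.
4. **Inference** — repeatability R = σ²_among/(σ²_among+σ²_residual) of
   departure, arrival and duration (REML, parametric-bootstrap CIs, boundary
   LRT p-values); gamma GLMs of EMD on a same-individual flag and
   departure-date difference; a binomial/log GLM for BA; backwards stepwise
   deletion and Tukey-adjusted marginal-mean contrasts.

The real tracking data behind such studies are access-restricted, so the
package includes a first-class synthetic-population generator
(`petrelmig.simulate`) with known variance components and destinations:
every stage is validated by recovering known truth.

## Worked example

```python
from petrelmig.glm import fit_glm
from petrelmig.mcmc import ChainsConfig
from petrelmig.pipeline import run_all
from petrelmig.simulate import SimConfig

cfg = SimConfig(n_individuals=5, years_per_individual=(2,), years_probs=(1.0,),
                pre_days=20, post_days=20)
chains = ChainsConfig(burn_in=400, conv_runs=3, conv_samples=100, conv_thin=3,
                      n_chains=2, n_samples=500, max_restarts=3)
res = run_all(cfg, seed=2, n_boot=200, chains=chains, with_similarity_splits=False)

w = res.comparisons_whole
print("true departure repeatability:", round(res.truth.true_repeatability, 3))
print(res.repeatabilities[["trait", "R", "ci_low", "ci_high"]].to_string(index=False))
print("within-individual mean EMD:",
      round(w[w.same_individual == 1].emd_km.mean(), 1), "km")
print("between-individual mean EMD:",
      round(w[w.same_individual == 0].emd_km.mean(), 1), "km")
fit = fit_glm(w, "emd_km", ["same_individual", "departure_diff_days"],
              family="gamma", link="identity")
print("same-individual coefficient:",
      round(fit.params[fit.columns.index("same_individual")], 1), "km")
```

prints (seed 2; ~8 min on one CPU, dominated by the MCMC refinements):

```
true departure repeatability: 0.787
    trait     R  ci_low  ci_high
departure 0.873     0.0    0.996
  arrival 0.000     0.0    0.925
 duration 0.000     0.0    0.925
within-individual mean EMD: 219.4 km
between-individual mean EMD: 1369.8 km
same-individual coefficient: -936.1 km
```

Read it as: the ten simulated deployments were geolocated, segmented and
compared; migrations of the same individual in different years are far more
similar (≈ 220 km of transport "effort" apart) than migrations of different
individuals (≈ 1370 km), and the gamma GLM attributes a ~940 km reduction
in EMD to the same-individual contrast. With only five individuals the
variance-component estimates are very noisy — the departure estimate lands
near its construction value while arrival and duration hit the boundary
R = 0, with bootstrap intervals wide enough to admit either — which is
exactly why such studies need tens of repeat-tracked individuals;
study-scale runs tighten all three.

The same pipeline is scriptable from the shell — `petrelmig simulate |
geolocate | segment | similarity | stats`, or `petrelmig run-all`; running
the stages one by one writes bit-identical outputs to the combined command
given the same `--config` and `--seed`.

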