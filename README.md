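# spatialipm

Spatially explicit integrated population models (IPMs) for assessing the
**source–sink status of breeding habitats** when mortality is confounded
with permanent emigration.

## The problem

Whether a habitat is a demographic *source* or *sink* hinges on its
per-capita contribution to next year's population,

```
C_h,t = b_h,t · f_h,t · φ_fl,h,t + φ_br,h,t
```

(breeding success × fledglings of the modelled sex per successful site ×
first-year survival, plus breeder survival): a source has C > 1, a sink
C < 1. In any finite study area, mark–resight data only yield *apparent*
survival — animals that permanently emigrate are indistinguishable from
dead ones — so survival, and with it C, is underestimated and sinks are
over-diagnosed, the more severely the longer the dispersal distances of
the habitat in question.

`spatialipm` implements a two-habitat (Short/Tall ground vegetation,
one adult age class) IPM that corrects for this by modelling the observed
inter-annual movements themselves: a heavy-tailed Student-T dispersal
kernel (df = 5, scale per age × habitat) with a site-fidelity atom for
breeders, embedded in a multi-event mark–resight model whose detection
probability varies between an intensively monitored core, the peripheral
study area, and zero outside it. Four data streams are fitted jointly:

| stream | model |
|---|---|
| territory counts per habitat/year | Poisson observation on latent breeders `NB`, Gaussian state-space dynamics `NB_{t+1} = A_t NB_t + Im` |
| breeding success (B of R sites) | Binomial, logit intercept + year effects |
| brood sizes (F fledglings over S sites) | shifted Poisson `F − S ~ Pois(2fS − S)` |
| encounter histories + coordinates | spatial multi-event hidden-state model |

Derived posteriors: annual contributions `C_h,t` with source/sink
classification, net-immigration residuals `Im_{t+1} = NB_{t+1} − A_t NB_t`,
and age × habitat emigration rates. A non-spatial comparator (constant
detection, no locations) quantifies what ignoring movement does to the
answers. An individual-based simulator generates all four streams from the
exact generative model for parameter-recovery experiments.

## Worked example

```python
from spatialipm import FitConfig, fit_ipm
from spatialipm.io import bundle_from_sim
from spatialipm.simulate import generate_landscape, reduced_scenario, simulate_dataset

land = generate_landscape(n_core_sites=64, n_peripheral_sites=32, rng_seed=1)
sim = simulate_dataset(land, reduced_scenario(seed=3))   # known truth
bundle = bundle_from_sim(sim, land.area)

post_sp = fit_ipm(bundle, FitConfig.desk(seed=11))                        # spatial
post_ns = fit_ipm(bundle, FitConfig.desk(seed=11, variant="nonspatial"))  # comparator

from spatialipm import summarize_posterior
print(summarize_posterior(post_sp))
```

A run of the above prints (excerpt; the generating first-year survival was
0.222/0.158 and realized fledgling emigration 0.358/0.429):

```
     parameter      mean    ci_low   ci_high
  phi_fl_Short  0.183105  0.141399  0.230883
   phi_fl_Tall  0.151606  0.083227  0.227498
  phi_br_Short  0.551842  0.487143  0.613472
   phi_br_Tall  0.494769  0.411883  0.572150
       C_Short  0.981491  0.879432  1.094386
        C_Tall  0.736189  0.608799  0.876716
 emig_fl_Short  0.278908  0.210618  0.350019
  emig_fl_Tall  0.332816  0.193378  0.530003
```

The same comparator fit gives `phi_fl_Short = 0.151`, `phi_fl_Tall =
0.113`: without the movement data, fledgling survival collapses to
apparent survival, well below the generating truth. The spatial model
attributes the right share of disappearances to emigration (`emig_fl_*`
above, tracking the realized fractions) and pulls the credible intervals
back over the truth; `C_Short` near 1 shows Short habitat as borderline
self-sustaining rather than a clear sink.

The same pipeline is scriptable from the shell:

```bash
spatialipm simulate --scenario scenario.yaml --out data/
spatialipm fit --data data/ --variant spatial --sex M --out male_spatial.npz
spatialipm summarize --posterior male_spatial.npz
spatialipm contrast --a male_spatial.npz --b male_nonspatial.npz
spatialipm emigration --posterior male_spatial.npz
spatialipm ppc --posterior male_spatial.npz --data data/
```

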