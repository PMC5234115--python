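# microtrace

Analysis of household microbiota traces: can the skin microbiota a person
deposits on household surfaces identify them — and how quickly does that
signal decay as skin and surface communities turn over?

A person's skin microbiota is individually distinctive, so the community
they transfer to the surfaces they touch has been proposed as a forensic
marker, a microbial analogue of a fingerprint. Unlike a fingerprint,
though, both the source community and the deposited trace change with
time. `microtrace` implements the full analysis chain for longitudinal
skin/surface/air cohort studies, and ships a synthetic household-cohort
generator with complete ground truth so every stage is testable without
any external data. It is aimed at microbiome researchers studying the
built environment and at anyone evaluating the forensic reliability of
microbiota matching.

## What it computes

- **Source apportionment** (`microtrace.apportion`): a collapsed Gibbs
  sampler estimating, per surface sample ("sink"), the fraction of reads
  from each candidate source environment plus a latent Unknown:
  `P(z_i = v | z_-i) ∝ (m_vt + n_vt + α1)/(m_v + n_v + T·α1) · (n_v + β)`.
- **Microbiota matching** (`microtrace.matching`): occupant-group
  matching for every (residence, season) arrangement, accuracy as a
  function of sampling delay (surface season − skin season, −3…+3) and
  of candidate-pool size.
- **UniFrac** (`microtrace.phylo_distance`): weighted
  `Σ_b ℓ_b |p_A(b) − p_B(b)|` and unweighted branch-presence UniFrac,
  within/between-residence comparisons and delay-resolved profiles.
- **Persistence** (`microtrace.persistence`): first-observation season
  mapping per (individual, body site) or (residence, surface site)
  context, seasonal-origin fractions, abundance share of persistent OTUs.
- **Identifiability** (`microtrace.identify`): indicator values
  (IndVal = specificity × fidelity, permutation-tested), greedy minimal
  hitting sets, and cross-season re-identification.
- **Survival models** (`microtrace.survive`): right-censored
  counting-format event tables for OTU loss (skin, surface) and
  skin→surface deposition, fitted by Cox proportional hazards (Efron
  ties, Wald inference) with abundance-bin, IndVal-bin and
  hitting-set-membership covariates.
- **Synthetic cohorts** (`microtrace.synthetic_household`): a seeded
  generator mirroring a nine-residence, 19-occupant, four-season design
  (380 skin / 288 surface / 144 air samples) with configurable mixing
  weights, retention and deposition rates, and recorded ground truth.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

A reduced cohort — four residences, six occupants, three seasons — with
faster surface than skin turnover:

```python
import warnings
import numpy as np
from microtrace import GeneratorConfig, generate_study
from microtrace.data_io import preprocess_study
from microtrace.apportion import GibbsParams, surface_source_decomposition
from microtrace.matching import matching_experiment, accuracy_by_delay

warnings.filterwarnings("ignore")
config = GeneratorConfig(
    n_residences=4, occupants_per_residence=[1, 1, 2, 2], n_seasons=3,
    skin_sites=["forehead", "palm", "forearm"],
    surface_sites=["desk", "tv", "sink"], air_sites=["bedroom"],
    n_controls=3, read_depth_range=(800, 1200),
    n_common_core_otus=25, n_core_otus_per_individual=4,
    n_shared_household_otus=5, n_transient_otus_per_season=8,
    n_identifying_otus_per_individual=3, n_environment_otus=40,
    n_contaminant_otus=5, skin_retention_prob=0.7,
    surface_retention_prob=0.3, rng_seed=101,
)
table, meta, tree, truth = generate_study(config)
print(f"{table.n_samples} samples x {table.n_otus} OTUs")

clean, meta = preprocess_study(table, meta)   # contaminant filter + rarefaction
params = GibbsParams(restarts=3, burnin=50)

estimates = surface_source_decomposition(clean, meta, season=2, params=params, seed=0)
for source in ("skin", "air", "control", "Unknown"):
    mean = np.mean([e.proportions[source] for e in estimates.values()])
    print(f"{source:>8}: {100 * mean:5.1f}%")

results = matching_experiment(clean, meta, params=params, seed=0)
for delay, acc in accuracy_by_delay(results).items():
    print(f"delay {delay:+d}: accuracy {100 * acc:5.1f}%")
```

prints

```
105 samples x 276 OTUs
    skin:  46.1%
     air:  19.0%
 control:   1.3%
 Unknown:  33.7%
delay -2: accuracy  58.3%
delay -1: accuracy  79.2%
delay +0: accuracy  97.2%
delay +1: accuracy  91.7%
delay +2: accuracy 100.0%
```

Occupant skin is recovered as the dominant surface source (the kit
controls, a negative-control source, contribute ~1%), matching is nearly
perfect when skin and surface samples are contemporaneous, and accuracy
degrades as the delay between them grows. On the full-size default
design the decay is resolved out to ±3 seasons. A `microtrace` console
script exposes each stage (`microtrace simulate|unifrac|apportion|match|
persistence|identify|survive --help`).

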