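# Methods

`microtrace` asks a forensic question of household microbiology: the skin
community a person sheds onto the surfaces they touch is individually
distinctive — can such a trace identify its depositor, and for how long,
given that both skin and surface communities turn over? The package
implements the full analysis chain on OTU tables (counts of 16S OTUs per
sample), per-sample metadata and a rooted OTU phylogeny, together with a
synthetic household-cohort generator that provides ground truth for every
stage.

## The synthetic cohort generator

`synthetic_household.generate_study` emulates a longitudinal cohort:
`n_residences` homes (default 9, with occupant counts
{1,1,2,2,2,2,3,3,3} — 19 individuals), four ordered seasons, five skin
sites per occupant, eight surface and four air sites per residence, and
nine seasonless kit controls; at the defaults this yields 380 skin, 288
surface and 144 air samples.

**Community model.** OTUs belong to one of six classes. A *common core*
(40 OTUs, doubled base abundance) is carried by every individual: most
skin biomass is ordinary human skin flora with no household signal, which
is what makes matching non-trivial and delay-sensitive. Each individual
additionally has a small private *core* (6 OTUs, permanent), *identifying*
OTUs (4, private, low-to-mid abundance, transient dynamics), and
*transient* OTUs (12 new per season, each surviving a further season with
probability `skin_retention_prob`, default 0.6/season). Each residence has
*shared* household OTUs (8, on all occupants). *Environment* OTUs (90)
split 2:1 into an air pool (seen in air samples) and a residual pool
(surface-only noise, the latent "unknown" source); half of each pool is
seasonal — present in a single season only — reflecting seasonally varying
outdoor input. *Contaminants* (8) dominate kit controls, which also carry
a 10% background of real-community OTUs so that controls retain reads
after contaminant filtering.

**Abundances and counts.** Per-OTU base abundances are log-normal(0, 1),
shared across seasons, with per-season multiplicative log-normal noise
(sigma 0.25). Observed counts are multinomial at a per-sample depth drawn
uniformly from `read_depth_range` (default 1500–5000). A fixed
per-(individual, OTU, site) mask (presence probability 0.9) creates
site-level fidelity structure for the indicator-value analysis.

**Surfaces.** A surface community is a mixture with weights `mix_weights`
(default 0.6 skin / 0.2 air / 0.2 residual) of (i) the pooled
current-season occupant skin community restricted to OTUs currently
*resident* on that surface, (ii) the residence's air pool and (iii) the
residual pool. Residency follows a deposition/retention process: each
season, every skin-present OTU not already resident succeeds a Bernoulli
deposition trial with probability
`deposition_prob_base * relabund^deposition_abundance_exponent`
(defaults 1.0 and 0.05 — a season aggregates roughly ninety days of
contact, so within-season deposition is near-complete and mildly
abundance-biased), and each resident OTU survives to the next season with
`surface_retention_prob` (default 0.4 < skin's 0.6: traces decay faster
than their source). Three regimes of this process were required for the
generator to reproduce the emulated system's qualitative behaviour rather
than its opposite: a shared common core (else matching never decays with
delay), near-complete deposition (else surfaces cannot be explained by
skin sources at all), and seasonal environment turnover (else surfaces
are *more* persistent than skin). These are defaults, not analysis-code
assumptions; every rate is configurable.

**What the generator does not emulate:** read-level sequencing error,
chimeras, primer bias, compositional copy-number effects, within-season
dynamics, occupant travel or pets. Passing tests therefore demonstrate
that the analysis chain recovers known truth under a plausible community
model, not that it would achieve any particular accuracy on real data.

All randomness flows from `rng_seed`; regeneration is bit-identical
across processes (set iteration is avoided wherever draws are consumed).

## Preprocessing

Following standard amplicon practice: any OTU at ≥5% relative abundance
in any kit control (inclusive boundary) is flagged a likely reagent
contaminant and removed; non-control samples are rarefied by uniform
subsampling without replacement to the most depauperate sample's depth
(samples below an explicitly requested depth are dropped with a warning);
controls keep their residual raw counts and serve only as a pooled
negative-control source. Presence is count > 0 after rarefaction. Before
source apportionment, OTUs present in fewer than 10% of an input table's
samples are removed, per input table.

## Source apportionment

`apportion.gibbs_apportion` is a collapsed Gibbs sampler over per-read
latent source labels z_i ∈ {known sources, Unknown}:

    P(z_i = v | z_-i) ∝ (m_vt + n_vt + α1)/(m_v + n_v + T·α1) · (n_v + β)

with m the pooled training counts of source v (zero for Unknown, whose
prior is α2), n the sink reads currently assigned to v, and T the OTU
vocabulary size. Each source's multinomial is re-estimated jointly with
the assignments; the fixed-source variant is unstable — whenever part of
the sink is genuinely unexplained, the Unknown's empirical distribution
out-fits any fixed source and absorbs everything. Note the Unknown's
flexibility scales inversely with T·α2, so very small toy vocabularies
(tens of OTUs) exaggerate the Unknown; recovery checks use realistic
vocabularies. Defaults: α1 = 0.001, α2 = 0.1, β = 10, 10 restarts, 100
burn-in sweeps, one retained draw per restart; proportions are the mean
of n_v/N over retained draws. The sweep kernel is compiled with numba;
experiment drivers use a lighter schedule (2–3 restarts, 30–50 sweeps),
which on the test regimes is indistinguishable from the defaults.

Surface decomposition uses, per surface sink, pooled same-residence
same-season skin, pooled same-residence air, and pooled kit controls as
sources. Matching pools skin samples per residence occupant group (one
environment per residence), prepares one input table per
(target residence, source season) — sinks are the residence's surfaces
from all seasons, so sources never span seasons — and scores a sink
correct when its own group's proportion strictly exceeds every other
group's (ties incorrect; Unknown never wins). Sampling delay is surface
season minus skin season; accuracy is per sink sample per delay.

## Distances, persistence, identifiability

UniFrac is computed on a single post-order indexing of the tree;
unweighted compares branch presence, weighted (raw by default, matching
the cited pipeline's default; normalized by flag) compares branch
abundance mass. Group comparisons use rank-based tests (Mann-Whitney,
Kruskal-Wallis) with asymptotic p-values.

Persistence statistics map each OTU, within its context — (individual,
body site) for skin, (residence, surface site) for surfaces — to the
first season observed; persistence counts distinct seasons (gaps allowed,
consistent with the survival module's interim rule).

IndVal for OTU o and individual i is specificity (i's mean site relative
abundance of o over the sum of that mean across individuals) times
fidelity (fraction of i's sites containing o); significance by permuting
individual labels over site samples (1000 permutations, add-one estimator
(b+1)/(B+1)), non-significant values masked to 0. Hitting sets use a
greedy cover: candidates are OTUs detected in the target at
≥ `detect_threshold` (default 1e-3 relative abundance); a candidate
resolves a confounder whose abundance is below `detect_threshold /
demotion_factor` (default 2); ties prefer higher target abundance then
lexicographic id. Re-identification requires every member OTU detected.
The thresholds are declared defaults of this implementation, not claims
about any external tool's configuration.

## Survival models

Each (OTU, context) is a subject encoded in right-censored counting
format, one interval per season transition from first observation.
Covariates at interval start: abundance percentile bin (0–69/70–89/
90–98/99th, ranked among OTUs present in the context that season; absent
interim seasons take the lowest bin), IndVal bin (0–0.2/0.2–0.6/0.6–0.9/
0.9–1; surfaces use the max over occupants), and hitting-set membership
fixed at the first-observed season. Loss events sit on the transition out
of the last observed season — the two natural readings of the censoring
rule conflict for single-season OTUs; placing the loss on the first
season of absence keeps every subject with ≥1 at-risk interval.
Subjects observed in the final season are censored; interim absences are
not events. Deposition subjects are skin (OTU, body site) observations;
the event is the first same-or-later-season observation on any of the
residence's surfaces (same-season events occupy the first interval), and
OTUs seen on a surface before any occupant's skin are excluded. Reference
levels (lowest bins, non-membership) are implicit by exclusion.

The fitter maximises the counting-process partial likelihood with the
Efron tie correction (Breslow available; note duplicating all records is
an exact invariance only under Breslow) by Newton-Raphson with
step-halving, converging at gradient norm < 1e-8 within 50 iterations.
Wald inference: z = β/SE from the inverse observed information, 95% CIs
exp(β ± 1.96·SE). Constant columns are dropped; |β| > 10 is flagged as
probable complete separation with a warning. Calibration checks:
grid-search agreement to 1e-4 on 8-subject toys, hazard-ratio recovery
±0.15 at a true ratio of 2 (n=500, 50 replicates), empirical Wald
type-I error within [2%, 9%] at nominal 5% (100 null replicates), and
coefficient agreement with an independent established fitter to 1e-6 on
untied data.

## Problem sizes and reproduction

Tests run on a reduced design (4 residences, 6 individuals, 3 seasons,
3 skin/3 surface/1 air sites, ~270 OTUs) where mechanism, not scale, is
under test, and on the full default design where vocabulary size matters
(source decomposition). `scripts/acceptance.py --seed <int> --out
<path>` regenerates the full-design study and recomputes every headline
quantity end-to-end; on default conditions the surface decomposition
lands near 58% skin / 19% air / ~1% control / 23% unknown, matching
accuracy is perfect at zero delay and decays with |delay|, skin
persistence exceeds surface persistence, and the hazard models recover
the designed directions (abundant OTUs rarely lost, identifying OTUs
preferentially lost).

## Known limitations

- The Gibbs mixing diagnostics are restart-variance only; no formal
  convergence statistics.
- Proportional-hazards diagnostics (Schoenfeld-type checks) are not
  implemented; with four seasons the models have at most three event
  times per subject and limited power to detect non-proportionality.
- IndVal permutation p-values are not multiplicity-adjusted (masking at
  0.05 follows the analysis convention, not an FDR argument).
- The generator's surface mixture is season-synchronous; it has no
  within-season kinetics, so "delay" is only resolved at season
  granularity.
- The generator reproduces the weighted-UniFrac delay skew (skin-after-
  surface pairs more similar) but not the corresponding skew in matching
  *accuracy*: because surfaces accumulate residues of several past
  seasons, surface-after-skin matching stays easier here than the
  reverse. Accuracy still decays with |delay| in both directions.
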