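"""Collapsed-Gibbs Bayesian source apportionment.

Estimates, for a sink community, what fraction of its reads originated
from each of a set of known source environments plus a latent Unknown
source.  Each sink read i carries a latent source label z_i; the
collapsed Gibbs update is

    P(z_i = v | z_-i)  propto  P(x_i | v) * (n_v^{-i} + beta)

where n_v is the number of sink reads currently assigned to v and:

- for a known source v, P(x_i | v) = (m_{v,x_i} + n_{v,x_i} + alpha1) /
  (sum_t m_{v,t} + n_v + T*alpha1), with m the pooled training counts
  of the source, n_{v,t} the sink reads currently assigned to v, and T
  the OTU vocabulary size — each source's multinomial is re-estimated
  jointly with the assignments, which anchors well-fitting sources
  against leakage into the Unknown;
- the Unknown source is the same conditional with zero training counts
  and its own prior alpha2.

Mixing proportions are the posterior mean of n_v / N over retained
draws, averaged across independent restarts.  Default priors and
schedule (alpha1 = 0.001, alpha2 = 0.1, beta = 10, 10 restarts, 100
burn-in sweeps, 1 retained draw per restart) follow the classic
source-tracking tool's v1.0 defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from microtrace.data_io import OtuTable, OtuTableError

__all__ = [
    "GibbsParams",
    "SourceEnvironment",
    "SourceEstimate",
    "gibbs_apportion",
    "surface_source_decomposition",
    "UNKNOWN",
]

UNKNOWN = "Unknown"


@dataclass
class GibbsParams:
    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    restarts: int = 10
    burnin: int = 100
    draws_per_restart: int = 1
    thin: int = 10

    def validate(self) -> None:
        if min(self.alpha1, self.alpha2) <= 0 or self.beta < 0:
            raise OtuTableError("priors must be positive")
        if self.restarts < 1 or self.burnin < 0 or self.draws_per_restart < 1:
            raise OtuTableError("invalid Gibbs schedule")


@dataclass
class SourceEnvironment:
    """A named candidate source: pooled member-sample counts over OTUs."""

    name: str
    counts: pd.Series

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise OtuTableError(f"source {self.name!r} has negative counts")


@dataclass
class SourceEstimate:
    """Posterior mixing proportions for one sink over sources + Unknown."""

    sink_id: str
    proportions: dict[str, float]
    draws: np.ndarray  # (n_draws_total, n_sources + 1), Unknown last

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise OtuTableError(f"proportions for {self.sink_id!r} sum to {total}")

    def predicted(self, exclude_unknown: bool = True) -> str:
        cand = {
            k: v for k, v in self.proportions.items() if not (exclude_unknown and k == UNKNOWN)
        }
        return max(cand, key=cand.get)


@njit(cache=True)
def _gibbs_core(
    reads: np.ndarray,  # taxon index per sink read, int64
    source_counts: np.ndarray,  # (V, T_sink) pooled source counts on sink taxa
    source_totals: np.ndarray,  # (V,) pooled source totals over ALL taxa
    alpha1: float,
    alpha2: float,
    beta: float,
    t_total: int,
    burnin: int,
    draws: int,
    thin: int,
    seed: int,
) -> np.ndarray:
    np.random.seed(seed)
    n = reads.shape[0]
    n_known = source_counts.shape[0]
    n_env = n_known + 1
    t_sink = source_counts.shape[1]
    z = np.empty(n, dtype=np.int64)
    env_counts = np.zeros(n_env, dtype=np.int64)
    # sink reads currently assigned to each environment, per taxon; the
    # Unknown environment (last row) has no training counts
    assigned = np.zeros((n_env, t_sink), dtype=np.int64)
    for i in range(n):
        v = np.random.randint(0, n_env)
        z[i] = v
        env_counts[v] += 1
        assigned[v, reads[i]] += 1
    probs = np.empty(n_env)
    out = np.zeros((draws, n_env))
    known_prior = t_total * alpha1
    unk_prior = t_total * alpha2
    n_sweeps = burnin + 1 + (draws - 1) * thin
    draw_idx = 0
    for sweep in range(n_sweeps):
        for i in range(n):
            t = reads[i]
            v_old = z[i]
            env_counts[v_old] -= 1
            assigned[v_old, t] -= 1
            total = 0.0
            for v in range(n_known):
                like = (source_counts[v, t] + assigned[v, t] + alpha1) / (
                    source_totals[v] + env_counts[v] + known_prior
                )
                p = like * (env_counts[v] + beta)
                probs[v] = p
                total += p
            unk_total = env_counts[n_known]
            p_unk = (
                (assigned[n_known, t] + alpha2)
                / (unk_total + unk_prior)
                * (unk_total + beta)
            )
            probs[n_known] = p_unk
            total += p_unk
            u = np.random.random() * total
            acc = 0.0
            v_new = n_env - 1
            for v in range(n_env):
                acc += probs[v]
                if u < acc:
                    v_new = v
                    break
            z[i] = v_new
            env_counts[v_new] += 1
            assigned[v_new, t] += 1
        if sweep >= burnin and (sweep - burnin) % thin == 0 and draw_idx < draws:
            for v in range(n_env):
                out[draw_idx, v] = env_counts[v] / n
            draw_idx += 1
    return out


def gibbs_apportion(
    sink,
    sources: list[SourceEnvironment],
    params: GibbsParams | None = None,
    seed: int = 0,
    sink_id: str = "sink",
    vocabulary_size: int | None = None,
) -> SourceEstimate:
    """Apportion one sink's reads over known sources plus Unknown.

    ``sink`` is a count vector (``pandas.Series`` indexed by OTU id).
    Sources with zero total counts are excluded with a warning; a sink
    with zero reads is an error.  ``vocabulary_size`` is the OTU
    vocabulary T used in the smoothing denominators (defaults to the
    union of sink and source support).
    """
    params = params or GibbsParams()
    params.validate()
    sink = pd.Series(sink).astype(np.int64)
    if sink.sum() <= 0:
        raise OtuTableError(f"sink {sink_id!r} has zero reads")
    kept: list[SourceEnvironment] = []
    for src in sources:
        if src.counts.sum() <= 0:
            warnings.warn(f"excluding empty source {src.name!r}", stacklevel=2)
        else:
            kept.append(src)
    if not kept:
        raise OtuTableError("no non-empty sources")
    names = [s.name for s in kept]
    if len(set(names)) != len(names):
        raise OtuTableError("duplicate source names")

    vocab = pd.Index(sink.index)
    for src in kept:
        vocab = vocab.union(src.counts.index)
    t_total = vocabulary_size if vocabulary_size is not None else len(vocab)

    sink_taxa = sink.index[sink > 0]
    reads = np.repeat(
        np.arange(len(sink_taxa), dtype=np.int64), sink[sink_taxa].to_numpy()
    )
    source_counts = np.empty((len(kept), len(sink_taxa)))
    source_totals = np.empty(len(kept))
    for v, src in enumerate(kept):
        source_counts[v] = src.counts.reindex(sink_taxa, fill_value=0).to_numpy(dtype=float)
        source_totals[v] = float(src.counts.sum())

    rng = np.random.default_rng(seed)
    all_draws = []
    for _ in range(params.restarts):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        all_draws.append(
            _gibbs_core(
                reads,
                source_counts,
                source_totals,
                params.alpha1,
                params.alpha2,
                params.beta,
                t_total,
                params.burnin,
                params.draws_per_restart,
                params.thin,
                restart_seed,
            )
        )
    draws = np.vstack(all_draws)
    mean = draws.mean(axis=0)
    mean = mean / mean.sum()
    proportions = {name: float(p) for name, p in zip(names + [UNKNOWN], mean)}
    return SourceEstimate(sink_id=sink_id, proportions=proportions, draws=draws)


def pooled_environment(table: OtuTable, sample_ids, name: str) -> SourceEnvironment:
    """Pool member samples of an environment by summing their counts."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise OtuTableError(f"environment {name!r} has no member samples")
    return SourceEnvironment(name=name, counts=table.data.loc[sample_ids].sum(axis=0))


def surface_source_decomposition(
    table: OtuTable,
    meta: pd.DataFrame,
    season: int,
    params: GibbsParams | None = None,
    seed: int = 0,
) -> dict[str, SourceEstimate]:
    """Apportion each surface sample of a season over skin/air/control sources.

    For each surface sink: sources are the pooled skin samples of the
    sink's own residence (same season), the pooled air samples of that
    residence (same season), and the pooled kit controls (a negative
    control source).  Returns a map sink id -> estimate with proportions
    over {"skin", "air", "control", "Unknown"}.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    surfaces = meta[(meta["type"] == "surface") & (meta["season"] == season)]
    if surfaces.empty:
        raise OtuTableError(f"no surface samples in season {season}")
    controls = meta[meta["type"] == "control"]
    if controls.empty:
        raise OtuTableError("missing source class: control")
    rng = np.random.default_rng(seed)
    out: dict[str, SourceEstimate] = {}
    for sid, row in surfaces.iterrows():
        res = row["residence"]
        skin_ids = meta[
            (meta["type"] == "skin") & (meta["residence"] == res) & (meta["season"] == season)
        ].index
        air_ids = meta[
            (meta["type"] == "air") & (meta["residence"] == res) & (meta["season"] == season)
        ].index
        if skin_ids.empty:
            raise OtuTableError(f"missing source class: skin for residence {res!r}")
        if air_ids.empty:
            raise OtuTableError(f"missing source class: air for residence {res!r}")
        sources = [
            pooled_environment(table, skin_ids, "skin"),
            pooled_environment(table, air_ids, "air"),
            pooled_environment(table, controls.index, "control"),
        ]
        out[sid] = gibbs_apportion(
            table.data.loc[sid],
            sources,
            params=params,
            seed=int(rng.integers(0, 2**31 - 1)),
            sink_id=sid,
            vocabulary_size=table.n_otus,
        )
    return out
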