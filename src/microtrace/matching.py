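"""Occupant-to-residence microbiota matching experiments.

For every (residence, season) pair an input table is prepared with the
residence's surface samples from *all* seasons as sinks and the skin
samples of all residences in the target season as candidate sources
(one pooled source environment per residence occupant group).  Rare
OTUs (present in <10% of the input table's samples) are removed within
each input table.  A sink is an accurate match when the estimated
contribution of its own residence's occupants strictly exceeds every
other candidate's; ties are scored incorrect and the Unknown source
never wins.  Accuracy is reported per sampling delay (surface season
minus source skin season, -(S-1)..+(S-1)) and, in the candidate-subset
experiment, per candidate-pool size at zero delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from microtrace.apportion import (
    UNKNOWN,
    GibbsParams,
    SourceEstimate,
    gibbs_apportion,
    pooled_environment,
)
from microtrace.data_io import OtuTable, OtuTableError, prevalence_filter

__all__ = [
    "MatchResult",
    "MatchingInput",
    "build_matching_inputs",
    "run_matching_input",
    "matching_experiment",
    "score_matches",
    "accuracy_by_delay",
    "subset_size_experiment",
]


@dataclass
class MatchResult:
    sink_id: str
    sink_residence: str
    sink_season: int
    source_season: int
    predicted: str
    correct: bool

    @property
    def delay(self) -> int:
        """Sink surface season minus source skin season."""
        return self.sink_season - self.source_season


@dataclass
class MatchingInput:
    """One (target residence, source season) matching arrangement."""

    residence: str
    season: int
    table: OtuTable  # prevalence-filtered over sinks + sources
    sink_ids: list[str]
    source_groups: dict[str, list[str]]  # candidate residence -> skin sample ids


def build_matching_inputs(
    table: OtuTable, meta: pd.DataFrame, min_prevalence: float = 0.10
) -> list[MatchingInput]:
    """Prepare input tables for all pairwise (residence, season) combinations.

    Sinks never mix with sources from more than one season; the
    prevalence filter is applied within each input table, not globally.
    Residences with no surface samples are skipped with a warning.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    surfaces = meta[meta["type"] == "surface"]
    skins = meta[meta["type"] == "skin"]
    residences = sorted(skins["residence"].dropna().unique())
    seasons = sorted(int(s) for s in skins["season"].dropna().unique())
    inputs: list[MatchingInput] = []
    for res in sorted(surfaces["residence"].dropna().unique().tolist() + [
        r for r in residences if r not in set(surfaces["residence"].dropna())
    ]):
        sink_ids = list(surfaces[surfaces["residence"] == res].index)
        if not sink_ids:
            warnings.warn(f"residence {res!r} has no surface samples; skipped", stacklevel=2)
            continue
        for season in seasons:
            season_skins = skins[skins["season"] == season]
            groups = {
                r: list(grp.index)
                for r, grp in season_skins.groupby("residence")
                if len(grp)
            }
            member_ids = sink_ids + [s for ids in groups.values() for s in ids]
            sub = prevalence_filter(table.subset_samples(member_ids), min_prevalence)
            inputs.append(
                MatchingInput(
                    residence=res,
                    season=season,
                    table=sub,
                    sink_ids=sink_ids,
                    source_groups=groups,
                )
            )
    return inputs


def run_matching_input(
    inp: MatchingInput,
    meta: pd.DataFrame,
    params: GibbsParams | None = None,
    seed: int = 0,
    candidate_subset: list[str] | None = None,
) -> dict[str, SourceEstimate]:
    """Apportion every sink of one matching input over its candidate groups."""
    groups = inp.source_groups
    if candidate_subset is not None:
        groups = {r: groups[r] for r in candidate_subset}
    if len(groups) < 2:
        raise OtuTableError("matching needs at least two candidate groups")
    sources = [pooled_environment(inp.table, ids, r) for r, ids in sorted(groups.items())]
    rng = np.random.default_rng(seed)
    estimates: dict[str, SourceEstimate] = {}
    for sid in inp.sink_ids:
        sink = inp.table.data.loc[sid]
        if sink.sum() == 0:
            warnings.warn(f"sink {sid!r} empty after filtering; skipped", stacklevel=2)
            continue
        estimates[sid] = gibbs_apportion(
            sink,
            sources,
            params=params,
            seed=int(rng.integers(0, 2**31 - 1)),
            sink_id=sid,
            vocabulary_size=inp.table.n_otus,
        )
    return estimates


def score_matches(
    estimates: dict[str, SourceEstimate],
    sink_truth: dict[str, tuple[str, int]],
    source_season: int,
) -> list[MatchResult]:
    """Score estimates against the sinks' true residences.

    ``sink_truth`` maps sink id -> (true residence, sink season).  The
    predicted residence is the candidate with the strictly greatest
    proportion (Unknown excluded); exact ties are conservatively scored
    incorrect.
    """
    results = []
    for sid, est in estimates.items():
        cand = {k: v for k, v in est.proportions.items() if k != UNKNOWN}
        if not cand or all(v == 0 for v in cand.values()):
            raise OtuTableError(f"sink {sid!r} has all-zero candidate proportions")
        best = max(cand.values())
        winners = [k for k, v in cand.items() if v == best]
        res, season = sink_truth[sid]
        predicted = winners[0] if len(winners) == 1 else "|".join(sorted(winners))
        correct = len(winners) == 1 and winners[0] == res
        results.append(
            MatchResult(
                sink_id=sid,
                sink_residence=res,
                sink_season=int(season),
                source_season=int(source_season),
                predicted=predicted,
                correct=correct,
            )
        )
    return results


def matching_experiment(
    table: OtuTable,
    meta: pd.DataFrame,
    params: GibbsParams | None = None,
    seed: int = 0,
    min_prevalence: float = 0.10,
    shuffle_sources: bool = False,
) -> list[MatchResult]:
    """Run the full delay-resolved matching experiment.

    Every surface sink is matched once per source season, so each sink
    appears (number of seasons) times in the results, once per sampling
    delay.  ``shuffle_sources`` permutes the candidate-group labels
    within each input table (chance-level control).
    """
    inputs = build_matching_inputs(table, meta, min_prevalence)
    rng = np.random.default_rng(seed)
    results: list[MatchResult] = []
    for inp in inputs:
        groups = inp.source_groups
        if shuffle_sources:
            names = sorted(groups)
            perm = [names[i] for i in rng.permutation(len(names))]
            inp = MatchingInput(
                residence=inp.residence,
                season=inp.season,
                table=inp.table,
                sink_ids=inp.sink_ids,
                source_groups={new: groups[old] for new, old in zip(names, perm)},
            )
        estimates = run_matching_input(
            inp, meta, params=params, seed=int(rng.integers(0, 2**31 - 1))
        )
        truth = {
            sid: (inp.residence, int(meta.loc[sid, "season"])) for sid in estimates
        }
        results.extend(score_matches(estimates, truth, inp.season))
    return results


def accuracy_by_delay(results: list[MatchResult]) -> dict[int, float]:
    """Fraction of correct matches per sampling delay; empty delays omitted."""
    if not results:
        raise OtuTableError("no match results to score")
    totals: dict[int, list[int]] = {}
    for r in results:
        totals.setdefault(r.delay, []).append(int(r.correct))
    return {d: float(np.mean(v)) for d, v in sorted(totals.items())}


def subset_size_experiment(
    table: OtuTable,
    meta: pd.DataFrame,
    sizes=(2, 4, 6, 8),
    n_repeats: int = 50,
    params: GibbsParams | None = None,
    seed: int = 0,
    min_prevalence: float = 0.10,
) -> dict[int, float]:
    """Zero-delay matching accuracy against random candidate subsets.

    For each subset size k, the candidate pool for a sink is its correct
    residence group plus k-1 others sampled without replacement; accuracy
    is averaged over ``n_repeats`` draws.  Only same-season (delay 0)
    sink/source arrangements are used.
    """
    if any(k < 2 for k in sizes):
        raise OtuTableError("subset sizes must be >= 2")
    inputs = build_matching_inputs(table, meta, min_prevalence)
    rng = np.random.default_rng(seed)
    correct: dict[int, list[int]] = {k: [] for k in sizes}
    for inp in inputs:
        groups = sorted(inp.source_groups)
        if inp.residence not in inp.source_groups:
            continue
        others = [g for g in groups if g != inp.residence]
        delay0_sinks = [
            s for s in inp.sink_ids if int(meta.loc[s, "season"]) == inp.season
        ]
        if not delay0_sinks:
            continue
        sub_inp = MatchingInput(
            residence=inp.residence,
            season=inp.season,
            table=inp.table,
            sink_ids=delay0_sinks,
            source_groups=inp.source_groups,
        )
        for k in sizes:
            if k > len(groups):
                raise OtuTableError(f"subset size {k} exceeds {len(groups)} candidate groups")
            for _ in range(n_repeats):
                chosen = [inp.residence] + [
                    others[i] for i in rng.choice(len(others), size=k - 1, replace=False)
                ]
                estimates = run_matching_input(
                    sub_inp,
                    meta,
                    params=params,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    candidate_subset=chosen,
                )
                truth = {
                    sid: (inp.residence, int(meta.loc[sid, "season"])) for sid in estimates
                }
                for r in score_matches(estimates, truth, inp.season):
                    correct[k].append(int(r.correct))
    return {k: float(np.mean(v)) for k, v in correct.items() if v}
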