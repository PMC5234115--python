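"""Identifiability of individuals from their skin microbiota.

Two measures of an OTU's identifying potential are provided:

- **Indicator value (IndVal):** for OTU o and individual i,
  specificity(o, i) is the mean relative abundance of o across i's
  body-site samples divided by the sum of that mean over all
  individuals, and fidelity(o, i) is the fraction of i's site samples
  containing o.  IndVal is their product, in [0, 1]; significance is
  assessed by permuting individual labels over site samples, with the
  add-one estimator p = (b + 1) / (B + 1), and non-significant values
  are masked to 0.

- **Minimal hitting sets:** a greedy cover that selects OTUs present in
  the target's profile (relative abundance >= ``detect_threshold``)
  that "resolve" confounders — other individuals whose abundance of the
  OTU falls below ``detect_threshold / demotion_factor`` — until every
  confounder is resolved.  A hitting set re-identifies a later profile
  when every member OTU is detected in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from microtrace.data_io import OtuTable, OtuTableError

__all__ = [
    "IndValEntry",
    "HittingSet",
    "indval",
    "skin_profiles",
    "build_hitting_set",
    "build_all_hitting_sets",
    "reidentify",
]

DETECT_THRESHOLD = 1e-3
DEMOTION_FACTOR = 2.0


@dataclass
class IndValEntry:
    otu: str
    individual: str
    season: int
    specificity: float
    fidelity: float
    indval: float
    p: float
    masked_value: float


@dataclass
class HittingSet:
    individual: str
    scope: str | None  # body site, or None for pooled sites
    otus: list[str]
    season: int
    status: str  # complete | partial | failed


def indval(
    table: OtuTable,
    meta: pd.DataFrame,
    season: int,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Indicator values of every OTU for every individual in one season.

    Uses the individual's skin site samples as replicates.  Returns a
    DataFrame with columns otu, individual, season, specificity,
    fidelity, indval, p, masked_value.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    skins = meta[(meta["type"] == "skin") & (meta["season"] == season)]
    individuals = sorted(skins["individual"].unique())
    if len(individuals) < 2:
        raise OtuTableError("IndVal needs skin samples for at least two individuals")
    rel = table.subset_samples(list(skins.index)).to_relative()
    X = rel.data.to_numpy()
    labels = skins["individual"].to_numpy()
    groups = np.array([individuals.index(l) for l in labels])
    n_groups = len(individuals)
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    if (counts == 0).any():
        raise OtuTableError("individual with zero site samples")

    def _indval_matrix(grp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        H = np.zeros((n_groups, len(grp)))
        H[grp, np.arange(len(grp))] = 1.0
        means = (H @ X) / counts[:, None]
        colsum = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            spec = np.where(colsum > 0, means / colsum, 0.0)
        fid = (H @ (X > 0)) / counts[:, None]
        return spec, fid, spec * fid

    spec, fid, iv = _indval_matrix(groups)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(iv)
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        _, _, iv_perm = _indval_matrix(perm)
        exceed += iv_perm >= iv - 1e-12
    p = (exceed + 1.0) / (n_permutations + 1.0)

    rows = []
    otus = rel.otu_ids
    for g, ind in enumerate(individuals):
        for k, otu in enumerate(otus):
            rows.append(
                dict(
                    otu=otu,
                    individual=ind,
                    season=int(season),
                    specificity=float(spec[g, k]),
                    fidelity=float(fid[g, k]),
                    indval=float(iv[g, k]),
                    p=float(p[g, k]),
                    masked_value=float(iv[g, k]) if p[g, k] < alpha else 0.0,
                )
            )
    return pd.DataFrame(rows)


def skin_profiles(
    table: OtuTable,
    meta: pd.DataFrame,
    season: int,
    site: str | None = None,
) -> dict[str, pd.Series]:
    """Per-individual relative-abundance profiles for one season.

    With ``site`` given, each profile is that single site sample; with
    ``site=None``, profiles are the mean relative abundance across the
    individual's sites (pooled mode).
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    skins = meta[(meta["type"] == "skin") & (meta["season"] == season)]
    if site is not None:
        skins = skins[skins["site"] == site]
    rel = table.subset_samples(list(skins.index)).to_relative()
    profiles = {}
    for ind, grp in skins.groupby("individual"):
        profiles[str(ind)] = rel.data.loc[grp.index].mean(axis=0)
    return profiles


def build_hitting_set(
    profiles: dict[str, pd.Series],
    target: str,
    season: int = 0,
    scope: str | None = None,
    detect_threshold: float = DETECT_THRESHOLD,
    demotion_factor: float = DEMOTION_FACTOR,
) -> HittingSet:
    """Greedy minimal hitting set distinguishing `target` from all others.

    A candidate OTU must be detected in the target (abundance >=
    ``detect_threshold``); it resolves confounder j when j's abundance is
    below ``detect_threshold / demotion_factor``.  The candidate
    resolving the most unresolved confounders is added repeatedly (ties
    broken by higher target abundance, then lexicographic OTU id).
    Status is ``failed`` when no candidate resolves any remaining
    confounder before any OTU is chosen, ``partial`` when coverage
    stalls with some confounders resolved, ``complete`` otherwise.
    """
    if target not in profiles:
        raise OtuTableError(f"target {target!r} not in profiles")
    if len(profiles) < 2:
        raise OtuTableError("need at least two individuals")
    others = sorted(k for k in profiles if k != target)
    tgt = profiles[target]
    candidates = sorted(tgt.index[tgt >= detect_threshold])
    absent_cut = detect_threshold / demotion_factor
    resolves = {
        o: {j for j in others if profiles[j].get(o, 0.0) < absent_cut} for o in candidates
    }
    unresolved = set(others)
    chosen: list[str] = []
    chosen_set: set[str] = set()
    while unresolved:
        best_otu, best_key = None, (0, -np.inf)
        for o in candidates:  # lexicographic order; strict > keeps the first of ties
            if o in chosen_set:
                continue
            key = (len(resolves[o] & unresolved), float(tgt[o]))
            if key[0] > 0 and key > best_key:
                best_otu, best_key = o, key
        if best_otu is None:
            status = "failed" if not chosen else "partial"
            return HittingSet(target, scope, chosen, int(season), status)
        chosen.append(best_otu)
        chosen_set.add(best_otu)
        unresolved -= resolves[best_otu]
    return HittingSet(target, scope, chosen, int(season), "complete")


def build_all_hitting_sets(
    table: OtuTable,
    meta: pd.DataFrame,
    season: int,
    per_site: bool = True,
    detect_threshold: float = DETECT_THRESHOLD,
    demotion_factor: float = DEMOTION_FACTOR,
) -> list[HittingSet]:
    """Hitting sets for every individual, per body site or pooled."""
    meta_sub = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    skins = meta_sub[(meta_sub["type"] == "skin") & (meta_sub["season"] == season)]
    sites = sorted(skins["site"].unique()) if per_site else [None]
    sets = []
    for site in sites:
        profiles = skin_profiles(table, meta, season, site=site)
        for ind in sorted(profiles):
            sets.append(
                build_hitting_set(
                    profiles,
                    ind,
                    season=season,
                    scope=site,
                    detect_threshold=detect_threshold,
                    demotion_factor=demotion_factor,
                )
            )
    return sets


def reidentify(
    sets: list[HittingSet],
    table: OtuTable,
    meta: pd.DataFrame,
    season: int,
    detect_threshold: float = DETECT_THRESHOLD,
) -> pd.DataFrame:
    """Attempt re-identification with previously built hitting sets.

    A set matches an individual's season profile when *every* member OTU
    is present at >= ``detect_threshold``.  Returns one row per usable
    (complete) set with columns individual, scope, true_positive,
    false_negative, false_positives (count of non-owners matched).
    """
    rows = []
    profile_cache: dict[str | None, dict[str, pd.Series]] = {}
    for hs in sets:
        if hs.status != "complete":
            continue
        if hs.scope not in profile_cache:
            profile_cache[hs.scope] = skin_profiles(table, meta, season, site=hs.scope)
        profiles = profile_cache[hs.scope]
        matches = {
            ind: all(prof.get(o, 0.0) >= detect_threshold for o in hs.otus)
            for ind, prof in profiles.items()
        }
        tp = bool(matches.get(hs.individual, False))
        fp = sum(1 for ind, m in matches.items() if m and ind != hs.individual)
        rows.append(
            dict(
                individual=hs.individual,
                scope=hs.scope,
                true_positive=tp,
                false_negative=not tp,
                false_positives=int(fp),
            )
        )
    return pd.DataFrame(rows)
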