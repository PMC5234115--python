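"""Seasonal first-observation mapping and OTU persistence statistics.

Within each context — a (individual, body site) for skin, a
(residence, surface site) for surfaces — every OTU is mapped to the
first season in which it was observed there.  Each sample's community
can then be decomposed by first-observed season, either by richness
(fraction of its OTUs) or by abundance (fraction of its reads), giving
the seasonal-origin profile of stable versus newly arrived OTUs.
Persistence is counted as the number of distinct seasons in which an
OTU was observed in its context; gaps do not reset the count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from microtrace.data_io import OtuTable, OtuTableError

__all__ = [
    "context_key",
    "first_observation_map",
    "seasonal_origin_fractions",
    "seasons_observed",
    "persistence_share",
]


def context_key(row: pd.Series) -> tuple:
    """Persistence context of a sample: (kind, key...).

    Skin samples belong to (individual, site); surface samples to
    (residence, site).  Air and control samples have no persistence
    context.
    """
    if row["type"] == "skin":
        return ("skin", row["individual"], row["site"])
    if row["type"] == "surface":
        return ("surface", row["residence"], row["site"])
    raise OtuTableError(f"no persistence context for sample type {row['type']!r}")


def _context_samples(meta: pd.DataFrame) -> dict[tuple, pd.DataFrame]:
    sub = meta[meta["type"].isin(["skin", "surface"])]
    return {
        ctx: grp
        for ctx, grp in sub.groupby(sub.apply(context_key, axis=1), sort=True)
    }


def first_observation_map(table: OtuTable, meta: pd.DataFrame) -> dict[tuple, dict[str, int]]:
    """Map context -> {OTU -> first season observed (count > 0)}.

    OTUs never observed within a context are absent from its map.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    out: dict[tuple, dict[str, int]] = {}
    cols = np.asarray(table.otu_ids)
    for ctx, grp in _context_samples(meta).items():
        first: dict[str, int] = {}
        for season in sorted(grp["season"].astype(int).unique()):
            sids = grp.index[grp["season"] == season]
            present = (table.data.loc[sids].to_numpy() > 0).any(axis=0)
            for otu in cols[present]:
                if otu not in first:
                    first[otu] = int(season)
        out[ctx] = first
    return out


def seasonal_origin_fractions(
    table: OtuTable,
    meta: pd.DataFrame,
    weighting: str = "richness",
    first_map: dict | None = None,
) -> pd.DataFrame:
    """Per-sample fractions of OTUs (or reads) by first-observed season.

    Returns a DataFrame indexed by sample id with one column per season;
    each non-empty sample's row sums to 1.  ``weighting="richness"``
    counts OTUs, ``"abundance"`` weights by reads.
    """
    if weighting not in ("richness", "abundance"):
        raise OtuTableError(f"unknown weighting {weighting!r}")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    if first_map is None:
        first_map = first_observation_map(table, meta)
    seasons = sorted(meta["season"].dropna().astype(int).unique())
    rows = {}
    for ctx, grp in _context_samples(meta).items():
        first = first_map.get(ctx, {})
        for sid in grp.index:
            counts = table.data.loc[sid]
            present = counts[counts > 0]
            frac = dict.fromkeys(seasons, 0.0)
            if len(present):
                weights = (
                    pd.Series(1.0, index=present.index)
                    if weighting == "richness"
                    else present.astype(float)
                )
                total = weights.sum()
                for otu, w in weights.items():
                    frac[first[otu]] += w / total
            rows[sid] = frac
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=seasons)
    out.index.name = "sample_id"
    return out


def seasons_observed(table: OtuTable, meta: pd.DataFrame) -> dict[tuple, pd.Series]:
    """Per context: Series OTU -> number of distinct seasons observed."""
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    out: dict[tuple, pd.Series] = {}
    for ctx, grp in _context_samples(meta).items():
        counts: dict[str, int] = {}
        cols = np.asarray(table.otu_ids)
        for season in sorted(grp["season"].astype(int).unique()):
            sids = grp.index[grp["season"] == season]
            present = (table.data.loc[sids].to_numpy() > 0).any(axis=0)
            for otu in cols[present]:
                counts[otu] = counts.get(otu, 0) + 1
        out[ctx] = pd.Series(counts, dtype=int)
    return out


def persistence_share(
    table: OtuTable,
    meta: pd.DataFrame,
    min_seasons: int = 2,
) -> pd.Series:
    """Per-sample relative-abundance share of OTUs persisting >= min_seasons.

    Persistence is evaluated within the sample's own context.  Shares
    are in [0, 1]; empty samples get 0.
    """
    if min_seasons < 1:
        raise OtuTableError("min_seasons must be >= 1")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    observed = seasons_observed(table, meta)
    shares = {}
    for ctx, grp in _context_samples(meta).items():
        n_seasons = observed[ctx]
        persistent = set(n_seasons.index[n_seasons >= min_seasons])
        for sid in grp.index:
            counts = table.data.loc[sid]
            total = counts.sum()
            if total == 0:
                shares[sid] = 0.0
            else:
                member = counts.index.isin(persistent)
                shares[sid] = float(counts[member].sum() / total)
    return pd.Series(shares, name="persistence_share")
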