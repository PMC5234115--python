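"""Seeded generator of multi-season household microbiome studies.

Emulates a longitudinal indoor-microbiome study design: a cohort of
residences, each with one or more occupants, sampled over consecutive
ordered seasons at several skin sites per occupant, surface sites and air
sites per residence, plus sequencing kit controls.  Every latent choice —
which OTUs belong to whom, when a skin OTU was deposited on which
surface, which OTUs were lost between seasons — is recorded in a
:class:`SyntheticTruth` so downstream analyses can be scored against a
known answer.

Community model
---------------
OTUs fall into six classes:

``core``
    always present on one occupant's skin, every season;
``shared``
    household OTUs present on every occupant of one residence;
``transient``
    appear on one occupant in a given season and survive each following
    season with probability ``skin_retention_prob``;
``identifying``
    private to a single occupant (the forensic signal); transient
    dynamics by default, drawn at low-to-mid abundance;
``environment``
    outdoor/indoor environmental OTUs, split between an air pool (seen
    in air samples and contributing to surfaces) and a residual pool
    (surface-only noise, the "unknown" source);
``contaminant``
    reagent OTUs dominating kit-control samples.

Per-OTU base abundances are log-normal, shared across seasons, with
per-season multiplicative log-normal noise; observed counts are
multinomial at a per-sample depth drawn uniformly from
``read_depth_range``.  A surface community is a three-way mixture of
pooled occupant skin (restricted to OTUs whose skin->surface deposition
Bernoulli trial has succeeded by that season, with per-season surface
retention applied), the residence's air pool, and residual noise, with
weights ``mix_weights``.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from microtrace.data_io import OtuTable, validate_metadata, write_otu_table, write_metadata, write_tree

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_study",
    "degrade_over_seasons",
    "random_coalescent_tree",
    "write_study",
]

DEFAULT_SKIN_SITES = ["forehead", "left_forearm", "left_palm", "right_forearm", "right_palm"]
DEFAULT_SURFACE_SITES = [
    "bed_headboard",
    "blanket",
    "fridge_seal",
    "kitchen_ventilator",
    "remote_control",
    "shower_curtain",
    "toilet_button",
    "tv_screen",
]
DEFAULT_AIR_SITES = ["bedroom", "kitchen", "living_room", "toilet"]

# family labels attached to generated OTUs, cycled per class; purely
# cosmetic but lets taxonomy-level summaries run on synthetic data
_SKIN_FAMILIES = [
    "Moraxellaceae",
    "Staphylococcaceae",
    "Micrococcaceae",
    "Corynebacteriaceae",
    "Streptococcaceae",
]
_ENV_FAMILIES = [
    "Sphingomonadaceae",
    "Methylobacteriaceae",
    "Pseudomonadaceae",
    "Rhodobacteraceae",
    "Xanthomonadaceae",
]
_CONTAM_FAMILIES = ["Bradyrhizobiaceae", "Comamonadaceae"]


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class GeneratorConfig:
    """Study design and community parameters for :func:`generate_study`.

    Defaults mirror a nine-residence, 19-occupant, four-season cohort with
    five skin sites per occupant, eight surface and four air sites per
    residence, and nine kit controls.
    """

    n_residences: int = 9
    occupants_per_residence: list[int] = field(
        default_factory=lambda: [1, 1, 2, 2, 2, 2, 3, 3, 3]
    )
    n_seasons: int = 4
    skin_sites: list[str] = field(default_factory=lambda: list(DEFAULT_SKIN_SITES))
    surface_sites: list[str] = field(default_factory=lambda: list(DEFAULT_SURFACE_SITES))
    air_sites: list[str] = field(default_factory=lambda: list(DEFAULT_AIR_SITES))
    n_controls: int = 9
    read_depth_range: tuple[int, int] = (1500, 5000)
    n_common_core_otus: int = 40
    n_core_otus_per_individual: int = 6
    n_shared_household_otus: int = 8
    n_transient_otus_per_season: int = 12
    n_identifying_otus_per_individual: int = 4
    n_environment_otus: int = 90
    n_contaminant_otus: int = 8
    skin_retention_prob: float = 0.6
    surface_retention_prob: float = 0.4
    deposition_prob_base: float = 1.0
    deposition_abundance_exponent: float = 0.05
    control_background_fraction: float = 0.1
    mix_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    abundance_lognormal_params: tuple[float, float] = (0.0, 1.0)
    site_presence_prob: float = 0.9
    season_noise_sigma: float = 0.25
    identifying_abundance_factor: float = 0.5
    common_core_abundance_factor: float = 2.0
    env_seasonal_fraction: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.occupants_per_residence) != self.n_residences:
            raise ConfigurationError(
                "occupants_per_residence length must equal n_residences"
            )
        if any(n < 1 for n in self.occupants_per_residence):
            raise ConfigurationError("each residence needs at least one occupant")
        if self.n_seasons < 2:
            raise ConfigurationError("need at least two ordered seasons")
        for name in ("skin_sites", "surface_sites", "air_sites"):
            if not getattr(self, name):
                raise ConfigurationError(f"{name} must be non-empty")
        dmin, dmax = self.read_depth_range
        if dmin > dmax or dmin < 1:
            raise ConfigurationError("invalid read_depth_range")
        for name in (
            "skin_retention_prob",
            "surface_retention_prob",
            "deposition_prob_base",
            "site_presence_prob",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if abs(sum(self.mix_weights) - 1.0) > 1e-9 or any(w < 0 for w in self.mix_weights):
            raise ConfigurationError("mix_weights must be non-negative and sum to 1")
        if self.n_environment_otus < 2:
            raise ConfigurationError("need at least 2 environment OTUs (air + residual pools)")
        if self.n_contaminant_otus < 1:
            raise ConfigurationError("need at least 1 contaminant OTU")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator.

    Attributes
    ----------
    otu_class:
        OTU id -> one of {core, shared, transient, identifying,
        environment, contaminant}.
    otu_owner:
        identifying OTU id -> owning individual.
    mixing:
        surface sample id -> realised mixture proportions over
        {"skin", "air", "residual"}.
    deposition_schedule:
        (otu, residence, surface site, season) tuples recording the season
        a skin OTU first became resident on that surface.
    loss_schedule:
        (otu, context, season) tuples recording the first season an OTU
        was absent after presence, where context is
        ``"skin:<individual>"`` or ``"surface:<residence>:<site>"``.
    skin_presence:
        (individual, season) -> frozenset of OTUs latently present on
        that individual's skin.
    surface_resident:
        (residence, site, season) -> frozenset of deposited skin OTUs
        resident on the surface that season.
    air_otus, residual_otus:
        the two environment sub-pools.
    """

    otu_class: dict[str, str]
    otu_owner: dict[str, str]
    mixing: dict[str, dict[str, float]]
    deposition_schedule: set[tuple[str, str, str, int]]
    loss_schedule: set[tuple[str, str, int]]
    skin_presence: dict[tuple[str, int], frozenset]
    surface_resident: dict[tuple[str, str, int], frozenset]
    air_otus: frozenset
    residual_otus: frozenset
    env_season: dict[str, int | None] = field(default_factory=dict)

    def individuals(self) -> list[str]:
        return sorted(set(self.otu_owner.values()))

    def to_json(self) -> str:
        payload = {
            "otu_class": self.otu_class,
            "otu_owner": self.otu_owner,
            "mixing": self.mixing,
            "deposition_schedule": sorted(map(list, self.deposition_schedule)),
            "loss_schedule": sorted(map(list, self.loss_schedule)),
            "skin_presence": {
                f"{ind}|{season}": sorted(v) for (ind, season), v in self.skin_presence.items()
            },
            "surface_resident": {
                f"{res}|{site}|{season}": sorted(v)
                for (res, site, season), v in self.surface_resident.items()
            },
            "air_otus": sorted(self.air_otus),
            "residual_otus": sorted(self.residual_otus),
            "env_season": self.env_season,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _residence_labels(n: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n)]


def _individual_labels(residences: list[str], occupants: list[int]) -> dict[str, list[str]]:
    letters = string.ascii_lowercase
    return {
        res: [f"{res}{letters[k]}" for k in range(n)] for res, n in zip(residences, occupants)
    }


def random_coalescent_tree(leaf_names: list[str], rng: np.random.Generator) -> TreeNode:
    """Random binary topology by successive pairwise joins, exp(1) branch lengths."""
    if not leaf_names:
        raise ConfigurationError("tree needs at least one leaf")
    nodes = [TreeNode(name=name, length=float(rng.exponential(1.0))) for name in leaf_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_study(config: GeneratorConfig):
    """Generate one full study: (OtuTable, metadata, tree, SyntheticTruth).

    One sample per (context, season) design cell: every (individual, skin
    site, season), (residence, surface site, season) and (residence, air
    site, season), plus ``n_controls`` seasonless kit controls.  All
    randomness is driven by ``config.rng_seed``; the same config yields a
    bit-identical study.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    residences = _residence_labels(config.n_residences)
    individuals_by_res = _individual_labels(residences, config.occupants_per_residence)
    all_individuals = [i for res in residences for i in individuals_by_res[res]]
    seasons = list(range(1, config.n_seasons + 1))

    # ---- OTU inventory -------------------------------------------------
    otu_class: dict[str, str] = {}
    otu_owner: dict[str, str] = {}
    otu_family: dict[str, str] = {}
    counter = 0

    def _new(n: int, cls: str, families: list[str]) -> list[str]:
        nonlocal counter
        ids = []
        for _ in range(n):
            oid = f"OTU_{counter:05d}"
            counter += 1
            otu_class[oid] = cls
            otu_family[oid] = families[counter % len(families)]
            ids.append(oid)
        return ids

    # a common human-skin core shared by every individual: the bulk of skin
    # mass carries no household signal, mirroring real skin communities
    common_core = _new(config.n_common_core_otus, "core", _SKIN_FAMILIES)
    core: dict[str, list[str]] = {}
    identifying: dict[str, list[str]] = {}
    transient: dict[tuple[str, int], list[str]] = {}
    for ind in all_individuals:
        core[ind] = common_core + _new(
            config.n_core_otus_per_individual, "core", _SKIN_FAMILIES
        )
        ids = _new(config.n_identifying_otus_per_individual, "identifying", _SKIN_FAMILIES)
        identifying[ind] = ids
        for oid in ids:
            otu_owner[oid] = ind
        for s in seasons:
            transient[(ind, s)] = _new(
                config.n_transient_otus_per_season, "transient", _SKIN_FAMILIES
            )
    shared: dict[str, list[str]] = {
        res: _new(config.n_shared_household_otus, "shared", _SKIN_FAMILIES)
        for res in residences
    }
    environment = _new(config.n_environment_otus, "environment", _ENV_FAMILIES)
    n_air_pool = max(1, (2 * len(environment)) // 3)
    air_pool = environment[:n_air_pool]
    residual_pool = environment[n_air_pool:] or environment[:1]
    # outdoor input is partly seasonal: a fraction of each environment pool
    # is present in a single season only (round-robin), the rest year-round
    env_season: dict[str, int | None] = {o: None for o in environment}
    for pool in (air_pool, residual_pool):
        n_seasonal = int(round(config.env_seasonal_fraction * len(pool)))
        for k, oid in enumerate(pool[:n_seasonal]):
            env_season[oid] = seasons[k % len(seasons)]
    contaminants = _new(config.n_contaminant_otus, "contaminant", _CONTAM_FAMILIES)
    otu_ids = sorted(otu_class)

    # ---- abundances ----------------------------------------------------
    mu, sigma = config.abundance_lognormal_params
    base = pd.Series(rng.lognormal(mu, sigma, size=len(otu_ids)), index=otu_ids)
    base[common_core] *= config.common_core_abundance_factor
    for ind in all_individuals:
        base[identifying[ind]] *= config.identifying_abundance_factor
    season_noise = {
        s: pd.Series(
            rng.lognormal(0.0, config.season_noise_sigma, size=len(otu_ids)), index=otu_ids
        )
        for s in seasons
    }

    # fixed per-(individual, OTU, site) site affiliation mask
    site_mask: dict[tuple[str, str], np.ndarray] = {}
    for ind in all_individuals:
        pool = core[ind] + identifying[ind] + [
            o for s in seasons for o in transient[(ind, s)]
        ]
        for oid in pool:
            mask = rng.random(len(config.skin_sites)) < config.site_presence_prob
            if not mask.any():
                mask[int(rng.integers(len(config.skin_sites)))] = True
            site_mask[(ind, oid)] = mask

    # ---- latent skin presence per (individual, season) ----------------
    skin_presence: dict[tuple[str, int], frozenset] = {}
    loss_schedule: set[tuple[str, str, int]] = set()
    for res in residences:
        for ind in individuals_by_res[res]:
            alive: set[str] = set()
            for s in seasons:
                if s == seasons[0]:
                    alive = set(identifying[ind]) | set(transient[(ind, s)])
                else:
                    survivors = {
                        o for o in sorted(alive) if rng.random() < config.skin_retention_prob
                    }
                    for o in alive - survivors:
                        loss_schedule.add((o, f"skin:{ind}", s))
                    alive = survivors | set(transient[(ind, s)])
                present = set(core[ind]) | set(shared[res]) | alive
                skin_presence[(ind, s)] = frozenset(present)

    # ---- surface deposition dynamics -----------------------------------
    col_index = pd.Index(otu_ids)

    def _skin_pool_vector(res: str, s: int) -> pd.Series:
        # current-season occupant communities: surfaces mirror the same
        # seasonal abundance realisation the skin samples are drawn from
        vec = pd.Series(0.0, index=col_index)
        for ind in individuals_by_res[res]:
            present = list(skin_presence[(ind, s)])
            vec[present] += (base[present] * season_noise[s][present]).to_numpy()
        return vec

    surface_resident: dict[tuple[str, str, int], frozenset] = {}
    deposition_schedule: set[tuple[str, str, str, int]] = set()
    skin_pool_by_rs: dict[tuple[str, int], pd.Series] = {}
    for res in residences:
        for s in seasons:
            skin_pool_by_rs[(res, s)] = _skin_pool_vector(res, s)
        for site in config.surface_sites:
            resident: set[str] = set()
            for s in seasons:
                if s > seasons[0]:
                    survivors = {
                        o
                        for o in sorted(resident)
                        if rng.random() < config.surface_retention_prob
                    }
                    for o in resident - survivors:
                        loss_schedule.add((o, f"surface:{res}:{site}", s))
                    resident = survivors
                pool = skin_pool_by_rs[(res, s)]
                total = pool.sum()
                for oid in sorted(pool.index[pool > 0]):
                    if oid in resident:
                        continue
                    rel = pool[oid] / total
                    p = config.deposition_prob_base * rel**config.deposition_abundance_exponent
                    if rng.random() < min(1.0, p):
                        resident.add(oid)
                        deposition_schedule.add((oid, res, site, s))
                surface_resident[(res, site, s)] = frozenset(resident)

    # ---- assemble samples ----------------------------------------------
    dmin, dmax = config.read_depth_range
    sample_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    mixing: dict[str, dict[str, float]] = {}

    def _multinomial(weights: pd.Series, depth: int) -> np.ndarray:
        w = weights.to_numpy(dtype=float)
        total = w.sum()
        if total <= 0:
            return np.zeros(len(w), dtype=np.int64)
        return rng.multinomial(depth, w / total)

    for s in seasons:
        for res in residences:
            for ind in individuals_by_res[res]:
                present = skin_presence[(ind, s)]
                for k, site in enumerate(config.skin_sites):
                    weights = pd.Series(0.0, index=col_index)
                    for oid in present:
                        mask = site_mask.get((ind, oid))
                        if mask is None or mask[k]:
                            weights[oid] = base[oid] * season_noise[s][oid]
                    depth = int(rng.integers(dmin, dmax + 1))
                    sample_ids.append(f"skin.{ind}.{site}.s{s}")
                    sample_rows.append(_multinomial(weights, depth))
                    meta_rows.append(
                        dict(type="skin", residence=res, site=site, individual=ind, season=s)
                    )
            air_active = [o for o in air_pool if env_season[o] is None or env_season[o] == s]
            air_weights = pd.Series(0.0, index=col_index)
            air_weights[air_active] = (
                base[air_active] * season_noise[s][air_active]
            ).to_numpy()
            for site in config.air_sites:
                depth = int(rng.integers(dmin, dmax + 1))
                sample_ids.append(f"air.{res}.{site}.s{s}")
                sample_rows.append(_multinomial(air_weights, depth))
                meta_rows.append(
                    dict(type="air", residence=res, site=site, individual=None, season=s)
                )
            resid_active = [
                o for o in residual_pool if env_season[o] is None or env_season[o] == s
            ]
            resid_weights = pd.Series(0.0, index=col_index)
            resid_weights[resid_active] = (
                base[resid_active] * season_noise[s][resid_active]
            ).to_numpy()
            for site in config.surface_sites:
                skin_w = skin_pool_by_rs[(res, s)].copy()
                resident = surface_resident[(res, site, s)]
                skin_w[~skin_w.index.isin(resident)] = 0.0
                components = {"skin": skin_w, "air": air_weights, "residual": resid_weights}
                w_skin, w_air, w_resid = config.mix_weights
                raw = {"skin": w_skin, "air": w_air, "residual": w_resid}
                active = {k: v for k, v in raw.items() if v > 0 and components[k].sum() > 0}
                norm = sum(active.values())
                mix = pd.Series(0.0, index=col_index)
                realised = {"skin": 0.0, "air": 0.0, "residual": 0.0}
                for k, wk in active.items():
                    comp = components[k]
                    mix += (wk / norm) * comp / comp.sum()
                    realised[k] = wk / norm
                depth = int(rng.integers(dmin, dmax + 1))
                sid = f"surface.{res}.{site}.s{s}"
                sample_ids.append(sid)
                sample_rows.append(_multinomial(mix, depth))
                meta_rows.append(
                    dict(type="surface", residence=res, site=site, individual=None, season=s)
                )
                mixing[sid] = realised

    # kit controls: reagent contaminants dominate, plus a thin background of
    # real-community OTUs (well-to-well leakage) so controls keep a few reads
    # after the contaminant filter and can serve as a negative-control source
    contam_weights = pd.Series(0.0, index=col_index)
    contam_share = rng.lognormal(0.0, 0.3, size=len(contaminants))
    contam_weights[contaminants] = (
        (1 - config.control_background_fraction) * contam_share / contam_share.sum()
    )
    background = environment + [o for res in residences for o in shared[res]]
    if background and config.control_background_fraction > 0:
        bg_share = base[background].to_numpy()
        contam_weights[background] = (
            config.control_background_fraction * bg_share / bg_share.sum()
        )
    for k in range(config.n_controls):
        depth = int(rng.integers(dmin, dmax + 1))
        sample_ids.append(f"control.k{k + 1}")
        sample_rows.append(_multinomial(contam_weights, depth))
        meta_rows.append(
            dict(type="control", residence=None, site=None, individual=None, season=None)
        )

    table = OtuTable(
        pd.DataFrame(np.asarray(sample_rows, dtype=np.int64), index=sample_ids, columns=otu_ids),
        mode="counts",
        taxonomy={
            o: f"k__Bacteria;p__;c__;o__;f__{otu_family[o]};g__" for o in otu_ids
        },
    )
    meta = validate_metadata(pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id")))
    tree = random_coalescent_tree(otu_ids, rng)
    truth = SyntheticTruth(
        otu_class=otu_class,
        otu_owner=otu_owner,
        mixing=mixing,
        deposition_schedule=deposition_schedule,
        loss_schedule=loss_schedule,
        skin_presence=skin_presence,
        surface_resident=surface_resident,
        air_otus=frozenset(air_pool),
        residual_otus=frozenset(residual_pool),
        env_season=env_season,
    )
    return table, meta, tree, truth


def degrade_over_seasons(
    truth: SyntheticTruth,
    table: OtuTable,
    meta: pd.DataFrame,
    retention: float,
    seed: int = 0,
) -> OtuTable:
    """Apply an extra season-to-season survival filter to non-core OTUs.

    Within each context (skin: individual; surface/air: residence + site),
    an OTU observed in season s survives to season s+1 with probability
    ``retention``, independently per context; core OTUs always survive.
    Killed cells are zeroed and each affected sample is re-normalised to
    its original depth by multinomial redistribution over surviving OTUs.
    """
    if not 0 <= retention <= 1:
        raise ConfigurationError("retention must be in [0, 1]")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    noncontrol = meta[meta["type"] != "control"]

    def _context(row) -> tuple:
        if row["type"] == "skin":
            return ("skin", row["individual"], row["site"])
        return (row["type"], row["residence"], row["site"])

    contexts: dict[tuple, dict[int, list[str]]] = {}
    for sid, row in noncontrol.iterrows():
        contexts.setdefault(_context(row), {}).setdefault(int(row["season"]), []).append(sid)

    core_otus = {o for o, c in truth.otu_class.items() if c == "core"}
    cols = data.columns
    changed: set[str] = set()
    for ctx in sorted(contexts, key=str):
        by_season = contexts[ctx]
        seasons = sorted(by_season)
        prev_present: np.ndarray | None = None
        for s in seasons:
            sids = by_season[s]
            block = data.loc[sids]
            present = (block.to_numpy() > 0).any(axis=0)
            if prev_present is not None:
                at_risk = present & prev_present & ~cols.isin(core_otus)
                kill = at_risk & (rng.random(len(cols)) >= retention)
                if kill.any():
                    data.loc[sids, cols[kill]] = 0
                    changed.update(sids)
                    present = present & ~kill
            prev_present = present

    for sid in sorted(changed):
        counts = data.loc[sid].to_numpy(dtype=float)
        orig_total = int(table.data.loc[sid].sum())
        remaining = counts.sum()
        if remaining > 0 and orig_total > 0:
            data.loc[sid] = rng.multinomial(orig_total, counts / remaining)
    return OtuTable(data, "counts", table.taxonomy)


def write_study(out_dir, table: OtuTable, meta: pd.DataFrame, tree: TreeNode, truth: SyntheticTruth) -> None:
    """Write table/metadata/tree/truth to a directory as TSV, newick and JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_otu_table(table, out / "otu_table.tsv")
    write_metadata(meta, out / "metadata.tsv")
    write_tree(tree, out / "tree.nwk")
    (out / "truth.json").write_text(truth.to_json())
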