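"""Counting-format event tables and Cox proportional-hazards models.

Each (OTU, context) pair is a survival subject.  Its observation period
starts in the season the OTU was first observed in that context and is
encoded as a sequence of (start, stop] season-transition intervals with
time-dependent covariates evaluated at the interval's start season:

- **abundance bin** — percentile rank of the OTU's relative abundance
  among OTUs present in the context that season, binned as 0-69th,
  70-89th, 90-98th and 99th percentiles (absent interim seasons take the
  lowest bin);
- **indicator-value bin** — the OTU's (masked) IndVal for the modelled
  occupant, binned 0-0.2, 0.2-0.6, 0.6-0.9, 0.9-1 (surfaces use the
  maximum over the residence's occupants);
- **hitting-set membership** — fixed at the subject's first-observed
  season (surfaces: membership of any occupant's hitting set).

A *loss* event is placed on the transition out of the last observed
season (interim absences are not losses); subjects observed in the final
season are right-censored.  A *deposition* event is the first
observation of a skin OTU on any household surface of the residence in
the same or a later season as its first skin observation; OTUs seen on a
surface before any occupant's skin are excluded.

The fitter maximises the counting-process partial likelihood with the
Efron correction for tied event times by Newton-Raphson, and reports
hazard ratios with Wald (normal-approximation) confidence intervals and
two-tailed p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from microtrace.data_io import OtuTable, OtuTableError

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "ABUNDANCE_BIN_LABELS",
    "INDVAL_BIN_LABELS",
    "abundance_bins",
    "indval_bin",
    "build_loss_records",
    "build_deposition_records",
    "cox_ph",
    "cox_fit",
    "hazard_report",
]

ABUNDANCE_BIN_LABELS = ["p0_69", "p70_89", "p90_98", "p99"]
INDVAL_BIN_LABELS = ["v0_02", "v02_06", "v06_09", "v09_1"]

COVARIATE_COLUMNS = [
    "abund_p70_89",
    "abund_p90_98",
    "abund_p99",
    "indval_02_06",
    "indval_06_09",
    "indval_09_1",
    "hitting_set_member",
]


@dataclass
class SurvivalRecord:
    """One (start, stop] interval of one (OTU, context) subject."""

    subject: tuple
    start: int
    stop: int
    abundance_bin: int  # 0..3, index into ABUNDANCE_BIN_LABELS
    indval_bin: int  # 0..3, index into INDVAL_BIN_LABELS
    hitting_set_member: bool
    event: str  # none | loss | deposition
    indval_value: float = 0.0

    def __post_init__(self) -> None:
        if self.stop - self.start != 1:
            raise OtuTableError("intervals must span exactly one season transition")


@dataclass
class CoxFit:
    """Fitted proportional-hazards model summary."""

    summary: pd.DataFrame  # coef, se, hazard_ratio, ci_low, ci_high, z, p per covariate
    loglik: float
    n_subjects: int
    n_events: int
    n_intervals: int
    converged: bool
    unstable: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def abundance_bins(counts: pd.Series) -> pd.Series:
    """Percentile-rank abundance bins among present OTUs of one context-season.

    Returns bin index 0-3 for OTUs with positive counts; ranks use the
    mid-rank convention so ties share a percentile.
    """
    present = counts[counts > 0]
    if present.empty:
        return pd.Series(dtype=int)
    pct = 100.0 * present.rank(method="average") / len(present)
    bins = pd.cut(
        pct, bins=[0, 70, 90, 99, 100.0001], labels=False, right=False, include_lowest=True
    )
    return bins.astype(int)


def indval_bin(value: float) -> int:
    if value <= 0.2:
        return 0
    if value <= 0.6:
        return 1
    if value <= 0.9:
        return 2
    return 3


def _presence_by_context(table: OtuTable, meta: pd.DataFrame, kind: str):
    """Per-context season -> (sample ids, presence sets, count vectors)."""
    sub = meta[meta["type"] == kind]
    contexts: dict[tuple, dict[int, pd.Series]] = {}
    for sid, row in sub.iterrows():
        key = (
            (row["individual"], row["site"]) if kind == "skin" else (row["residence"], row["site"])
        )
        season = int(row["season"])
        counts = table.data.loc[sid]
        if key not in contexts:
            contexts[key] = {}
        if season in contexts[key]:
            contexts[key][season] = contexts[key][season] + counts
        else:
            contexts[key][season] = counts.copy()
    return contexts


def _indval_lookup(indval_tables: dict[int, pd.DataFrame] | None):
    """(season, individual, otu) -> masked IndVal, defaulting to 0."""
    table: dict[tuple, float] = {}
    if indval_tables:
        for season, df in indval_tables.items():
            for row in df.itertuples(index=False):
                table[(int(season), row.individual, row.otu)] = float(row.masked_value)
    return lambda season, ind, otu: table.get((season, ind, otu), 0.0)


def _hitting_set_members(hitting_sets: dict[int, list] | None):
    """(season, individual, site) -> set of member OTUs (site None matches all)."""
    members: dict[tuple, set] = {}
    if hitting_sets:
        for season, sets in hitting_sets.items():
            for hs in sets:
                members.setdefault((int(season), hs.individual, hs.scope), set()).update(hs.otus)

    def lookup(season: int, ind: str, site: str | None) -> set:
        out = set(members.get((season, ind, site), set()))
        out |= members.get((season, ind, None), set())
        return out

    return lookup


def build_loss_records(
    table: OtuTable,
    meta: pd.DataFrame,
    kind: str,
    indval_tables: dict[int, pd.DataFrame] | None = None,
    hitting_sets: dict[int, list] | None = None,
) -> list[SurvivalRecord]:
    """Counting-format loss records for skin or surface contexts.

    ``indval_tables`` maps season -> the output of
    :func:`microtrace.identify.indval`; ``hitting_sets`` maps season ->
    the output of :func:`microtrace.identify.build_all_hitting_sets`.
    Surface subjects are restricted to OTUs seen on at least one occupant
    skin sample of the residence (any season) and on the modelled surface
    (any season); their IndVal is the maximum over the residence's
    occupants and membership is of any occupant's hitting set.
    """
    if kind not in ("skin", "surface"):
        raise OtuTableError(f"loss records kind must be skin or surface, got {kind!r}")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    seasons = sorted(meta.loc[meta["type"] != "control", "season"].dropna().astype(int).unique())
    if seasons != list(range(min(seasons), max(seasons) + 1)):
        raise OtuTableError("seasons must be consecutive and ordered")
    final = max(seasons)
    iv = _indval_lookup(indval_tables)
    hs = _hitting_set_members(hitting_sets)
    contexts = _presence_by_context(table, meta, kind)

    occupants_by_res: dict[str, list[str]] = {}
    skin_otus_by_res: dict[str, set] = {}
    if kind == "surface":
        skins = meta[meta["type"] == "skin"]
        for res, grp in skins.groupby("residence"):
            occupants_by_res[res] = sorted(grp["individual"].unique())
            pres = (table.data.loc[grp.index].to_numpy() > 0).any(axis=0)
            skin_otus_by_res[res] = set(np.asarray(table.otu_ids)[pres])

    records: list[SurvivalRecord] = []
    for key in sorted(contexts):
        by_season = contexts[key]
        bins_by_season = {s: abundance_bins(c) for s, c in by_season.items()}
        present_by_season = {s: set(b.index) for s, b in bins_by_season.items()}
        all_otus = set().union(*present_by_season.values())
        if kind == "surface":
            res, site = key
            all_otus &= skin_otus_by_res.get(res, set())
        for otu in sorted(all_otus):
            obs = sorted(s for s in seasons if otu in present_by_season.get(s, set()))
            if not obs:
                continue
            first, last = obs[0], obs[-1]
            end = final if last == final else last + 1
            for s in range(first, end):
                abin = (
                    int(bins_by_season[s][otu]) if otu in present_by_season.get(s, set()) else 0
                )
                if kind == "skin":
                    ind, site = key
                    value = iv(s, ind, otu)
                    member = otu in hs(first, ind, site)
                else:
                    res, site = key
                    occ = occupants_by_res.get(res, [])
                    value = max((iv(s, i, otu) for i in occ), default=0.0)
                    member = any(otu in hs(first, i, None) or otu in hs(first, i, site) for i in occ)
                event = "loss" if (last != final and s == end - 1) else "none"
                records.append(
                    SurvivalRecord(
                        subject=(kind,) + key + (otu,),
                        start=s,
                        stop=s + 1,
                        abundance_bin=abin,
                        indval_bin=indval_bin(value),
                        hitting_set_member=bool(member),
                        event=event,
                        indval_value=value,
                    )
                )
    return records


def build_deposition_records(
    table: OtuTable,
    meta: pd.DataFrame,
    indval_tables: dict[int, pd.DataFrame] | None = None,
    hitting_sets: dict[int, list] | None = None,
) -> list[SurvivalRecord]:
    """Counting-format skin-to-surface deposition records.

    Subjects are (OTU, occupant body site) observations.  The event is
    the first observation of the OTU on any household surface of the
    subject's residence in the same or a later season as the subject's
    first skin observation; same-season depositions occupy the subject's
    first interval.  OTUs observed on any of the residence's surfaces
    before their first observation on any occupant's skin are excluded.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    seasons = sorted(meta.loc[meta["type"] != "control", "season"].dropna().astype(int).unique())
    final = max(seasons)
    iv = _indval_lookup(indval_tables)
    hs = _hitting_set_members(hitting_sets)
    skin_contexts = _presence_by_context(table, meta, "skin")

    skins = meta[meta["type"] == "skin"]
    residence_of = {ind: grp["residence"].iloc[0] for ind, grp in skins.groupby("individual")}

    # per residence: first surface season per OTU; first skin season (any occupant)
    surf_first: dict[str, dict[str, int]] = {}
    surfaces = meta[meta["type"] == "surface"]
    for res, grp in surfaces.groupby("residence"):
        first: dict[str, int] = {}
        for season in seasons:
            sids = grp.index[grp["season"] == season]
            if len(sids) == 0:
                continue
            pres = (table.data.loc[sids].to_numpy() > 0).any(axis=0)
            for otu in np.asarray(table.otu_ids)[pres]:
                first.setdefault(otu, season)
        surf_first[res] = first
    skin_first_any: dict[str, dict[str, int]] = {}
    for res, grp in skins.groupby("residence"):
        first = {}
        for season in seasons:
            sids = grp.index[grp["season"] == season]
            if len(sids) == 0:
                continue
            pres = (table.data.loc[sids].to_numpy() > 0).any(axis=0)
            for otu in np.asarray(table.otu_ids)[pres]:
                first.setdefault(otu, season)
        skin_first_any[res] = first

    records: list[SurvivalRecord] = []
    for key in sorted(skin_contexts):
        ind, site = key
        res = residence_of[ind]
        by_season = skin_contexts[key]
        bins_by_season = {s: abundance_bins(c) for s, c in by_season.items()}
        present_by_season = {s: set(b.index) for s, b in bins_by_season.items()}
        all_otus = set().union(*present_by_season.values())
        for otu in sorted(all_otus):
            obs = sorted(s for s in seasons if otu in present_by_season.get(s, set()))
            first = obs[0]
            sf = surf_first.get(res, {}).get(otu)
            if sf is not None and sf < skin_first_any[res].get(otu, first):
                continue  # surface-before-skin: cannot be attributed to deposition
            event_season = sf if (sf is not None and sf >= first) else None
            if event_season is None:
                stop_season = final  # censored
                intervals = range(first, stop_season)
            elif event_season == first:
                intervals = range(first, first + 1)
            else:
                intervals = range(first, event_season)
            for s in intervals:
                abin = (
                    int(bins_by_season[s][otu])
                    if otu in present_by_season.get(s, set())
                    else 0
                )
                value = iv(s, ind, otu)
                member = otu in hs(first, ind, site)
                if event_season is None:
                    event = "none"
                elif event_season == first:
                    event = "deposition"
                else:
                    event = "deposition" if s == event_season - 1 else "none"
                records.append(
                    SurvivalRecord(
                        subject=("deposition", ind, site, otu),
                        start=s,
                        stop=s + 1,
                        abundance_bin=abin,
                        indval_bin=indval_bin(value),
                        hitting_set_member=bool(member),
                        event=event,
                        indval_value=value,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Cox partial-likelihood fitter (counting process, Efron ties)
# ---------------------------------------------------------------------------

def _partial_likelihood_terms(start, stop, event, X):
    event_times = np.unique(stop[event])
    groups = []
    for t in event_times:
        dead = np.flatnonzero(event & (stop == t))
        risk = np.flatnonzero((start < t) & (t <= stop))
        groups.append((dead, risk))
    return groups


def cox_ph(
    start,
    stop,
    event,
    X,
    names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox model on counting-format intervals.

    ``start``/``stop``/``event`` are per-interval arrays; ``X`` the
    covariate matrix.  Tied event times are handled with the Efron
    correction by default (``ties="breslow"`` selects the cruder
    approximation).  Newton-Raphson with step-halving, converging when
    the gradient norm falls below ``tol``.  Covariate columns that never
    vary are dropped; near-separated coefficients (|coef| > 10) are
    flagged unstable with a warning.
    """
    if ties not in ("efron", "breslow"):
        raise OtuTableError(f"unknown tie handling {ties!r}")
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    if not event.any():
        raise OtuTableError("cannot fit a hazard model with zero events")

    keep = [j for j in range(p) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(p) if j not in keep]
    X = X[:, keep]
    kept_names = [names[j] for j in keep]
    p = len(keep)
    if p == 0:
        raise OtuTableError("no varying covariates")

    groups = _partial_likelihood_terms(start, stop, event, X)

    def evaluate(beta):
        eta = X @ beta
        w = np.exp(eta)
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for dead, risk in groups:
            d = len(dead)
            wr, wd = w[risk], w[dead]
            Xr, Xd = X[risk], X[dead]
            S_r, S_d = wr.sum(), wd.sum()
            a_r, a_d = Xr.T @ wr, Xd.T @ wd
            b_r = (Xr * wr[:, None]).T @ Xr
            b_d = (Xd * wd[:, None]).T @ Xd
            ll += eta[dead].sum()
            grad += Xd.sum(axis=0)
            for j in range(d):
                f = j / d if ties == "efron" else 0.0
                phi = S_r - f * S_d
                a = a_r - f * a_d
                b = b_r - f * b_d
                ll -= np.log(phi)
                grad -= a / phi
                mu = a / phi
                info += b / phi - np.outer(mu, mu)
        return ll, grad, info

    beta = np.zeros(p)
    ll, grad, info = evaluate(beta)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving on log-likelihood decrease
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_info = evaluate(new_beta)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
    else:
        if np.linalg.norm(grad) < tol:
            converged = True
    if not converged and np.linalg.norm(grad) > 1e-4:
        warnings.warn(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})",
            stacklevel=2,
        )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hazard_ratio": np.exp(beta),
                "ci_low": np.exp(beta - 1.96 * se),
                "ci_high": np.exp(beta + 1.96 * se),
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=pd.Index(kept_names, name="covariate"),
        )
    unstable = [nm for nm, b in zip(kept_names, beta) if abs(b) > 10]
    if unstable:
        warnings.warn(
            "possible complete separation; unstable coefficients: "
            + ", ".join(unstable),
            stacklevel=2,
        )
    n_subjects = n  # callers with repeated subjects should pass subject counts
    return CoxFit(
        summary=summary,
        loglik=float(ll),
        n_subjects=n_subjects,
        n_events=int(event.sum()),
        n_intervals=n,
        converged=bool(converged),
        unstable=unstable,
        dropped=dropped,
    )


def records_to_frame(records: list[SurvivalRecord], continuous_indval: bool = False) -> pd.DataFrame:
    """Expand records into a design frame with indicator covariates.

    Reference levels (lowest abundance bin, lowest IndVal bin,
    non-membership) are implicit by exclusion.
    """
    if not records:
        raise OtuTableError("no survival records")
    rows = []
    for r in records:
        row = {
            "subject": r.subject,
            "start": r.start,
            "stop": r.stop,
            "event": r.event != "none",
            "abund_p70_89": int(r.abundance_bin == 1),
            "abund_p90_98": int(r.abundance_bin == 2),
            "abund_p99": int(r.abundance_bin == 3),
            "indval_02_06": int(r.indval_bin == 1),
            "indval_06_09": int(r.indval_bin == 2),
            "indval_09_1": int(r.indval_bin == 3),
            "hitting_set_member": int(r.hitting_set_member),
        }
        if continuous_indval:
            row["indval_value"] = r.indval_value
        rows.append(row)
    return pd.DataFrame(rows)


def cox_fit(records: list[SurvivalRecord], continuous_indval: bool = False) -> CoxFit:
    """Fit the standard covariate set on a list of survival records."""
    df = records_to_frame(records, continuous_indval=continuous_indval)
    covs = [c for c in df.columns if c not in ("subject", "start", "stop", "event")]
    fit = cox_ph(
        df["start"].to_numpy(),
        df["stop"].to_numpy(),
        df["event"].to_numpy(),
        df[covs].to_numpy(),
        names=covs,
    )
    fit.n_subjects = df["subject"].nunique()
    return fit


def hazard_report(fits: dict[str, CoxFit], alpha: float = 0.05) -> pd.DataFrame:
    """Long-format hazard-ratio table across model families.

    One row per (model, covariate level) with the hazard ratio, 95% CI,
    Wald z and p, and a significance flag; unstable (near-separated)
    coefficients are marked.
    """
    rows = []
    for model, fit in fits.items():
        for cov, r in fit.summary.iterrows():
            rows.append(
                dict(
                    model=model,
                    covariate=cov,
                    hazard_ratio=r["hazard_ratio"],
                    ci_low=r["ci_low"],
                    ci_high=r["ci_high"],
                    z=r["z"],
                    p=r["p"],
                    significant=bool(r["p"] < alpha),
                    unstable=cov in fit.unstable,
                )
            )
    return pd.DataFrame(rows)
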