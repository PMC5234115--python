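"""Event-table construction rules and the Cox partial-likelihood fitter."""

import numpy as np
import pandas as pd
import pytest

from microtrace.data_io import OtuTable, OtuTableError
from microtrace.survive import (
    SurvivalRecord,
    abundance_bins,
    build_deposition_records,
    build_loss_records,
    cox_fit,
    cox_ph,
    hazard_report,
    indval_bin,
)


def _study(skin_patterns, surface_patterns=None, n_seasons=4):
    """Build a one-individual, one-site study from presence patterns.

    ``skin_patterns``: {otu: set of seasons present on skin}.
    ``surface_patterns``: {otu: set of seasons present on the surface}.
    """
    seasons = range(1, n_seasons + 1)
    otus = sorted(set(skin_patterns) | set(surface_patterns or {}))
    rows, ids, meta_rows = [], [], []
    for s in seasons:
        ids.append(f"skin.s{s}")
        rows.append([10 if s in skin_patterns.get(o, set()) else 0 for o in otus])
        meta_rows.append(
            dict(type="skin", residence="R1", site="palm", individual="i1", season=s)
        )
        ids.append(f"surf.s{s}")
        rows.append(
            [10 if s in (surface_patterns or {}).get(o, set()) else 0 for o in otus]
        )
        meta_rows.append(
            dict(type="surface", residence="R1", site="desk", individual=None, season=s)
        )
    table = OtuTable(pd.DataFrame(rows, index=ids, columns=otus))
    meta = pd.DataFrame(meta_rows, index=ids)
    return table, meta


def _intervals(records, otu):
    return [
        (r.start, r.stop, r.event)
        for r in sorted(records, key=lambda r: r.start)
        if r.subject[-1] == otu
    ]


class TestLossRecordConstruction:
    def test_canonical_presence_patterns(self):
        table, meta = _study(
            {
                "all": {1, 2, 3, 4},
                "first_two": {1, 2},
                "gap": {1, 3},
                "last_only": {4},
                "single": {2},
            }
        )
        records = build_loss_records(table, meta, "skin")
        # present every season: three censored transitions
        assert _intervals(records, "all") == [
            (1, 2, "none"), (2, 3, "none"), (3, 4, "none")
        ]
        # winter+spring only: loss on the transition out of spring
        assert _intervals(records, "first_two") == [(1, 2, "none"), (2, 3, "loss")]
        # interim absence is not a loss; the loss follows the return season
        assert _intervals(records, "gap") == [
            (1, 2, "none"), (2, 3, "none"), (3, 4, "loss")
        ]
        # first observed in the final season: no transition to model
        assert _intervals(records, "last_only") == []
        # observed in one non-final season: a single at-risk interval, lost
        assert _intervals(records, "single") == [(2, 3, "loss")]

    def test_interim_season_takes_lowest_abundance_bin(self):
        table, meta = _study({"gap": {1, 3}, "fill": {1, 2, 3, 4}})
        records = build_loss_records(table, meta, "skin")
        gap_spring = [
            r for r in records if r.subject[-1] == "gap" and r.start == 2
        ][0]
        assert gap_spring.abundance_bin == 0

    def test_surface_subjects_restricted_to_occupant_skin_otus(self):
        table, meta = _study(
            {"both": {1, 2}},
            {"both": {1, 2, 3, 4}, "surface_only": {1, 2, 3, 4}},
        )
        records = build_loss_records(table, meta, "surface")
        subjects = {r.subject[-1] for r in records}
        assert subjects == {"both"}


class TestDepositionRecordConstruction:
    def test_deposit_next_season(self):
        table, meta = _study({"o": {1, 2, 3, 4}}, {"o": {2, 3}})
        records = build_deposition_records(table, meta)
        assert _intervals(records, "o") == [(1, 2, "deposition")]

    def test_same_season_deposition_on_first_interval(self):
        table, meta = _study({"o": {2, 3}}, {"o": {2}})
        records = build_deposition_records(table, meta)
        assert _intervals(records, "o") == [(2, 3, "deposition")]

    def test_never_deposited_censored_over_all_transitions(self):
        table, meta = _study({"o": {1, 2, 3, 4}}, {})
        records = build_deposition_records(table, meta)
        assert _intervals(records, "o") == [
            (1, 2, "none"), (2, 3, "none"), (3, 4, "none")
        ]

    def test_surface_before_skin_excluded(self):
        table, meta = _study({"o": {2, 3, 4}}, {"o": {1, 3}})
        records = build_deposition_records(table, meta)
        assert _intervals(records, "o") == []


class TestCovariateBinning:
    def test_abundance_percentile_bins(self):
        counts = pd.Series(np.arange(1, 101), index=[f"o{i}" for i in range(100)])
        bins = abundance_bins(counts)
        assert (bins.iloc[:69] == 0).all()  # up to 69th percentile
        assert (bins.iloc[69:89] == 1).all()
        assert (bins.iloc[89:98] == 2).all()
        assert (bins.iloc[98:] == 3).all()  # 99th percentile

    def test_indval_bin_edges(self):
        assert indval_bin(0.0) == 0
        assert indval_bin(0.2) == 0
        assert indval_bin(0.6) == 1
        assert indval_bin(0.9) == 2
        assert indval_bin(0.95) == 3


# ---------------------------------------------------------------------------
# fitter
# ---------------------------------------------------------------------------

def _efron_loglik_oracle(start, stop, event, x, beta):
    """Direct Efron partial log-likelihood by explicit set enumeration."""
    ll = 0.0
    for t in sorted({s for s, e in zip(stop, event) if e}):
        dead = [i for i in range(len(stop)) if event[i] and stop[i] == t]
        risk = [i for i in range(len(stop)) if start[i] < t <= stop[i]]
        d = len(dead)
        s_r = sum(np.exp(beta * x[i]) for i in risk)
        s_d = sum(np.exp(beta * x[i]) for i in dead)
        ll += sum(beta * x[i] for i in dead)
        for j in range(d):
            ll -= np.log(s_r - (j / d) * s_d)
    return ll


class TestCoxFitter:
    def _toy(self):
        # 8 subjects, tied event times, one binary covariate
        start = np.zeros(8)
        stop = np.array([2.0, 2.0, 3.0, 4.0, 2.0, 3.0, 4.0, 4.0])
        event = np.array([1, 1, 1, 0, 1, 0, 1, 0], dtype=bool)
        x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        return start, stop, event, x

    def test_matches_grid_search_oracle(self):
        start, stop, event, x = self._toy()
        grid = np.arange(-4.0, 4.0, 1e-4)
        lls = [_efron_loglik_oracle(start, stop, event, x, b) for b in grid]
        best = grid[int(np.argmax(lls))]
        fit = cox_ph(start, stop, event, x, names=["grp"])
        assert fit.summary.loc["grp", "coef"] == pytest.approx(best, abs=1e-4)
        assert fit.converged

    def test_agrees_with_lifelines_on_untied_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 50
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1.0 / np.exp(0.7 * x))
            # perturb to guarantee no ties
            t = t + rng.random(n) * 1e-6
            e = rng.random(n) < 0.8
            if e.sum() < 5 or len(np.unique(x[e])) < 2:
                continue
            fit = cox_ph(np.zeros(n), t, e, x, names=["x"])
            df = pd.DataFrame({"T": t, "E": e, "x": x})
            cph = lifelines.CoxPHFitter()
            cph.fit(
                df,
                duration_col="T",
                event_col="E",
                fit_options={"precision": 1e-12},
            )
            assert fit.summary.loc["x", "coef"] == pytest.approx(
                float(cph.params_["x"]), abs=1e-6
            )

    def test_duplicating_records_keeps_coef_scales_z(self):
        # exact under Breslow tie handling (duplication doubles tie groups,
        # which the Efron correction deliberately treats differently)
        start, stop, event, x = self._toy()
        fit1 = cox_ph(start, stop, event, x, names=["g"], ties="breslow")
        fit2 = cox_ph(
            np.tile(start, 2), np.tile(stop, 2), np.tile(event, 2), np.tile(x, 2),
            names=["g"], ties="breslow",
        )
        assert fit2.summary.loc["g", "coef"] == pytest.approx(
            fit1.summary.loc["g", "coef"], abs=1e-6
        )
        assert fit2.summary.loc["g", "z"] == pytest.approx(
            fit1.summary.loc["g", "z"] * np.sqrt(2), rel=1e-4
        )

    def test_record_order_invariance(self):
        start, stop, event, x = self._toy()
        perm = np.random.default_rng(1).permutation(8)
        fit1 = cox_ph(start, stop, event, x, names=["g"])
        fit2 = cox_ph(start[perm], stop[perm], event[perm], x[perm], names=["g"])
        assert fit1.summary.loc["g", "coef"] == pytest.approx(
            fit2.summary.loc["g", "coef"], abs=1e-10
        )

    def test_constant_covariate_dropped(self):
        start, stop, event, x = self._toy()
        X = np.column_stack([x, np.ones(8)])
        fit = cox_ph(start, stop, event, X, names=["g", "const"])
        assert fit.dropped == ["const"]
        assert list(fit.summary.index) == ["g"]

    def test_separation_flagged_unstable(self):
        # covariate perfectly predicts the event
        n = 40
        x = np.array([1.0] * 20 + [0.0] * 20)
        stop = np.concatenate([np.linspace(1, 2, 20), np.linspace(5, 6, 20)])
        event = np.array([True] * 20 + [False] * 20)
        with pytest.warns(UserWarning):
            fit = cox_ph(np.zeros(n), stop, event, x, names=["g"], max_iter=25)
        assert "g" in fit.unstable

    def test_zero_events_rejected(self):
        with pytest.raises(OtuTableError, match="zero events"):
            cox_ph(np.zeros(3), np.ones(3), np.zeros(3, dtype=bool), np.ones(3))


class TestRecordFitAndReport:
    def test_cox_fit_builds_indicator_design(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(300):
            abin = int(rng.integers(0, 4))
            event = rng.random() < (0.5 if abin == 0 else 0.2)
            records.append(
                SurvivalRecord(
                    subject=("skin", "i", "s", f"o{i}"),
                    start=1,
                    stop=2,
                    abundance_bin=abin,
                    indval_bin=int(rng.integers(0, 2)),
                    hitting_set_member=bool(rng.random() < 0.3),
                    event="loss" if event else "none",
                )
            )
        fit = cox_fit(records)
        assert fit.n_events == sum(r.event == "loss" for r in records)
        report = hazard_report({"skin_loss": fit})
        assert set(report["model"]) == {"skin_loss"}
        assert {"hazard_ratio", "ci_low", "ci_high", "significant"} <= set(report.columns)
        # CI must bracket the point estimate
        assert (report["ci_low"] <= report["hazard_ratio"] + 1e-12).all()
        assert (report["hazard_ratio"] <= report["ci_high"] + 1e-12).all()
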