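"""Closed-form recursive free-energy estimation from reporter tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import triadswitch as ts
from triadswitch.enhancers import REF_STATE, restrict_model
from triadswitch.fitting import InfeasibleFitError, ReporterRow, ReporterTable, fit_relaxed


def table(enhancer, rows):
    return ReporterTable(
        enhancer=enhancer,
        rows=tuple(ReporterRow(c, frozenset(s), f) for c, s, f in rows),
    )


class TestInvertSingle:
    def test_no_enhancement_means_no_binding(self):
        assert ts.invert_single(1.0, 900.0) == 0.0

    def test_matches_numeric_root_oracle(self):
        F, K = 820.51, 900.0
        w_oracle = brentq(lambda w: K * (1 + w) / (K + w) - F, 0.0, 1e9, xtol=1e-6)
        w = ts.invert_single(F, K)
        assert w == pytest.approx(w_oracle, rel=1e-9)
        assert w == pytest.approx(9278.6, abs=0.5)

    def test_infeasible_when_fold_reaches_K(self):
        with pytest.raises(InfeasibleFitError, match="maximal possible"):
            ts.invert_single(820.51, 800.0)
        with pytest.raises(InfeasibleFitError, match="maximal possible"):
            ts.invert_single(900.0, 900.0)

    def test_fold_below_baseline_rejected(self):
        with pytest.raises(InfeasibleFitError, match="below"):
            ts.invert_single(0.5, 900.0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(w=st.floats(1e-6, 1e8), K=st.floats(1.1, 1e4))
    def test_roundtrip_with_fold_formula(self, w, K):
        F = K * (1 + w) / (K + w)
        if F >= K:  # numerically saturated; inversion undefined
            return
        assert ts.invert_single(F, K) == pytest.approx(w, rel=1e-6)


class TestFitScl19:
    def test_reference_wild_type_reproduced_exactly(self, reference_tables):
        t = next(x for x in reference_tables if x.enhancer == "Scl+19")
        m = ts.fit_scl19(t, K_s=900.0)
        assert ts.fold_enhancement(m, REF_STATE) == pytest.approx(820.51, rel=1e-13)
        # Single-site constructs also match
        for sites, fold in ((("GATA",), 40.0), (("ETS",), 60.0)):
            sub = restrict_model(m, sites)
            assert ts.fold_enhancement(sub, REF_STATE) == pytest.approx(fold, rel=1e-13)

    def test_noise_free_synthetic_recovery(self):
        truth = ts.scl19_model(12.0, 345.0, 6789.0, K=5e4)
        rows = []
        for sites in ({"GATA"}, {"ETS"}, {"GATA", "ETS"}):
            sub = restrict_model(truth, sites)
            rows.append(("c", sites, ts.fold_enhancement(sub, REF_STATE)))
        m = ts.fit_scl19(table("Scl+19", rows), K_s=truth.K)
        for cid, w in truth.weights().items():
            assert m.weights()[cid] == pytest.approx(w, rel=1e-9)

    def test_all_ones_table_gives_zero_weights(self):
        t = table("Scl+19", [("a", {"GATA"}, 1.0), ("b", {"ETS"}, 1.0),
                            ("c", {"GATA", "ETS"}, 1.0)])
        m = ts.fit_scl19(t, K_s=100.0)
        assert all(w == 0.0 for w in m.weights().values())

    def test_negative_synergy_is_infeasible_not_clamped(self):
        # wt fold below the additive expectation of the single sites
        t = table("Scl+19", [("a", {"GATA"}, 40.0), ("b", {"ETS"}, 60.0),
                            ("c", {"GATA", "ETS"}, 80.0)])
        with pytest.raises(InfeasibleFitError, match="negative"):
            ts.fit_scl19(t, K_s=900.0)


class TestFitGata2m3:
    def test_noise_free_synthetic_recovery(self):
        truth = ts.gata2m3_model(3.0, 44.0, 120.0, 9000.0, K=5e4)
        rows = []
        for sites in ({"GATA"}, {"ETS"}, {"GATA", "ETS"}, {"GATA", "ETS", "E-BOX"}):
            sub = restrict_model(truth, sites)
            rows.append(("c", sites, ts.fold_enhancement(sub, REF_STATE)))
        m = ts.fit_gata2m3(table("Gata2-3", rows), K_g=truth.K)
        for cid, w in truth.weights().items():
            assert m.weights()[cid] == pytest.approx(w, rel=1e-9)

    def test_scl_site_alone_gives_no_enhancement(self, reference_tables):
        t = next(x for x in reference_tables if x.enhancer == "Gata2-3")
        m = ts.fit_gata2m3(t, K_g=525.0)
        scl_only = restrict_model(m, {"E-BOX"})
        assert ts.fold_enhancement(scl_only, REF_STATE) == 1.0

    def test_equal_ds_and_wt_folds_zero_scl_configuration(self):
        rows = [("a", {"GATA"}, 15.0), ("b", {"ETS"}, 25.0),
                ("c", {"GATA", "ETS"}, 150.0),
                ("wt", {"GATA", "ETS", "E-BOX"}, 150.0)]
        m = ts.fit_gata2m3(table("Gata2-3", rows), K_g=525.0)
        assert m.weights()["S.G.FF"] == 0.0


class TestFitFli1p12:
    def test_reference_20_and_60_fold_reproduced(self, reference_tables):
        t = next(x for x in reference_tables if x.enhancer == "Fli1+12")
        m = ts.fit_fli1p12(t, K_f=63.0)
        assert ts.fold_enhancement(m, REF_STATE) == pytest.approx(60.0, rel=1e-13)
        double_mut = restrict_model(m, {"GATA-primary", "ETS"})
        assert ts.fold_enhancement(double_mut, REF_STATE) == pytest.approx(
            20.0, rel=1e-13
        )

    def test_weak_sites_alone_give_no_enhancement(self, reference_tables):
        t = next(x for x in reference_tables if x.enhancer == "Fli1+12")
        m = ts.fit_fli1p12(t, K_f=63.0)
        for site in ("GATA-secondary", "E-BOX"):
            sub = restrict_model(m, {site})
            assert ts.fold_enhancement(sub, REF_STATE) == 1.0

    def test_noise_free_synthetic_recovery(self):
        truth = ts.fli1p12_model(2.0, 7.5, 31.0, 900.0, K=2e4)
        rows = []
        for sites in (
            {"GATA-primary"},
            {"ETS"},
            {"GATA-primary", "ETS"},
            {"GATA-primary", "ETS", "E-BOX", "GATA-secondary"},
        ):
            sub = restrict_model(truth, sites)
            rows.append(("c", sites, ts.fold_enhancement(sub, REF_STATE)))
        m = ts.fit_fli1p12(table("Fli1+12", rows), K_f=truth.K)
        for cid, w in truth.weights().items():
            assert m.weights()[cid] == pytest.approx(w, rel=1e-9)


class TestFeasibilityBound:
    def test_reference_bounds(self, reference_tables):
        bounds = {t.enhancer: ts.feasibility_bound(t) for t in reference_tables}
        assert bounds["Scl+19"] == 820.51
        assert bounds["Fli1+12"] == 60.0

    def test_trivial_table(self):
        t = table("Scl+19", [("a", {"GATA"}, 1.0), ("b", {"ETS"}, 1.0),
                            ("c", {"GATA", "ETS"}, 1.0)])
        assert ts.feasibility_bound(t) == 1.0

    def test_increasing_K_decreases_fitted_occupancy(self, reference_tables):
        t = next(x for x in reference_tables if x.enhancer == "Scl+19")
        occ = []
        for K in (900.0, 2000.0, 10000.0):
            m = ts.fit_scl19(t, K_s=K)
            zb = ts.bound_weight_sum(m, REF_STATE)
            occ.append(zb / (K + zb))  # implied open-trapped occupancy
        assert occ[0] > occ[1] > occ[2]


class TestNoiseRecovery:
    def test_median_error_shrinks_with_noise(self):
        """Median absolute relative weight error -> 0 as sigma -> 0."""
        medians = {}
        for sigma in (0.0, 0.05, 0.2):
            errs = []
            for seed in range(25):
                truth = ts.generate_truth(seed, sigma=sigma)
                for t in ts.generate_library(truth):
                    tm = truth.models[t.enhancer]
                    try:
                        fit = ts.fit_enhancer(t, tm.K)
                    except InfeasibleFitError:
                        continue  # noise pushed a composite weight negative
                    wt, wf = tm.weights(), fit.weights()
                    errs.extend(abs(wf[k] - wt[k]) / wt[k] for k in wt)
            medians[sigma] = float(np.median(errs))
        assert medians[0.0] < 1e-9
        assert medians[0.0] < medians[0.05] < medians[0.2]


class TestRelaxedFit:
    def test_matches_exact_fit_on_feasible_table(self, reference_tables):
        t = next(x for x in reference_tables if x.enhancer == "Scl+19")
        exact = ts.fit_scl19(t, K_s=900.0)
        relaxed = fit_relaxed(t, K=900.0)
        for cid, w in exact.weights().items():
            assert relaxed.weights()[cid] == pytest.approx(w, rel=1e-5)

    def test_returns_best_compromise_on_infeasible_table(self):
        t = table("Scl+19", [("a", {"GATA"}, 40.0), ("b", {"ETS"}, 60.0),
                            ("c", {"GATA", "ETS"}, 80.0)])
        m = fit_relaxed(t, K=900.0)
        assert all(w >= 0 for w in m.weights().values())
        # wild-type fold between the additive floor and the measured value
        F = ts.fold_enhancement(m, REF_STATE)
        assert 60.0 < F < 110.0


class TestCsvIO:
    def test_roundtrip(self, tmp_path, reference_tables):
        path = tmp_path / "lib.csv"
        ts.write_reporter_csv(reference_tables, path)
        back = ts.read_reporter_csv(path)
        by_name = {t.enhancer: t for t in back}
        for t in reference_tables:
            b = by_name[t.enhancer]
            for r1, r2 in zip(t.rows, b.rows):
                assert r1.intact_sites == r2.intact_sites
                assert r1.fold == pytest.approx(r2.fold)
                assert r1.source == r2.source

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("enhancer,construct\nScl+19,wt\n")
        with pytest.raises(ValueError, match="missing columns"):
            ts.read_reporter_csv(p)

    def test_missing_construct_row_is_schema_error(self, reference_tables):
        t = next(x for x in reference_tables if x.enhancer == "Scl+19")
        short = ReporterTable(enhancer="Scl+19", rows=t.rows[1:])
        with pytest.raises(KeyError, match="no construct"):
            ts.fit_scl19(short, K_s=900.0)
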