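import itertools
import math

import numpy as np
import pandas as pd
import pytest

import sitefid as sf
from sitefid.return_dynamics import _newton_cox


# ---------------------------------------------------------------------------
# brute-force partial likelihood oracle (independent of the engine)
# ---------------------------------------------------------------------------


def brute_partial_loglik(x, time, event, beta, ties):
    """Hand-written Cox log partial likelihood by direct enumeration."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(time):
        x = x.T
    eta = x @ np.atleast_1d(beta)
    ll = 0.0
    for t in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        deaths = [i for i in range(len(time)) if time[i] == t and event[i]]
        risk = [i for i in range(len(time)) if time[i] >= t]
        d = len(deaths)
        ll += sum(eta[i] for i in deaths)
        if ties == "breslow":
            ll -= d * math.log(sum(math.exp(eta[i]) for i in risk))
        else:  # efron
            sr = sum(math.exp(eta[i]) for i in risk)
            sd = sum(math.exp(eta[i]) for i in deaths)
            for l in range(d):
                ll -= math.log(sr - l / d * sd)
    return ll


def random_small_case(rng):
    n = int(rng.integers(2, 6))
    time = rng.integers(1, 6, size=n).astype(float)
    event = rng.integers(0, 2, size=n)
    if event.sum() == 0:
        event[int(rng.integers(0, n))] = 1
    x = rng.normal(size=n)
    return x, time, event


class TestPartialLikelihood:
    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_brute_force_enumeration(self, ties):
        rng = np.random.default_rng(17)
        for _ in range(100):
            x, time, event = random_small_case(rng)
            beta = float(rng.normal())
            ours = sf.cox_partial_loglik(
                x[:, None], time, event, np.array([beta]), ties=ties
            )
            assert ours == pytest.approx(
                brute_partial_loglik(x, time, event, beta, ties), abs=1e-9
            )

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_newton_optimum_matches_grid_search(self, ties):
        """The fitted coefficient maximizes the brute-force likelihood."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            x, time, event = random_small_case(rng)
            if len(set(x)) < 2:
                continue
            beta_hat, *_ = _newton_cox(x[:, None], time, event, ties=ties)
            grid = np.arange(-4.0, 4.0, 0.01)
            vals = [brute_partial_loglik(x, time, event, b, ties) for b in grid]
            if max(vals) - min(vals) < 1e-8:
                continue  # flat likelihood (each event alone in its risk set)
            b0 = grid[int(np.argmax(vals))]
            fine = np.arange(b0 - 0.02, b0 + 0.02, 1e-5)
            vals = [brute_partial_loglik(x, time, event, b, ties) for b in fine]
            b1 = fine[int(np.argmax(vals))]
            if abs(b1) > 3.5:
                continue  # near-separable case: optimum diverges
            assert float(beta_hat[0]) == pytest.approx(b1, abs=1e-4)

    def test_ties_methods_agree_on_distinct_event_times(self):
        rng = np.random.default_rng(31)
        n = 40
        x = rng.normal(size=(n, 2))
        time = rng.permutation(np.arange(1.0, n + 1.0))  # all distinct
        event = rng.integers(0, 2, size=n)
        event[0] = 1
        rec = pd.DataFrame(
            {"time": time, "event": event, "x1": x[:, 0], "x2": x[:, 1],
             "ant": "a"}
        )
        fe = sf.fit_cox(rec, ("x1", "x2"), ties="efron", variance="model")
        fb = sf.fit_cox(rec, ("x1", "x2"), ties="breslow", variance="model")
        np.testing.assert_allclose(
            fe.table["coef"], fb.table["coef"], atol=1e-8
        )
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-8)


class TestFitCox:
    def test_matches_statsmodels_reference(self):
        from statsmodels.duration.hazard_regression import PHReg

        rng = np.random.default_rng(2)
        n = 300
        x = rng.normal(size=(n, 2))
        t = np.round(rng.exponential(np.exp(-0.5 * x[:, 0])), 1) + 0.1
        e = (rng.uniform(size=n) < 0.8).astype(int)
        rec = pd.DataFrame(
            {"time": t, "event": e, "x1": x[:, 0], "x2": x[:, 1], "ant": "a"}
        )
        for ties in ("breslow", "efron"):
            res = PHReg(t, x, status=e, ties=ties).fit(disp=False)
            fit = sf.fit_cox(rec, ("x1", "x2"), ties=ties, variance="model")
            np.testing.assert_allclose(
                fit.table["coef"], res.params, atol=1e-6
            )
            np.testing.assert_allclose(fit.table["se"], res.bse, atol=1e-6)

    def test_beta_recovery_on_simulated_exponential_survival(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        c = rng.exponential(2.0, size=n)
        rec = pd.DataFrame(
            {
                "time": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "x": x,
                "ant": "a",
            }
        )
        fit = sf.fit_cox(rec, ("x",), variance="model")
        assert abs(fit.table.at["x", "coef"] - 0.5) < 0.15

    def test_null_confidence_interval_coverage(self):
        """With return times independent of the covariate, the 95% CI for
        the coefficient covers 0 in at least 90 of 100 replicates."""
        cover = 0
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            x = rng.normal(size=200)
            t = rng.exponential(1.0, size=200)
            c = rng.exponential(2.0, size=200)
            rec = pd.DataFrame(
                {
                    "time": np.minimum(t, c),
                    "event": (t <= c).astype(int),
                    "x": x,
                    "ant": "a",
                }
            )
            lo, hi = sf.fit_cox(rec, ("x",), variance="model").confint_hr("x")
            cover += int(lo <= 1.0 <= hi)
        assert cover >= 90

    def test_constant_predictor_dropped_all_constant_rejected(self):
        rec = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 0, 1],
                "x": [1.0, 1.0, 1.0, 1.0],
                "y": [0.0, 1.0, 0.0, 1.0],
                "ant": list("aabb"),
            }
        )
        with pytest.raises(ValueError, match="not identifiable"):
            sf.fit_cox(rec, ("x",))
        with pytest.warns(UserWarning, match="constant"):
            fit = sf.fit_cox(rec, ("x", "y"), variance="model")
        assert fit.dropped == ["x"] and list(fit.table.index) == ["y"]

    def test_robust_clustered_se_matches_r_convention(self):
        """Sandwich variance equals the grouped-score formulation used by
        the survival literature (verified against R survival's cluster())."""
        rng = np.random.default_rng(0)
        n = 300
        x = rng.normal(size=(n, 2))
        t = np.round(rng.exponential(np.exp(-0.5 * x[:, 0])), 1) + 0.1
        e = (rng.uniform(size=n) < 0.8).astype(int)
        g = np.repeat(np.arange(30), 10)
        rec = pd.DataFrame(
            {"time": t, "event": e, "x1": x[:, 0], "x2": x[:, 1],
             "ant": g.astype(str)}
        )
        fit = sf.fit_cox(rec, ("x1", "x2"), ties="efron", variance="robust",
                         cluster="ant")
        # frozen reference values from coxph(Surv(time,event)~x1+x2+cluster(g))
        np.testing.assert_allclose(
            fit.table["coef"], [0.5209198, -0.01864881], atol=1e-6
        )
        np.testing.assert_allclose(
            fit.table["se"], [0.0934042, 0.06410009], atol=1e-6
        )

    def test_gaussian_frailty_matches_r_at_fixed_theta(self):
        """Penalized log-normal frailty coefficients agree with R survival's
        frailty.gaussian(theta=0.5) on the same data."""
        rng = np.random.default_rng(0)
        n = 300
        x = rng.normal(size=(n, 2))
        t = np.round(rng.exponential(np.exp(-0.5 * x[:, 0])), 1) + 0.1
        e = (rng.uniform(size=n) < 0.8).astype(int)
        g = np.repeat(np.arange(30), 10)
        rec = pd.DataFrame(
            {"time": t, "event": e, "x1": x[:, 0], "x2": x[:, 1],
             "ant": g.astype(str)}
        )
        fit = sf.fit_cox(
            rec, ("x1", "x2"), ties="efron", variance="frailty",
            frailty_group="ant", frailty_theta=0.5,
        )
        np.testing.assert_allclose(
            fit.table["coef"], [0.5337754, 0.0125672], atol=1e-5
        )


class TestVisitHistory:
    def _two_visit_records(self, grid):
        from conftest import make_site_sequence

        seq = make_site_sequence([0, 0, 1, 0, 0], grid)
        visits = sf.compute_visits(seq)
        colony_visits = {"C01": {"A1": visits}}
        castes = {("C01", "A1"): "worker"}
        return colony_visits, castes

    def test_event_and_censor_rows(self, grid):
        colony_visits, castes = self._two_visit_records(grid)
        rec = sf.build_visit_history(colony_visits, castes)
        site0 = rec[rec["site"] == 0].sort_values("visit_k")
        assert site0["event"].tolist() == [1, 0]
        assert site0["time"].tolist() == [20.0, 0.0]
        # exactly one censored record per (ant, site)
        assert (
            rec.groupby(["ant", "site"])["event"].apply(lambda e: (e == 0).sum())
            == 1
        ).all()

    def test_unpartitioned_colony_excluded(self, grid):
        colony_visits, castes = self._two_visit_records(grid)
        part = sf.CommunityPartition(
            colony_id="C01", membership={"A1": 0}, modularity=0.0, seed=0
        )
        with pytest.warns(UserWarning, match="excluded"):
            rec = sf.build_visit_history(
                colony_visits, castes, partitions={"C01": part}
            )
        assert rec.empty

    def test_brood_covariates_carry_forward(self, grid):
        colony_visits, castes = self._two_visit_records(grid)
        cell0_x = grid.cell_size / 2
        census = sf.BroodCensus(
            colony_id="C01",
            items=pd.DataFrame(
                [
                    {"census_tick": 0, "stage": "egg", "x_mm": cell0_x,
                     "y_mm": cell0_x},
                    {"census_tick": 0, "stage": "egg", "x_mm": cell0_x,
                     "y_mm": cell0_x},
                    {"census_tick": 0, "stage": "egg", "x_mm": cell0_x,
                     "y_mm": cell0_x},
                ]
            ),
        )
        rec = sf.build_visit_history(
            colony_visits, castes, censuses={"C01": census}, grid=grid
        )
        assert (rec[rec["site"] == 0]["n_egg"] == 3).all()
        assert (rec[rec["site"] == 1]["n_egg"] == 0).all()


class TestModelSelection:
    def _records(self, seed=0, group_effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(20):
            b = rng.normal(0, group_effect)
            for _ in range(15):
                x = rng.normal()
                t = rng.exponential(np.exp(-(0.3 * x + b)))
                rows.append(
                    {"time": t, "event": 1, "x": x, "ant": f"g{g}",
                     "colony": "C"}
                )
        return pd.DataFrame(rows)

    def test_identical_candidates_tie_break_to_first(self):
        rec = self._records()
        fit, table = sf.model_selection(
            rec, ("x",),
            candidates=[{"variance": "model"}, {"variance": "model"}],
        )
        assert table["aic"].nunique() == 1
        assert fit.variance == "model"

    def test_useless_random_effect_not_preferred(self):
        """Without group heterogeneity the plain model wins within 2 AIC."""
        rec = self._records(group_effect=0.0)
        fit, table = sf.model_selection(
            rec, ("x",),
            candidates=[
                {"variance": "model"},
                {"variance": "frailty", "frailty_group": "ant"},
            ],
        )
        aics = table["aic"].to_numpy()
        assert aics[1] > aics[0] - 2.0

    def test_real_group_heterogeneity_prefers_frailty(self):
        rec = self._records(seed=3, group_effect=0.8)
        fit, table = sf.model_selection(
            rec, ("x",),
            candidates=[
                {"variance": "model"},
                {"variance": "frailty", "frailty_group": "ant"},
            ],
        )
        assert fit.variance == "frailty"

    def test_aic_invariant_to_record_order(self):
        rec = self._records(seed=5)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        _, t1 = sf.model_selection(rec, ("x",),
                                   candidates=[{"variance": "model"}])
        _, t2 = sf.model_selection(shuffled, ("x",),
                                   candidates=[{"variance": "model"}])
        assert t1["aic"].iloc[0] == pytest.approx(t2["aic"].iloc[0], abs=1e-8)
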