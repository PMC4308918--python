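import numpy as np
import pandas as pd
import pytest

from mirnome.survival import (
    ClinicalTable,
    cox_multivariate,
    independent_both_endpoints,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    replicate,
    survival_screen,
)


def clinical_from(times, events, ipi=None, coo=None, cohort="discovery", pfs=None):
    n = len(times)
    pfs_times, pfs_events = pfs if pfs is not None else (times, events)
    return ClinicalTable(
        pd.DataFrame(
            {
                "os_time": times,
                "os_event": events,
                "pfs_time": pfs_times,
                "pfs_event": pfs_events,
                "ipi": ipi if ipi is not None else [0] * n,
                "coo": coo if coo is not None else ["GCB"] * n,
                "cohort": [cohort] * n,
            },
            index=[f"p{i}" for i in range(n)],
        )
    )


class TestKaplanMeier:
    def test_no_events_flat(self):
        km = km_estimate([5, 8, 10], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_death(self):
        km = km_estimate([10, 12, 15, 20], [1, 0, 0, 0])
        after = km[km["time"] >= 10]["survival"]
        assert np.allclose(after, 0.75)

    def test_hand_product_limit_with_censoring(self):
        # times (5+, 8, 12, 16+): risk sets 3 then 2 at the event times
        km = km_estimate([5, 8, 12, 16], [0, 1, 1, 0]).set_index("time")
        assert km.loc[8, "survival"] == pytest.approx(2 / 3)
        assert km.loc[12, "survival"] == pytest.approx(1 / 3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups(self):
        times = [3, 5, 7, 3, 5, 7]
        events = [1, 1, 0, 1, 1, 0]
        stat, p = logrank_test(times, events, [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_no_events(self):
        stat, _p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert stat == 0.0

    def test_hand_computation(self):
        # 3+3 patients, all events, fully separated survival
        times = [1, 2, 3, 10, 11, 12]
        events = [1] * 6
        groups = [0, 0, 0, 1, 1, 1]
        stat, _ = logrank_test(times, events, groups)
        # manual risk-table O-E/V computation
        o1 = e1 = v = 0.0
        t_arr, e_arr, g_arr = map(np.asarray, (times, events, groups))
        for t in sorted(set(t_arr[e_arr == 1])):
            at = t_arr >= t
            n, n1 = at.sum(), (at & (g_arr == 1)).sum()
            d = ((t_arr == t) & (e_arr == 1)).sum()
            d1 = ((t_arr == t) & (e_arr == 1) & (g_arr == 1)).sum()
            o1 += d1
            e1 += d * n1 / n
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert stat == pytest.approx((o1 - e1) ** 2 / v)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=60)
        events = rng.random(60) < 0.7
        groups = rng.random(60) < 0.5
        stat, p = logrank_test(times, events.astype(int), groups)
        ref = ll_logrank(times[groups], times[~groups], events[groups], events[~groups])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [1, 1])


def brute_force_best_split(expr, times, events, min_fraction):
    from mirnome.survival import _logrank_chi2

    n = len(expr)
    best = -1.0
    vals = np.unique(expr)
    for lo, hi in zip(vals[:-1], vals[1:]):
        cut = (lo + hi) / 2
        high = expr > cut
        if min(high.sum(), n - high.sum()) < min_fraction * n:
            continue
        best = max(best, _logrank_chi2(times, events, high))
    return best


class TestOptimalCutpoint:
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_maximum(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        expr = pd.Series(rng.lognormal(2, 1, n), index=[f"p{i}" for i in range(n)], name="f")
        clin = clinical_from(rng.exponential(10, n), (rng.random(n) < 0.7).astype(int))
        res = optimal_cutpoint(expr, clin, "OS", min_fraction=0.10)
        best = brute_force_best_split(
            expr.to_numpy(), *clin.endpoint("OS"), 0.10
        )
        assert res.logrank_chisq == pytest.approx(best, abs=1e-9)

    def test_min_fraction_boundary(self):
        # n=10, min_fraction=0.10: 1-patient groups are admissible (1 >= 1)
        expr = pd.Series(np.arange(10, dtype=float), index=[f"p{i}" for i in range(10)], name="f")
        times = [1] + [50] * 9  # first (lowest-expression) patient dies early
        events = [1] * 10
        clin = clinical_from(times, events)
        res = optimal_cutpoint(expr, clin, "OS", min_fraction=0.10)
        labels = res.group_labels
        assert (labels == "low").sum() >= 1

    def test_constant_expression_rejected(self):
        expr = pd.Series([2.0] * 10, index=[f"p{i}" for i in range(10)], name="f")
        clin = clinical_from([1] * 10, [1] * 10)
        with pytest.raises(ValueError):
            optimal_cutpoint(expr, clin)


class TestCox:
    def test_matches_r_survival(self, tmp_path):
        """Coefficients and Wald p agree with R's coxph to 4 decimals."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(8)
        n = 120
        group = rng.random(n) < 0.5
        coo = rng.choice(["ABC", "GCB", "unclassified"], size=n)
        ipi = rng.integers(0, 6, size=n)
        lp = 0.7 * group + 0.4 * (coo == "ABC") + 0.1 * ipi
        times = rng.exponential(np.exp(-lp) * 20)
        events = (rng.random(n) < 0.8).astype(int)
        clin = clinical_from(times, events, ipi=ipi, coo=coo)
        labels = pd.Series(np.where(group, "high", "low"), index=clin.patient_ids)
        out = cox_multivariate(labels, clin)
        df = clin.table.copy()
        df["expr_high"] = group.astype(int)
        csv = tmp_path / "d.csv"
        df.to_csv(csv)
        script = tmp_path / "cox.R"
        script.write_text(
            f"""
            library(survival)
            d <- read.csv("{csv}")
            d$coo_ABC <- as.integer(d$coo == "ABC")
            d$coo_unclassified <- as.integer(d$coo == "unclassified")
            f <- coxph(Surv(os_time, os_event) ~ expr_high + coo_ABC + coo_unclassified + ipi,
                       data = d, ties = "efron")
            s <- summary(f)$coefficients
            write.csv(s, "{tmp_path}/out.csv")
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        for cov in ("expr_high", "coo_ABC", "coo_unclassified", "ipi"):
            assert out.loc[cov, "coef"] == pytest.approx(ref.loc[cov, "coef"], abs=1e-4)
            assert out.loc[cov, "p"] == pytest.approx(ref.loc[cov, "Pr(>|z|)"], abs=1e-4)

    def test_score_test_equals_logrank_tie_free(self):
        """For one binary covariate without ties, the Cox score statistic at
        beta=0 equals the log-rank statistic."""
        rng = np.random.default_rng(12)
        n = 40
        group = rng.random(n) < 0.5
        times = rng.exponential(10 * np.exp(-0.8 * group))
        events = np.ones(n, dtype=int)
        stat, _ = logrank_test(times, events, group)
        # independent score-test computation: U(0)^2 / I(0)
        order = np.argsort(times)
        t, e, g = times[order], events[order], group[order].astype(float)
        u = info = 0.0
        for i in range(n):
            if e[i] != 1:
                continue
            risk = np.arange(n) >= i
            pbar = g[risk].mean()
            u += g[i] - pbar
            info += pbar * (1 - pbar)
        assert stat == pytest.approx(u**2 / info, rel=1e-9)

    def test_no_events_rejected(self):
        clin = clinical_from([1, 2, 3, 4], [0, 0, 0, 0])
        labels = pd.Series(["high", "low", "high", "low"], index=clin.patient_ids)
        with pytest.raises(ValueError):
            cox_multivariate(labels, clin)


class TestScreenAndReplicate:
    def _cohort(self, seed, n=80, effect=1.5, cohort="discovery"):
        rng = np.random.default_rng(seed)
        expr = rng.lognormal(3, 1, n)
        cut = np.median(expr)
        high = expr > cut
        lp = effect * high
        times = rng.exponential(np.exp(-lp) * 20)
        events = (rng.random(n) < 0.8).astype(int)
        pfs_times = rng.exponential(np.exp(-lp) * 12)
        pfs_events = (rng.random(n) < 0.8).astype(int)
        clin = clinical_from(
            times, events, ipi=rng.integers(0, 6, n),
            coo=rng.choice(["ABC", "GCB", "unclassified"], n),
            cohort=cohort, pfs=(pfs_times, pfs_events),
        )
        # one associated feature and three null features
        mat = pd.DataFrame(
            np.vstack([expr, rng.lognormal(3, 1, (3, n))]),
            index=["hit", "null1", "null2", "null3"],
            columns=clin.patient_ids,
        )
        from mirnome.expression import ExpressionMatrix

        return ExpressionMatrix(values=mat, unit="RPM"), clin

    def test_discovery_screen_flags_planted_feature(self):
        expr, clin = self._cohort(0)
        res = survival_screen(expr, clin, mode="discovery")
        hit = res[(res["feature_id"] == "hit")]
        assert hit["independent"].all()

    def test_replication_requires_both_cohorts(self):
        expr_d, clin_d = self._cohort(1)
        expr_v, clin_v = self._cohort(2, cohort="validation")
        disc = survival_screen(expr_d, clin_d, mode="discovery")
        valid = survival_screen(expr_v, clin_v, mode="validation")
        assert replicate(disc, valid) == ["hit"]
        # a feature absent from validation independence cannot replicate
        valid_null = valid.copy()
        valid_null["independent"] = False
        assert replicate(disc, valid_null) == []

    def test_empty_discovery_empty_replication(self):
        expr_v, clin_v = self._cohort(3, cohort="validation")
        valid = survival_screen(expr_v, clin_v, mode="validation")
        empty = valid.copy()
        empty["independent"] = False
        assert replicate(empty, valid) == []

    def test_independent_both_endpoints_requires_both(self):
        expr, clin = self._cohort(4)
        res = survival_screen(expr, clin, mode="discovery")
        only_os = res[res["endpoint"] == "OS"]
        assert len(independent_both_endpoints(only_os)) == 0
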