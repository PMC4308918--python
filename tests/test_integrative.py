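import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata, spearmanr

from mirnome.datagen import SimulationConfig, simulate_cohort
from mirnome.expression import filter_expressed_mrna, rpm_normalize
from mirnome.integrative import (
    NullHistogram,
    anti_correlated,
    bin_index,
    bin_rank_filter,
    build_null,
    call_interactions,
    integrate,
    per_mirna_bh,
    seed_match_sites,
    sites_to_frame,
    spearman_all_pairs,
)

from conftest import matrix


class TestSpearman:
    def test_monotone_extremes(self):
        mi = matrix([[1, 2, 3, 4, 5]], features=["m"])
        mr = matrix([[10, 8, 6, 4, 2], [1, 2, 3, 4, 5]], features=["down", "up"], unit="FPKM")
        pairs = spearman_all_pairs(mi, mr)
        assert pairs.set_index("mrna_id").loc["down", "rho"] == pytest.approx(-1.0)
        assert pairs.set_index("mrna_id").loc["up", "rho"] == pytest.approx(1.0)

    def test_matches_rank_pearson_oracle(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([3, 1, 4, 5, 2.0])
        mi = matrix([x], features=["m"])
        mr = matrix([y], features=["t"], unit="FPKM")
        pairs = spearman_all_pairs(mi, mr)
        expected = pearsonr(rankdata(x), rankdata(y)).statistic
        assert pairs["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert pairs["rho"].iloc[0] == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_p_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.random(20)
        y = rng.random(20)
        pairs = spearman_all_pairs(matrix([x], features=["m"]), matrix([y], features=["t"], unit="FPKM"))
        ref = spearmanr(x, y)
        assert pairs["rho"].iloc[0] == pytest.approx(ref.statistic, abs=1e-12)
        assert pairs["p_value"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_gives_nan(self):
        mi = matrix([[2, 2, 2, 2]], features=["const"])
        mr = matrix([[1, 2, 3, 4]], features=["t"], unit="FPKM")
        pairs = spearman_all_pairs(mi, mr)
        assert np.isnan(pairs["rho"].iloc[0])


class TestPerMirnaBH:
    def test_single_isoform_family(self):
        pairs = pd.DataFrame(
            {"mirna_id": ["m1"], "mrna_id": ["t1"], "p_value": [0.03], "rho": [-0.5]}
        )
        out = per_mirna_bh(pairs)
        assert out["q_value"].iloc[0] == pytest.approx(0.03)

    def test_family_independence(self):
        p = [0.001, 0.03, 0.2]
        pairs = pd.DataFrame(
            {
                "mirna_id": ["a"] * 3 + ["b"] * 3,
                "mrna_id": ["t1", "t2", "t3"] * 2,
                "p_value": p + p,
                "rho": [-0.5] * 6,
            }
        )
        out = per_mirna_bh(pairs)
        qa = out[out["mirna_id"] == "a"]["q_value"].to_numpy()
        qb = out[out["mirna_id"] == "b"]["q_value"].to_numpy()
        assert np.allclose(qa, qb)
        assert np.allclose(qa, [0.003, 0.045, 0.2])


class TestAntiCorrelated:
    @pytest.mark.parametrize(
        "rho,q,kept",
        [(-0.6, 0.01, True), (0.0, 0.001, False), (-0.9, 0.05, False), (-0.01, 0.049, True)],
    )
    def test_strict_thresholds(self, rho, q, kept):
        pairs = pd.DataFrame({"mirna_id": ["m"], "mrna_id": ["t"], "rho": [rho], "q_value": [q]})
        assert (len(anti_correlated(pairs)) == 1) is kept


class TestNull:
    def _matrices(self, seed=3, n_mi=8, n_mr=12, n=30):
        rng = np.random.default_rng(seed)
        mi = matrix(rng.lognormal(3, 1, (n_mi, n)), features=[f"m{i}" for i in range(n_mi)])
        mr = matrix(rng.lognormal(2, 1, (n_mr, n)), features=[f"t{i}" for i in range(n_mr)], unit="FPKM")
        return mi, mr

    def test_count_conservation(self):
        mi, mr = self._matrices()
        null = build_null(mi, mr, n_permutations=7, seed=0)
        assert null.null_totals.sum() == 8 * 12 * 7
        assert null.observed_counts.sum() == 8 * 12

    def test_identity_permutation_equals_observed(self):
        mi, mr = self._matrices()
        null = build_null(mi, mr, n_permutations=3, seed=0, _identity=True)
        assert np.array_equal(null.null_totals, null.observed_counts * 3)

    def test_null_matches_observed_under_independence(self):
        from scipy.stats import chisquare

        mi, mr = self._matrices(seed=3, n_mi=20, n_mr=40, n=40)
        null = build_null(mi, mr, n_permutations=50, n_bins=10, seed=3)
        exp = null.null_counts
        obs = null.observed_counts
        keep = exp >= 5
        res = chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert res.pvalue > 0.01

    def test_permutation_target_symmetry(self):
        from scipy.stats import chisquare

        mi, mr = self._matrices(seed=4, n_mi=20, n_mr=40, n=40)
        a = build_null(mi, mr, n_permutations=40, n_bins=10, seed=1)
        b = build_null(mi, mr, n_permutations=40, n_bins=10, seed=2, permute_mrna=True)
        keep = (a.null_counts >= 5) & (b.null_counts >= 5)
        res = chisquare(
            a.null_counts[keep] * 40,
            b.null_counts[keep] * 40 * a.null_counts[keep].sum() / b.null_counts[keep].sum(),
        )
        assert res.pvalue > 0.01

    def test_deterministic_given_seed(self):
        mi, mr = self._matrices()
        a = build_null(mi, mr, n_permutations=5, seed=9)
        b = build_null(mi, mr, n_permutations=5, seed=9)
        assert np.array_equal(a.null_totals, b.null_totals)

    def test_bad_permutation_count(self):
        mi, mr = self._matrices()
        with pytest.raises(ValueError):
            build_null(mi, mr, n_permutations=0)


class TestBinRankFilter:
    def _null(self, observed, null_mean, n_bins=2):
        return NullHistogram(
            bin_edges=np.linspace(-1, 1, n_bins + 1),
            observed_counts=np.asarray(observed),
            null_totals=(np.asarray(null_mean) * 10).astype(np.int64),
            n_permutations=10,
        )

    def _pairs(self, rhos, qs):
        return pd.DataFrame(
            {
                "mirna_id": [f"m{i}" for i in range(len(rhos))],
                "mrna_id": [f"t{i}" for i in range(len(rhos))],
                "rho": rhos,
                "p_value": qs,
                "q_value": qs,
            }
        )

    def test_excess_keeps_smallest_q(self):
        pairs = self._pairs([-0.5] * 5, [0.01, 0.02, 0.03, 0.04, 0.05])
        null = self._null([5, 0], [2.0, 0.0])
        out = bin_rank_filter(pairs, null)
        passed = set(out[out["passed_null"]]["mirna_id"])
        assert passed == {"m0", "m1", "m2"}

    def test_null_dominates_bin(self):
        pairs = self._pairs([-0.5] * 3, [0.01, 0.02, 0.03])
        null = self._null([3, 0], [5.0, 0.0])
        out = bin_rank_filter(pairs, null)
        assert out["passed_null"].sum() == 0

    def test_two_bin_toy(self):
        rhos = [-0.5] * 4 + [0.5] * 6
        qs = list(np.linspace(0.01, 0.1, 10))
        pairs = self._pairs(rhos, qs)
        null = self._null([4, 6], [1.0, 6.0])
        out = bin_rank_filter(pairs, null)
        assert out[out["rho"] < 0]["passed_null"].sum() == 3
        assert out[out["rho"] > 0]["passed_null"].sum() == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        pairs = self._pairs(rng.uniform(-1, 1, 30), rng.random(30))
        null = self._null([0, 0], [3.0, 3.0])
        out1 = bin_rank_filter(pairs, null).sort_values("mirna_id")
        out2 = bin_rank_filter(pairs.sample(frac=1, random_state=1), null).sort_values("mirna_id")
        assert (out1["passed_null"].to_numpy() == out2["passed_null"].to_numpy()).all()

    def test_boundary_bins(self):
        assert bin_index(np.array([-1.0]), 40)[0] == 0
        assert bin_index(np.array([1.0]), 40)[0] == 39
        assert bin_index(np.array([-0.95]), 40)[0] == 1
        with pytest.raises(ValueError):
            bin_index(np.array([1.5]), 40)


class TestSeedMatch:
    MIR10393 = "UUGGUCAGAUUUGAACUCUUCA"  # seed (nt 2-8) UGGUCAG; site motif CTGACCA

    def test_printed_sequence_site(self):
        transcripts = {"tx": ("AAAA" + "CTGACCA" + "GGGG", [("3UTR", 0, 15)])}
        sites = seed_match_sites({"miR-10393-3p": self.MIR10393}, transcripts)
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end, sites[0].region) == (4, 11, "3UTR")

    def test_no_match_no_sites(self):
        transcripts = {"tx": ("A" * 30, [("CDS", 0, 30)])}
        assert seed_match_sites({"m": self.MIR10393}, transcripts) == []

    def test_match_spanning_region_boundary_skipped(self):
        seq = "AAAA" + "CTGACCA" + "GGGG"
        transcripts = {"tx": (seq, [("5UTR", 0, 7), ("CDS", 7, 15)])}
        assert seed_match_sites({"m": self.MIR10393}, transcripts) == []

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError, match="tx"):
            seed_match_sites({"m": self.MIR10393}, {"tx": ("ACGTN", [("CDS", 0, 5)])})


class TestCallInteractions:
    def _pairs(self):
        return pd.DataFrame(
            {
                "mirna_id": ["m1", "m2"],
                "mrna_id": ["t1", "t2"],
                "rho": [-0.8, -0.8],
                "p_value": [0.001, 0.001],
                "q_value": [0.01, 0.01],
                "passed_null": [True, True],
            }
        )

    def _sites(self, pairs):
        return pd.DataFrame(pairs, columns=["mirna_id", "transcript_id"]).assign(
            region="3UTR", start=0, end=7
        )

    def test_single_predictor_insufficient(self):
        out = call_interactions(
            self._pairs(),
            {"A": self._sites([("m1", "t1")]), "B": self._sites([])},
        )
        assert not out["site_predicted"].any()

    def test_both_predictors_required_and_sufficient(self):
        out = call_interactions(
            self._pairs(),
            {"A": self._sites([("m1", "t1")]), "B": self._sites([("m1", "t1")])},
        )
        assert out.set_index("mirna_id")["interaction"].to_dict() == {"m1": True, "m2": False}


def test_full_toy_run_recovers_planted_pairs():
    """Small planted fixture: the interaction set equals the planted set."""
    cfg = SimulationConfig(
        n_tumor=60, n_normal=10, n_validation=2, n_mirna=40, n_mrna=60,
        n_de_mirna=0, n_regulatory_pairs=5, n_survival_mirna=0,
        n_cluster_markers=0, decoy_site_rate=0.0, seed=11,
    )
    mirna, mrna, ann, _clin, truth = simulate_cohort(cfg)
    rpm = rpm_normalize(mirna, ann.table["aligned_reads"])
    disc = ann.samples_in(cohort="discovery")
    sites = sites_to_frame(truth.binding_sites)
    by_pred = {p: sites[sites["predictor"] == p] for p in ("A", "B")}
    kept = filter_expressed_mrna(mrna)
    pairs, _null = integrate(
        rpm.subset_samples(disc), mrna.subset_features(kept), by_pred,
        n_permutations=30, seed=5,
    )
    called = {(r.mirna_id, r.mrna_id) for r in pairs[pairs["interaction"]].itertuples()}
    planted = {(m, t) for m, t, _s in truth.regulatory_pairs}
    assert called == planted
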