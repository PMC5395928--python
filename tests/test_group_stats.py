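"""Demographic statistics, FDR control, and the anxiety regression."""

import numpy as np
import pandas as pd
import pytest

from nirsconn import group_stats as gs
from nirsconn import reference
from nirsconn import synthetic_data as sd
from nirsconn.errors import EstimationError, NirsconnError


def samples_with_summary(mean, sd, n, rng):
    """Raw samples whose sample mean/sd match the summary exactly."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestWelch:
    def test_published_anxiety_comparison(self):
        res = gs.welch_ttest((95.4, 22.1, 8), (74.1, 15.2, 7))
        assert res.pvalue == pytest.approx(0.047, abs=0.005)

    @pytest.mark.parametrize("var,expected_p", [
        ("age", 0.58), ("education", 0.43), ("iq", 0.97), ("cigarettes", 0.61),
    ])
    def test_published_demographic_pvalues(self, var, expected_p):
        (m1, s1), (m2, s2) = (reference.COHORT_SUMMARY[var]["HD"],
                              reference.COHORT_SUMMARY[var]["CG"])
        res = gs.welch_ttest((m1, s1, reference.N_HD), (m2, s2, reference.N_CG))
        assert res.pvalue == pytest.approx(expected_p, abs=0.005)

    def test_identical_groups(self, rng):
        x = rng.normal(size=10)
        res = gs.welch_ttest(x, x.copy())
        assert res.tstat == 0.0 and res.pvalue == 1.0

    def test_summary_equals_raw_samples(self, rng):
        a = samples_with_summary(5.0, 2.0, 9, rng)
        b = samples_with_summary(3.5, 1.5, 7, rng)
        from_raw = gs.welch_ttest(a, b)
        from_summary = gs.welch_ttest((5.0, 2.0, 9), (3.5, 1.5, 7))
        assert from_raw.tstat == pytest.approx(from_summary.tstat, abs=1e-10)
        assert from_raw.df == pytest.approx(from_summary.df, abs=1e-8)

    def test_agreement_with_permutation_oracle(self, rng):
        a = rng.normal(0.8, 1.0, 8)
        b = rng.normal(0.0, 1.0, 7)
        res = gs.welch_ttest(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(np.mean(a) - np.mean(b))
        count = 0
        n_perm = 10000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += abs(np.mean(perm[:8]) - np.mean(perm[8:])) >= obs
        assert res.pvalue == pytest.approx(count / n_perm, abs=0.02)

    def test_tiny_group_rejected(self):
        with pytest.raises(NirsconnError):
            gs.welch_ttest([1.0], [1.0, 2.0])


class TestCombinedMean:
    @pytest.mark.parametrize("var,expected", [
        ("stai", 85.5), ("iq", 83.0), ("cigarettes", 21.5),
        ("smoking_years", 31.3), ("education", 6.4),
    ])
    def test_published_weighted_means(self, var, expected):
        hd = (reference.COHORT_SUMMARY[var]["HD"][0], reference.N_HD)
        cg = (reference.COHORT_SUMMARY[var]["CG"][0], reference.N_CG)
        assert gs.combined_mean(hd, cg) == pytest.approx(expected, abs=0.05)

    def test_equal_means_unchanged(self):
        assert gs.combined_mean((4.2, 5), (4.2, 9)) == pytest.approx(4.2)


def bf_step_up(p, q):
    """Literal Benjamini-Hochberg definition as the oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBHFDR:
    def test_hand_enumerated_example(self):
        qvals, reject = gs.bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.10)
        assert list(reject) == [True, True, True, False]
        assert np.all(qvals >= [0.01, 0.02, 0.03, 0.5])

    def test_all_zero_rejected(self):
        _, reject = gs.bh_fdr([0.0, 0.0, 0.0], q=0.05)
        assert reject.all()

    def test_single_p_reduces_to_threshold(self):
        assert gs.bh_fdr([0.04], q=0.05)[1][0]
        assert not gs.bh_fdr([0.06], q=0.05)[1][0]

    def test_empty_input(self):
        qvals, reject = gs.bh_fdr([], q=0.1)
        assert qvals.size == 0 and reject.size == 0

    def test_matches_step_up_oracle_on_random_families(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 11))
            p = rng.uniform(0, 1, m) ** 2
            _, reject = gs.bh_fdr(p, q=0.10)
            assert list(reject) == list(bf_step_up(p, 0.10))

    def test_qvalues_dominate_pvalues(self, rng):
        p = rng.uniform(0, 1, 20)
        qvals, _ = gs.bh_fdr(p, q=0.10)
        assert np.all(qvals >= p - 1e-12)


class TestAnxietyRegression:
    def _cohort(self, rng, slope, n=15, noise_sd=3.0):
        z = rng.uniform(0.2, 1.2, n)
        df = pd.DataFrame({
            "group": ["HD"] * 8 + ["CG"] * (n - 8),
            "age": rng.normal(46, 6, n),
            "iq": rng.normal(83, 10, n),
            "education": rng.normal(6.4, 2.5, n),
            "cigarettes": rng.normal(21, 10, n),
            "z_11_6": z,
            "z_11_1": rng.uniform(0.2, 1.2, n),
            "stai": 70 + slope * z + rng.normal(0, noise_sd, n),
        })
        return df

    def test_recovers_planted_slope(self, rng):
        df = self._cohort(rng, slope=20.0)
        out = gs.regress_anxiety_on_connectivity(df, 11, [6, 1])
        est, se = out.loc[6, "estimate"], out.loc[6, "se"]
        assert abs(est - 20.0) < 2 * se
        assert out.loc[6, "significant"]

    def test_orthogonal_connectivity_gives_null_coefficient(self, rng):
        df = self._cohort(rng, slope=0.0, noise_sd=0.0)
        df["stai"] = 70.0 + df["age"] * 0.0  # constant + exact covariates only
        df["stai"] += rng.normal(0, 1e-9, len(df))
        out = gs.regress_anxiety_on_connectivity(df, 11, [6])
        assert abs(out.loc[6, "estimate"]) < 1e-6

    def test_zero_variance_covariate_raises(self, rng):
        df = self._cohort(rng, slope=5.0)
        df["iq"] = 100.0
        with pytest.raises(EstimationError):
            gs.regress_anxiety_on_connectivity(df, 11, [6])

    def test_collinear_design_names_offender(self, rng):
        df = self._cohort(rng, slope=5.0)
        df["iq"] = 2.0 * df["age"] + 1.0
        with pytest.raises(EstimationError, match="age"):
            gs.regress_anxiety_on_connectivity(df, 11, [6])

    def test_missing_edge_column_rejected(self, rng):
        df = self._cohort(rng, slope=5.0)
        with pytest.raises(NirsconnError):
            gs.regress_anxiety_on_connectivity(df, 11, [99])


class TestNodalStrengthComparison:
    def test_identical_groups_nonsignificant(self, rng):
        strengths = pd.DataFrame(
            rng.normal(0.5, 0.05, (10, 12)), index=[f"S{i}" for i in range(10)],
            columns=range(1, 13))
        groups = pd.Series(["HD"] * 5 + ["CG"] * 5, index=strengths.index)
        out = gs.compare_nodal_strength(strengths, groups)
        # no planted difference: nothing should be strongly significant
        assert (out["p"] < 0.05).sum() <= 1
        assert (out["p"] > 0.001).all()

    def test_planted_shift_detected(self, rng):
        """A uniform +0.2 strength shift in one group is flagged on most
        channels across replicates."""
        hits, total = 0, 0
        for _ in range(20):
            hd = rng.normal(0.5, 0.05, (8, 12)) + 0.2
            cg = rng.normal(0.5, 0.05, (7, 12))
            strengths = pd.DataFrame(
                np.vstack([hd, cg]),
                index=[f"S{i}" for i in range(15)], columns=range(1, 13))
            groups = pd.Series(["HD"] * 8 + ["CG"] * 7, index=strengths.index)
            out = gs.compare_nodal_strength(strengths, groups)
            hits += int((out["p"] < 0.05).sum())
            total += 12
        assert hits >= 0.8 * total

    def test_one_record_per_channel_and_masked_nan(self, rng):
        strengths = pd.DataFrame(rng.normal(0.5, 0.1, (6, 4)),
                                 index=[f"S{i}" for i in range(6)],
                                 columns=[1, 2, 3, 4])
        strengths.loc[:, 3] = np.nan
        groups = pd.Series(["HD"] * 3 + ["CG"] * 3, index=strengths.index)
        out = gs.compare_nodal_strength(strengths, groups)
        assert len(out) == 4
        assert np.isnan(out.loc[3, "p"])


class TestDemographicTable:
    def test_full_table_recomputation(self):
        table = gs.demographic_table(reference.COHORT_SUMMARY,
                                     reference.N_HD, reference.N_CG)
        assert table.loc["stai", "all_mean"] == pytest.approx(85.5, abs=0.05)
        assert table.loc["stai", "p"] == pytest.approx(0.047, abs=0.005)
        assert table.loc["age", "p"] == pytest.approx(0.58, abs=0.005)
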