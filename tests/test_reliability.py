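import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from screencut.cohorts import PairedCohort, ScaleSpec
from screencut.reliability import (
    DegenerateDataError,
    change_metrics,
    icc_absolute_agreement,
    icc_from_paired,
    pairs_from_items,
    sdc_from_sem,
    subscale_reliability,
    two_way_anova,
)
from screencut.synthetic import RetestSpec, generate_retest


def paired_from_matrix(data, dataset_id="m"):
    data = np.asarray(data)
    big = ScaleSpec(n_items=1, item_min=-1000, item_max=1000)
    ids = np.array([f"s{i}" for i in range(len(data))], dtype=object)
    return PairedCohort(dataset_id, ids, data[:, 0], data[:, 1], big)


class TestAnova:
    def test_hand_worked_three_subjects(self):
        an = two_way_anova(np.array([[1, 2], [3, 4], [5, 6]], float))
        assert an.ms_rows == pytest.approx(8.0)
        assert an.ms_cols == pytest.approx(1.5)
        assert an.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns(self):
        an = two_way_anova(np.array([[1, 1], [4, 4], [9, 9]], float))
        assert an.ms_cols == pytest.approx(0.0, abs=1e-12)
        assert an.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_matches_general_purpose_anova(self):
        rng = np.random.default_rng(0)
        data = rng.normal(30, 5, size=(50, 2))
        an = two_way_anova(data)
        # independent oracle: statsmodels two-way ANOVA on the long layout
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "subj": np.repeat(np.arange(50), 2).astype(str),
                "col": np.tile(["a", "b"], 50),
            }
        )
        tab = sm.stats.anova_lm(ols("y ~ C(subj) + C(col)", data=long).fit(), typ=2)
        assert an.ms_rows == pytest.approx(
            tab.loc["C(subj)", "sum_sq"] / tab.loc["C(subj)", "df"], abs=1e-10
        )
        assert an.ms_cols == pytest.approx(
            tab.loc["C(col)", "sum_sq"] / tab.loc["C(col)", "df"], abs=1e-10
        )
        assert an.ms_error == pytest.approx(
            tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"], abs=1e-10
        )

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDataError):
            two_way_anova(np.array([[1, 2], [3, 4]], float))


class TestICC:
    def test_plug_in_arithmetic(self):
        an = two_way_anova(np.array([[1, 2], [3, 4], [5, 6]], float))
        rep = icc_absolute_agreement(an)
        assert rep.icc_a1 == pytest.approx(8 / 9)

    def test_perfect_agreement(self):
        rep = icc_from_paired(paired_from_matrix([[1, 1], [5, 5], [9, 9], [2, 2]]))
        assert rep.icc_a1 == pytest.approx(1.0)
        assert rep.icc_a2 == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        spec = RetestSpec(n=80, true_icc=0.8, mean=33.0, sd_between=8.0, seed=5)
        paired = generate_retest(spec)
        mine = icc_from_paired(paired)
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(len(paired)), 2),
                "rater": np.tile([1, 2], len(paired)),
                "score": paired.matrix().ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="score")
        ref = ref.set_index("Type")
        assert mine.icc_a1 == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert mine.icc_a2 == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-10)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert mine.icc_a1_ci[0] == pytest.approx(lo, abs=5e-3)
        assert mine.icc_a1_ci[1] == pytest.approx(hi, abs=5e-3)

    def test_average_measure_gains_over_single(self, suite):
        rep = icc_from_paired(suite.paired)
        assert rep.icc_a2 >= rep.icc_a1
        assert rep.icc_a1_ci[0] <= rep.icc_a1 <= rep.icc_a1_ci[1]
        assert rep.icc_a2_ci[0] <= rep.icc_a2 <= rep.icc_a2_ci[1]

    def test_mean_shift_strictly_lowers_absolute_agreement(self):
        spec = RetestSpec(n=200, true_icc=0.9, mean=33.0, sd_between=8.0, seed=2)
        base = icc_from_paired(generate_retest(spec))
        shifted_pair = generate_retest(spec)
        big = ScaleSpec(n_items=1, item_min=-1000, item_max=1000)
        shifted = PairedCohort(
            "s",
            shifted_pair.participant_ids,
            shifted_pair.scores_t1,
            shifted_pair.scores_t2 + 5,
            big,
        )
        rep = icc_from_paired(shifted)
        assert rep.icc_a1 < base.icc_a1
        # a consistency-type ICC (Pearson r here, k=2) is unchanged by the shift
        r_base = np.corrcoef(shifted_pair.scores_t1, shifted_pair.scores_t2)[0, 1]
        r_shift = np.corrcoef(shifted.scores_t1, shifted.scores_t2)[0, 1]
        assert r_shift == pytest.approx(r_base, abs=1e-12)

    def test_invariance_to_relabelling_and_common_shift(self):
        spec = RetestSpec(n=100, true_icc=0.85, mean=33.0, sd_between=8.0, seed=3)
        paired = generate_retest(spec)
        base = icc_from_paired(paired).icc_a1
        perm = np.random.default_rng(0).permutation(len(paired))
        big = ScaleSpec(n_items=1, item_min=-1000, item_max=1000)
        shuffled = PairedCohort(
            "p",
            paired.participant_ids[perm],
            paired.scores_t1[perm],
            paired.scores_t2[perm],
            big,
        )
        both_shifted = PairedCohort(
            "q", paired.participant_ids, paired.scores_t1 + 7, paired.scores_t2 + 7, big
        )
        assert icc_from_paired(shuffled).icc_a1 == pytest.approx(base, abs=1e-12)
        assert icc_from_paired(both_shifted).icc_a1 == pytest.approx(base, abs=1e-12)

    def test_interpretation_bands(self):
        an = two_way_anova(np.array([[1, 2], [3, 4], [5, 6]], float))
        assert icc_absolute_agreement(an).interpretation_band == "good"  # 0.889


class TestChangeMetrics:
    def test_sem_chain_from_published_inputs(self):
        cm = change_metrics(sd_t1=7.97, icc_a1=0.884, n=462)
        assert cm.sem == pytest.approx(2.71, abs=0.005)
        # the published smallest-detectable-change chain starts from the
        # SEM rounded for report (2.71), not the full-precision value
        sdc_ind, sdc_grp = sdc_from_sem(2.71, n=462)
        assert sdc_ind == pytest.approx(7.51, abs=0.005)
        assert sdc_grp == pytest.approx(0.35, abs=0.005)

    def test_perfect_reliability_means_no_detectable_change_floor(self):
        cm = change_metrics(sd_t1=8.0, icc_a1=1.0, n=100)
        assert cm.sem == 0.0 and cm.sdc_individual == 0.0 and cm.sdc_group == 0.0

    def test_sem_never_exceeds_sd(self):
        for icc in (0.0, 0.3, 0.884, 1.0):
            assert change_metrics(8.0, icc, 10).sem <= 8.0

    def test_negative_icc_refused(self):
        with pytest.raises(ValueError):
            change_metrics(8.0, -0.1, 10)


class TestSubscales:
    def test_single_subscale_identical_to_total(self, suite):
        table = subscale_reliability({"total": suite.paired})
        single = table[table.measure == "single"].iloc[0]
        assert single["icc"] == pytest.approx(icc_from_paired(suite.paired).icc_a1)

    def test_two_subscales_recovered_in_order(self):
        specs = {
            "stable": RetestSpec(n=462, true_icc=0.90, mean=20, sd_between=5.0, seed=8,
                                 scale=ScaleSpec(n_items=7)),
            "noisy": RetestSpec(n=462, true_icc=0.65, mean=9, sd_between=2.5, seed=9,
                                scale=ScaleSpec(n_items=3)),
        }
        pairs = {k: generate_retest(s) for k, s in specs.items()}
        table = subscale_reliability(pairs).set_index(["scale", "measure"])
        assert table.loc[("stable", "single"), "icc"] > table.loc[("noisy", "single"), "icc"]

    def test_pairs_from_items_applies_subscale_map(self):
        scale = ScaleSpec(
            subscale_map={
                "beliefs": tuple(range(1, 8)),
                "deliberation": (8, 9, 10),
                "pain": (11, 12, 13),
            }
        )
        rng = np.random.default_rng(4)
        t1 = pd.DataFrame(rng.integers(1, 6, (30, 13)), columns=[f"q{i}" for i in range(1, 14)])
        t2 = pd.DataFrame(rng.integers(1, 6, (30, 13)), columns=[f"q{i}" for i in range(1, 14)])
        ids = np.array([f"p{i}" for i in range(30)], dtype=object)
        pairs = pairs_from_items(ids, t1, t2, scale)
        assert set(pairs) == {"total", "beliefs", "deliberation", "pain"}
        np.testing.assert_array_equal(
            pairs["total"].scores_t1,
            pairs["beliefs"].scores_t1
            + pairs["deliberation"].scores_t1
            + pairs["pain"].scores_t1,
        )

    def test_permuting_participants_leaves_iccs_unchanged(self, suite):
        base = subscale_reliability({"total": suite.paired})["icc"].tolist()
        perm = np.random.default_rng(1).permutation(len(suite.paired))
        shuffled = PairedCohort(
            "perm",
            suite.paired.participant_ids[perm],
            suite.paired.scores_t1[perm],
            suite.paired.scores_t2[perm],
            suite.paired.scale,
        )
        assert subscale_reliability({"total": shuffled})["icc"].tolist() == pytest.approx(base)
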