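import numpy as np
import pandas as pd
import pytest

from screencut.cohorts import CohortDataset, ScaleSpec
from screencut.cutoffs import (
    NoAdmissibleCutoffError,
    YoudenProfile,
    admissible_set,
    iu_profile,
    near_optimal_plateau,
    per_dataset_optimal_table,
    transportable_cutoff,
    youden_profile,
)
from screencut.roc import confusion_at_cutoff, empirical_roc

from conftest import PUBLISHED_AT_35, PUBLISHED_AUC, random_cohort


def profile_from(j_map):
    jmax = max(j_map.values())
    return YoudenProfile(
        dataset_id="x",
        j_by_cutoff=j_map,
        jmax_cutoff=min(c for c, j in j_map.items() if j == jmax),
        jmax_value=jmax,
    )


def negatives_with_specificity(sp34, sp35, n_neg=100, dataset_id="k"):
    """Cohort whose negatives hit exact specificities at cut-offs 34 and 35."""
    below34 = int(round(sp34 * n_neg))
    at34 = int(round(sp35 * n_neg)) - below34
    above = n_neg - below34 - at34
    neg_scores = [20] * below34 + [34] * at34 + [50] * above
    scores = np.array(neg_scores + [60, 61])
    outcomes = np.array([0] * n_neg + [1, 1])
    ids = np.array([f"{dataset_id}{i}" for i in range(len(scores))], dtype=object)
    return CohortDataset(dataset_id, ids, scores, outcomes, ScaleSpec())


class TestYoudenProfile:
    def test_tie_break_prefers_lower_cutoff(self):
        cohort = negatives_with_specificity(0.5, 0.5)
        # positives far above all negatives: several cut-offs tie at J = 1
        prof = youden_profile(cohort)
        ties = [c for c, j in prof.j_by_cutoff.items() if j == prof.jmax_value]
        assert prof.jmax_cutoff == min(ties)

    def test_perfect_separation_jmax_one(self, tiny_cohort):
        prof = youden_profile(tiny_cohort)
        assert prof.jmax_value == 1.0
        assert prof.jmax_cutoff == 35  # smallest c above every negative score

    @pytest.mark.parametrize("seed", range(8))
    def test_jmax_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng, n=70)
        prof = youden_profile(cohort)
        best_j, best_c = -2.0, None
        for c in range(13, 67):
            tp, fp, tn, fn = confusion_at_cutoff(cohort, c)
            j = tp / (tp + fn) + tn / (tn + fp) - 1
            if j > best_j + 1e-15:
                best_j, best_c = j, c
        assert prof.jmax_cutoff == best_c
        assert prof.jmax_value == pytest.approx(best_j, abs=1e-12)


class TestPlateau:
    def test_threshold_example(self):
        prof = profile_from(
            {33: 0.75, 34: 0.805, 35: 0.809, 36: 0.806, 37: 0.811, 38: 0.812, 39: 0.79}
        )
        assert near_optimal_plateau(prof, 0.01) == (34, 35, 36, 37, 38)

    def test_all_equal_gives_full_candidate_set(self):
        prof = profile_from({c: 0.5 for c in range(30, 40)})
        assert near_optimal_plateau(prof, 0.01) == tuple(range(30, 40))

    def test_epsilon_zero_is_argmax_set(self):
        prof = profile_from({34: 0.7, 35: 0.71, 36: 0.71, 37: 0.6})
        assert near_optimal_plateau(prof, 0.0) == (35, 36)


class TestAdmissibleSet:
    def test_majority_specificity_floor(self):
        sp = pd.DataFrame(
            {
                f"k{i}": [a, b]
                for i, (a, b) in enumerate(
                    zip(
                        (0.70, 0.72, 0.74, 0.76, 0.80),
                        (0.76, 0.77, 0.74, 0.80, 0.72),
                    )
                )
            },
            index=[34, 35],
        )
        admissible, table = admissible_set([34, 35], None, tau=0.75, sp_table=sp)
        assert admissible == (35,)
        assert table.loc[34].sum() == 2  # 2/5 cohorts pass at 34
        assert table.loc[35].sum() == 3

    def test_cohort_path_counts_like_table_path(self):
        cohorts = [
            negatives_with_specificity(a, b, dataset_id=f"k{i}")
            for i, (a, b) in enumerate(zip((0.70, 0.74, 0.80), (0.74, 0.80, 0.84)))
        ]
        admissible, table = admissible_set([34, 35], cohorts, tau=0.75)
        assert admissible == (35,)  # 34 passes in only 1/3 of cohorts
        assert table.loc[35].tolist() == [False, True, True]

    def test_single_cohort_majority(self):
        cohort = negatives_with_specificity(0.80, 0.90)
        admissible, _ = admissible_set([34], [cohort], tau=0.75)
        assert admissible == (34,)  # 1/1 > 1/2

    def test_tau_zero_admits_whole_plateau(self):
        cohort = negatives_with_specificity(0.10, 0.20)
        admissible, _ = admissible_set([34, 35], [cohort], tau=0.0)
        assert admissible == (34, 35)


class TestTransportableCutoff:
    def test_degenerates_to_youden_optimum(self, suite):
        cohort = suite.cohorts[0]
        sel = transportable_cutoff(cohort, [cohort], epsilon=0.0, tau=0.0)
        assert sel.c_star == youden_profile(cohort).jmax_cutoff

    def test_c_star_in_plateau_and_admissible(self, suite):
        sel = transportable_cutoff(suite.cohorts[0], suite.cohorts)
        assert sel.c_star in sel.plateau
        assert sel.c_star in sel.admissible
        assert sel.c_star == min(sel.admissible)

    def test_removing_floor_never_raises_c_star(self, suite):
        sel = transportable_cutoff(suite.cohorts[0], suite.cohorts)
        no_floor = transportable_cutoff(suite.cohorts[0], suite.cohorts, tau=0.0)
        assert no_floor.c_star <= sel.c_star

    def test_delta_j_of_derivation_within_epsilon(self, suite):
        sel = transportable_cutoff(suite.cohorts[0], suite.cohorts)
        j = sel.profile.j_by_cutoff
        assert j[sel.profile.jmax_cutoff] - j[sel.c_star] <= sel.epsilon + 1e-12

    def test_floor_failing_everywhere_is_explicit(self, suite):
        with pytest.raises(NoAdmissibleCutoffError) as err:
            transportable_cutoff(suite.cohorts[0], suite.cohorts, tau=1.0)
        assert err.value.plateau  # decision trail carried on the error
        assert not err.value.floor_table.empty


class TestIndexOfUnion:
    def test_single_point_arithmetic(self):
        # |0.935 - 0.960| + |0.874 - 0.960| = 0.025 + 0.086
        rates = pd.DataFrame(
            {"dataset": ["d"], "cutoff": [35], "sensitivity": [0.935], "specificity": [0.874]}
        )
        prof = iu_profile(None, [35], rates=rates, auc_targets={"d": 0.960})
        assert prof.per_dataset.loc[35, "d"] == pytest.approx(0.111, abs=1e-12)

    def test_zero_when_margins_equal_auc(self):
        rates = pd.DataFrame(
            {"dataset": ["d"], "cutoff": [35], "sensitivity": [0.9], "specificity": [0.9]}
        )
        prof = iu_profile(None, [35], rates=rates, auc_targets={"d": 0.9})
        assert prof.per_dataset.loc[35, "d"] == 0.0

    def test_aggregate_from_published_rates_table(self):
        rows = [
            {"dataset": ds, "cutoff": 35, "sensitivity": se, "specificity": sp}
            for ds, (_, se, sp) in PUBLISHED_AT_35.items()
        ]
        prof = iu_profile(
            None, [35], rates=pd.DataFrame(rows), auc_targets=PUBLISHED_AUC
        )
        # equal-weight *sum* (not mean) of the five per-dataset values
        assert prof.iu_agg[35] == pytest.approx(0.661, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_minima_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        cohorts = [random_cohort(rng, n=60, dataset_id=f"c{i}") for i in range(3)]
        cand = list(range(25, 50))
        prof = iu_profile(cohorts, cand)
        for cohort in cohorts:
            roc = empirical_roc(cohort, np.asarray(cand))
            a = roc.auc
            best = min(
                roc.points,
                key=lambda p: (abs(p.se - a) + abs(p.sp - a), abs(p.se - p.sp), p.cutoff),
            )
            assert prof.per_dataset_minima[cohort.dataset_id] == best.cutoff
        # aggregate argmin: exhaustive scan with the same cascade
        agg = prof.iu_agg
        ws = prof.weights
        se_sum = {}
        sp_sum = {}
        for c in cand:
            se_sum[c] = sum(
                ws[k.dataset_id] * empirical_roc(k, np.asarray(cand)).point_at(c).se
                for k in cohorts
            )
            sp_sum[c] = sum(
                ws[k.dataset_id] * empirical_roc(k, np.asarray(cand)).point_at(c).sp
                for k in cohorts
            )
        expected = min(cand, key=lambda c: (agg[c], abs(se_sum[c] - sp_sum[c]), c))
        assert prof.iu_agg_argmin == expected


class TestOptimalVsFixedTable:
    def test_delta_j_nonnegative_and_zero_at_own_optimum(self, suite):
        sel = transportable_cutoff(suite.cohorts[0], suite.cohorts)
        table = per_dataset_optimal_table(suite.cohorts, sel.c_star)
        assert (table["delta_j"] >= -1e-12).all()
        own = table[table["optimal_cutoff"] == sel.c_star]
        assert (own["delta_j"].abs() < 1e-12).all()
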