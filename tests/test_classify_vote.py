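"""Vote aggregation, grouped CV, subgroup selection and the learner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voicedep import (
    SubgroupError,
    TrainConfig,
    VoteVector,
    aggregate_votes,
    fuse_self_report,
    generate_cohort,
    grouped_kfold,
    run_cv_experiment,
    select_lh_subgroup,
    train_chunk_classifier,
)
from voicedep import CohortSpec, cohort_feature_table
from voicedep.classify_vote import predict_chunks
from voicedep.evaluation import ConfusionCounts, metrics


def brute_force_vote(c, tau):
    """Independent oracle: literal count against the capped threshold."""
    return 1 if sum(c) >= min(tau, len(c)) else 0


class TestAggregateVotes:
    def test_formula_forced_cases(self):
        assert aggregate_votes(np.array([1, 1, 1, 0, 0]), tau=3) == 1
        assert aggregate_votes(np.array([1, 1, 1, 0, 0]), tau=4) == 0
        assert aggregate_votes(np.zeros(6, int), tau=1) == 0

    def test_cap_rule_for_short_vote_vectors(self):
        assert aggregate_votes(np.array([1, 1]), tau=4) == 1
        assert aggregate_votes(np.array([1, 0]), tau=4) == 0

    def test_exhaustive_agreement_with_brute_force(self):
        for r in range(1, 7):
            for bits in range(2**r):
                c = [(bits >> j) & 1 for j in range(r)]
                for tau in range(1, 7):
                    assert aggregate_votes(np.array(c), tau) == brute_force_vote(c, tau)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aggregate_votes(np.array([], dtype=int), 1)
        with pytest.raises(ValueError):
            aggregate_votes(np.array([1, 0]), 0)
        with pytest.raises(ValueError):
            VoteVector("P", np.array([2, 0]))

    @given(
        c=st.lists(st.integers(0, 1), min_size=1, max_size=12),
        tau=st.integers(1, 12),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_oracle_property(self, c, tau):
        assert aggregate_votes(np.array(c), tau) == brute_force_vote(c, tau)


def test_tau_monotone_sensitivity_specificity():
    """For fixed chunk predictions, raising tau never raises sensitivity and
    never lowers specificity (exhaustive over all vote vectors with r <= 6)."""
    rng = np.random.default_rng(0)
    patients = []
    for r in range(1, 7):
        for bits in range(2**r):
            c = np.array([(bits >> j) & 1 for j in range(r)])
            patients.append((c, int(rng.integers(2))))
    prev_sens, prev_spec = None, None
    for tau in range(1, 7):
        y_true = np.array([y for _, y in patients])
        y_pred = np.array([aggregate_votes(c, tau) for c, _ in patients])
        m = metrics(ConfusionCounts.from_labels(y_true, y_pred))
        if prev_sens is not None:
            assert m["sensitivity"] <= prev_sens + 1e-12
            assert m["specificity"] >= prev_spec - 1e-12
        prev_sens, prev_spec = m["sensitivity"], m["specificity"]


class TestLhSubgroup:
    def _cohort(self):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(6)],
                "gender": ["F", "F", "F", "F", "M", "M"],
                "suds": [5, 9, 1, 10, 9, 1],
                "depressed": [1, 1, 0, 1, 1, 0],
            }
        )

    def test_filter_rules(self):
        lh = select_lh_subgroup(self._cohort())
        assert set(lh["patient_id"]) == {"P1", "P2", "P3"}  # F with SUDs 1/9/10

    def test_share_arithmetic_on_published_group_sizes(self):
        # 52 of 123 women sit in the extreme-SUDs tails -> 42.3%
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(123)],
                "gender": ["F"] * 123,
                "suds": [1] * 26 + [9] * 26 + [5] * 71,
                "depressed": [0] * 26 + [1] * 26 + [1] * 71,
            }
        )
        share = len(select_lh_subgroup(df)) / len(df)
        assert round(100 * share, 1) == 42.3

    def test_empty_selection_raises(self):
        df = self._cohort()
        df["suds"] = 5
        with pytest.raises(SubgroupError):
            select_lh_subgroup(df)


class TestGroupedKfold:
    def _cohort(self, n, prevalence=0.5, seed=0):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, int)
        y[: int(round(n * prevalence))] = 1
        rng.shuffle(y)
        return pd.DataFrame(
            {"patient_id": [f"P{i:03d}" for i in range(n)], "depressed": y}
        )

    def test_52_patients_3_folds_published_split_sizes(self):
        cohort = self._cohort(52)
        folds = grouped_kfold(cohort, 3, seed=1)
        test_sizes = sorted(len(te) for _, te in folds)
        train_sizes = sorted(len(tr) for tr, _ in folds)
        assert test_sizes == [17, 17, 18]
        assert train_sizes == [34, 35, 35]

    def test_no_patient_leakage_and_full_coverage(self):
        cohort = self._cohort(37, prevalence=0.6)
        folds = grouped_kfold(cohort, 4, seed=2)
        seen = []
        for tr, te in folds:
            assert set(tr) & set(te) == set()
            seen.extend(te)
        assert sorted(seen) == sorted(cohort["patient_id"])

    def test_stratification(self):
        cohort = self._cohort(52)
        labels = cohort.set_index("patient_id")["depressed"]
        for _, te in grouped_kfold(cohort, 3, seed=3):
            prev = labels.loc[te].mean()
            assert abs(prev - 0.5) <= 1.0 / len(te)

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(self._cohort(3), 5)


def _chunk_table(n_patients, n_chunks, informative, seed=0, prevalence=0.5,
                 separation=2.5):
    """Small synthetic chunk table without audio."""
    rng = np.random.default_rng(seed)
    y_patient = np.zeros(n_patients, int)
    y_patient[: int(round(n_patients * prevalence))] = 1
    rng.shuffle(y_patient)
    rows = []
    for i in range(n_patients):
        for j in range(n_chunks):
            x = rng.standard_normal(3)
            if informative:
                x[0] += separation * y_patient[i]
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "chunk_index": j,
                    "feat_a": x[0],
                    "feat_b": x[1],
                    "feat_c": x[2],
                    "label": y_patient[i],
                }
            )
    table = pd.DataFrame(rows)
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n_patients)],
            "gender": "F",
            "depressed": y_patient,
            "suds": np.where(y_patient == 1, 9, 1),
            "phq15": 10,
        }
    )
    return table, cohort


class TestChunkClassifier:
    def test_separable_table_fits_perfectly(self):
        table, _ = _chunk_table(20, 4, informative=True, separation=10.0)
        model = train_chunk_classifier(table, TrainConfig())
        assert (predict_chunks(model, table) == table["label"]).mean() == 1.0

    def test_single_class_rejected(self):
        table, _ = _chunk_table(10, 3, informative=False)
        table["label"] = 1
        with pytest.raises(ValueError):
            train_chunk_classifier(table, TrainConfig())

    def test_label_permutation_stays_near_baseline(self):
        table, cohort = _chunk_table(40, 5, informative=True, seed=4)
        rng = np.random.default_rng(5)
        perm = rng.permutation(cohort["depressed"].to_numpy())
        cohort["depressed"] = perm
        labels = cohort.set_index("patient_id")["depressed"]
        table["label"] = labels.loc[table["patient_id"]].to_numpy()
        rep = run_cv_experiment(
            table.drop(columns="label"), cohort, TrainConfig(ks=(3,), taus=(2,), seed=6)
        )
        sigma_prime = np.sqrt(0.25 / (40 / 3)) / np.sqrt(3)
        assert abs(rep["accuracy_mean"].iloc[0] - rep["baseline"].iloc[0]) <= 3 * sigma_prime

    def test_test_fold_labels_cannot_influence_predictions(self):
        table, _ = _chunk_table(30, 4, informative=True, seed=7)
        train = table[table["patient_id"] < "P020"]
        test = table[table["patient_id"] >= "P020"].copy()
        model = train_chunk_classifier(train, TrainConfig())
        before = predict_chunks(model, test)
        test["label"] = 1 - test["label"]  # shuffling test labels
        after = predict_chunks(model, test)
        assert np.array_equal(before, after)


class TestFuseSelfReport:
    def test_adds_exactly_one_constant_column(self):
        table, cohort = _chunk_table(8, 3, informative=False)
        fused = fuse_self_report(table, cohort, use_suds=True)
        assert fused.shape[1] == table.shape[1] + 1
        for _, grp in fused.groupby("patient_id"):
            assert grp["suds"].nunique() == 1

    def test_missing_scores_rejected(self):
        table, cohort = _chunk_table(8, 3, informative=False)
        with pytest.raises(ValueError):
            fuse_self_report(table, cohort.drop(columns="suds"), use_suds=True)

    def test_suds_only_model_is_accurate_on_lh_cohort(self):
        """A classifier given only the SUDs self-report separates the
        extreme-SUDs (LH) subgroup well, as the strong SUDs-label
        correlation implies."""
        _, cohort = generate_cohort(
            CohortSpec(n_patients=300, female_fraction=1.0, prevalence=0.64, seed=19)
        )
        lh = select_lh_subgroup(cohort)
        rows = [
            {"patient_id": pid, "chunk_index": j}
            for pid in lh["patient_id"]
            for j in range(5)
        ]
        table = pd.DataFrame(rows)
        config = TrainConfig(
            ks=(2,), taus=(3,), subgroup="lh", fuse_suds=True,
            feature_columns=["suds"], seed=8,
        )
        rep = run_cv_experiment(table, cohort, config)
        assert rep["accuracy_mean"].iloc[0] >= 0.8


def test_effect_size_monotonicity(vad_model):
    """A stronger injected depression effect does not lower cross-validated
    patient accuracy (3-seed averages)."""
    means = {}
    for effect in (0.4, 1.2):
        accs = []
        for seed in (0, 1, 2):
            spec = CohortSpec(
                n_patients=24, female_fraction=1.0, prevalence=0.5,
                effect_size=effect, seed=200 + seed,
            )
            recs, cohort = generate_cohort(spec)
            feats = cohort_feature_table(recs, spec, vad_model=vad_model)
            rep = run_cv_experiment(
                feats, cohort, TrainConfig(ks=(3,), taus=(2,), seed=seed)
            )
            accs.append(rep["accuracy_mean"].iloc[0])
        means[effect] = np.mean(accs)
    assert means[1.2] >= means[0.4] - 0.02


def test_strong_effect_cohort_beats_baseline_by_three_sigma(women200_report):
    rep = women200_report
    row = rep[rep["tau"] == 2].iloc[0]
    n_test = 200 / 3
    sigma_prime = np.sqrt(row["baseline"] * (1 - row["baseline"]) / n_test) / np.sqrt(3)
    assert row["accuracy_mean"] >= row["baseline"] + 3 * sigma_prime
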