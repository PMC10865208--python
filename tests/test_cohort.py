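"""Inclusion rules, ED/BD assembly, balanced evaluation split, z-scoring."""

import numpy as np
import pandas as pd
import pytest

from triage_enrich.cohort import (
    DEFAULT_ED_FLAGS,
    FeatureTable,
    PatientRecord,
    apply_inclusion,
    build_datasets,
    inclusion_summary,
    split_eval,
    zscore_by_split,
)
from triage_enrich.lexicon_nlp import ALL_CATEGORIES, PAG_CATEGORIES, RERE_CATEGORIES, ExtractionFlags

from conftest import make_table


def flags_of(*on):
    return ExtractionFlags(
        referral_reason={c: int(c in on) for c in RERE_CATEGORIES},
        patient_goal={c: int(c in on) for c in PAG_CATEGORIES},
    )


def record(pid, flags, label=1, q=None):
    return PatientRecord(
        patient_id=pid, questionnaire=q or {"q0": 1.0, "q1": 2.0}, flags=flags, label=label
    )


class TestInclusion:
    def test_mixed_fixture(self):
        records = (
            [record(f"N{i}", None) for i in range(2)]                  # no letter
            + [record("Z0", flags_of())]                               # letter, no category
            + [record(f"F{i}", flags_of("RehabReRe")) for i in range(7)]
        )
        kept = apply_inclusion(records)
        assert [r.patient_id for r in kept] == [f"F{i}" for i in range(7)]

    def test_only_patient_goal_retained(self):
        kept = apply_inclusion([record("P", flags_of("PainRedPaG"))])
        assert len(kept) == 1

    def test_all_flagless_empty(self):
        assert apply_inclusion([record("P", flags_of())]) == []

    def test_idempotent(self):
        records = [record("A", flags_of("AdviceReRe")), record("B", None)]
        once = apply_inclusion(records)
        assert apply_inclusion(once) == once

    def test_summary_percentages(self):
        records = (
            [record(f"N{i}", None) for i in range(2)]
            + [record("Z", flags_of())]
            + [record(f"F{i}", flags_of("RehabReRe")) for i in range(7)]
        )
        s = inclusion_summary(records)
        assert s["n_with_letter"] == 8
        assert s["n_included"] == 7
        assert s["pct_with_letter"] == pytest.approx(80.0)
        assert s["pct_included_of_letters"] == pytest.approx(87.5)


class TestBuildDatasets:
    def test_column_arithmetic(self):
        recs = [record(f"P{i}", flags_of("RehabReRe"), label=i % 4) for i in range(8)]
        ed, bd = build_datasets(recs, ed_flag_names=DEFAULT_ED_FLAGS)
        assert ed.features.shape[1] == 2 + 8
        assert bd.features.shape[1] == 2

    def test_empty_flag_list_gives_identical_tables(self):
        recs = [record(f"P{i}", flags_of()) for i in range(4)]
        ed, bd = build_datasets(recs, ed_flag_names=[])
        pd.testing.assert_frame_equal(ed.features, bd.features)

    def test_unknown_flag_name(self):
        with pytest.raises(KeyError, match="NotAFlag"):
            build_datasets([record("P", flags_of())], ed_flag_names=["NotAFlag"])

    def test_flags_never_missing_and_bd_matches_ed(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(30):
            q = {f"q{j}": (float("nan") if rng.uniform() < 0.3 else float(rng.normal()))
                 for j in range(5)}
            on = [c for c in ALL_CATEGORIES if rng.uniform() < 0.4]
            recs.append(record(f"P{i}", flags_of(*on), label=int(rng.integers(4)), q=q))
        ed, bd = build_datasets(recs)
        flag_cols = [c for c in ed.features.columns if c in ALL_CATEGORIES]
        assert not ed.features[flag_cols].isna().any().any()
        pd.testing.assert_frame_equal(ed.features[bd.features.columns], bd.features)


class TestSplitEval:
    def test_published_training_counts(self):
        counts = {1: 571, 2: 228, 3: 109, 0: 301}
        y = np.concatenate([np.full(n, c) for c, n in counts.items()])
        table = make_table(np.zeros((len(y), 2)), y)
        out = split_eval(table, per_class=50, seed=0)
        train_counts = {
            c: int(((out.labels == c) & (out.split == "train")).sum()) for c in counts
        }
        assert train_counts == {1: 521, 2: 178, 3: 59, 0: 251}
        assert int((out.split == "eval").sum()) == 200
        assert sum(train_counts.values()) == 1009

    def test_label_multiset_preserved(self):
        y = np.array([0] * 5 + [1] * 7 + [2] * 6 + [3] * 9)
        out = split_eval(make_table(np.zeros((len(y), 1)), y), per_class=3, seed=1)
        for c in range(4):
            n_train = ((out.labels == c) & (out.split == "train")).sum()
            n_eval = ((out.labels == c) & (out.split == "eval")).sum()
            assert n_train + n_eval == (y == c).sum()
            assert n_eval == 3

    def test_per_class_zero(self):
        out = split_eval(make_table(np.zeros((4, 1)), [0, 1, 2, 3]), per_class=0, seed=0)
        assert (out.split == "train").all()

    def test_deterministic(self):
        y = np.repeat([0, 1, 2, 3], 20)
        t = make_table(np.zeros((len(y), 1)), y)
        a = split_eval(t, per_class=5, seed=9)
        b = split_eval(t, per_class=5, seed=9)
        assert (a.split == b.split).all()

    def test_small_class_error_names_class(self):
        with pytest.raises(ValueError, match="class 3"):
            split_eval(make_table(np.zeros((5, 1)), [0, 0, 1, 1, 3]), per_class=2, seed=0)

    def test_ed_bd_share_rows(self):
        y = np.repeat([0, 1, 2, 3], 25)
        ed = make_table(np.zeros((100, 3)), y, condition="ED")
        bd = make_table(np.zeros((100, 1)), y, condition="BD")
        assert (split_eval(ed, 10, seed=4).split == split_eval(bd, 10, seed=4).split).all()


class TestZscore:
    def test_sample_convention_three_points(self):
        t = make_table([[1], [2], [3]], [0, 1, 0], split=["train"] * 3)
        out = zscore_by_split(t, sd_convention="sample")
        assert out.features["f0"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_population_convention_matches_sklearn_scaler(self):
        from sklearn.preprocessing import StandardScaler

        X = np.random.default_rng(0).normal(size=(20, 3))
        t = make_table(X, [0, 1] * 10, split=["train"] * 20)
        out = zscore_by_split(t, sd_convention="population")
        expected = StandardScaler().fit_transform(X)
        np.testing.assert_allclose(out.features.to_numpy(), expected, atol=1e-12)

    def test_constant_column_maps_to_zero(self):
        t = make_table([[5.0], [5.0], [5.0]], [0, 1, 0], split=["train"] * 3)
        out = zscore_by_split(t)
        assert (out.features["f0"] == 0).all()

    def test_per_split_means_are_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        split = ["train"] * 30 + ["eval"] * 10
        out = zscore_by_split(make_table(X, [0, 1] * 20, split=split))
        for tag in ("train", "eval"):
            block = out.features[np.asarray(split) == tag]
            assert np.abs(block.mean(axis=0)).max() < 1e-9

    def test_missing_entries_stay_missing(self):
        X = np.array([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0]])
        out = zscore_by_split(make_table(X, [0, 1, 0], split=["train"] * 3))
        assert np.isnan(out.features.iloc[0, 1])
        assert out.features.iloc[:, 0].notna().all()

    def test_train_params_mode_reuses_training_moments(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        split = ["train", "train", "eval", "eval"]
        out = zscore_by_split(make_table(X, [0, 1, 0, 1], split=split),
                              sd_convention="population", mode="train_params")
        # train mean 1, population sd 1 -> eval rows (10-1)/1, (12-1)/1
        assert out.features["f0"].tolist() == pytest.approx([-1, 1, 9, 11])


def test_feature_table_roundtrip_via_frame():
    t = make_table([[1.0, 2.0], [3.0, 4.0]], [0, 1], split=["train", "eval"])
    back = FeatureTable.from_frame(t.to_frame(), condition=t.condition)
    pd.testing.assert_frame_equal(back.features, t.features)
    assert (back.labels == t.labels).all()
    assert (back.split == t.split).all()
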