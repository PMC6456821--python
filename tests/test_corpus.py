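"""Corpus pipeline: occurrence coding, filters, GLMM fits, reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from motimsg.corpus import (
    CodedAnswer,
    build_occurrence,
    cohens_kappa,
    derive_length_table,
    derive_probability_table,
    filter_types,
    fit_type_model,
    lrt,
    read_corpus_csv,
    retain_statements,
    write_corpus_csv,
)
from motimsg.database import StatementType
from motimsg.simulate import ExpertSimSpec, simulate_expert_corpus
from motimsg.situations import Situation, enumerate_situations

RISING_LOW = Situation.parse("rising:low")

FOREST = [
    StatementType("note_pcl"),
    StatementType("note_pcl_rising", parent="note_pcl"),
    StatementType("note_pcl_stable", parent="note_pcl"),
    StatementType("empathy"),
]


def answer(expert, types, situation=RISING_LOW, answer_id="0"):
    return CodedAnswer(
        expert_id=expert,
        situation=situation,
        statements=tuple((f"{t} text", t) for t in types),
        answer_id=answer_id,
    )


def leaf_table(db):
    return {
        key: {n: p for n, p in row.items() if db.is_leaf(n)}
        for key, row in db.probabilities.items()
    }


class TestBuildOccurrence:
    def test_supertype_column_is_or_of_leaves(self):
        matrix = build_occurrence(
            [answer("e1", ["note_pcl_rising", "empathy"])], FOREST
        )
        row = matrix.data.iloc[0]
        assert row["note_pcl_rising"] == 1
        assert row["note_pcl"] == 1
        assert row["empathy"] == 1
        assert row["note_pcl_stable"] == 0

    def test_duplicate_type_within_answer_stays_binary(self):
        matrix = build_occurrence(
            [answer("e1", ["empathy", "empathy"])], FOREST
        )
        assert matrix.data.iloc[0]["empathy"] == 1
        assert matrix.instance_counts["empathy"] == 2

    def test_empty_corpus_and_unknown_type_raise(self):
        with pytest.raises(ValueError):
            build_occurrence([], FOREST)
        with pytest.raises(KeyError):
            build_occurrence([answer("e1", ["mystery"])], FOREST)


class TestFilterTypes:
    def make_matrix(self, counts):
        corpus = []
        for i, (name, count) in enumerate(counts.items()):
            for j in range(count):
                corpus.append(
                    answer(f"e{j}", [name], answer_id=f"{name}{j}")
                )
        return build_occurrence(corpus, FOREST)

    def test_boundary_keeps_ten_drops_nine(self):
        matrix = self.make_matrix({"empathy": 10, "note_pcl_rising": 9})
        filtered, fraction = filter_types(matrix, min_count=10)
        assert "empathy" in filtered.type_names
        assert "note_pcl_rising" not in filtered.type_names
        assert fraction == pytest.approx(10 / 19)

    def test_all_frequent_types_fully_retained(self):
        matrix = self.make_matrix({"empathy": 12, "note_pcl_rising": 15})
        _filtered, fraction = filter_types(matrix, min_count=10)
        assert fraction == 1.0


class TestFitTypeModel:
    def test_matches_cell_proportions_without_heterogeneity(self, default_db):
        spec = ExpertSimSpec(
            true_table=leaf_table(default_db),
            true_lengths=default_db.lengths,
            n_experts=50,
            answers_per_situation=4,
            intercept_sd=0.0,
            seed=11,
            force_lengths=False,
        )
        matrix = build_occurrence(
            simulate_expert_corpus(spec), default_db
        )
        for type_name in ("empathy", "give_perspective", "normalize"):
            fit = fit_type_model(matrix, type_name)
            observed = pd.DataFrame({
                "situation": matrix.situations.to_numpy(),
                "y": matrix.data[type_name].to_numpy(),
            }).groupby("situation")["y"].mean()
            for key, prop in observed.items():
                assert fit.probabilities[key] == pytest.approx(
                    prop, abs=0.02
                )

    def test_always_present_type_flags_separation(self):
        corpus = []
        for e in range(4):
            for s in enumerate_situations():
                corpus.append(answer(
                    f"e{e}", ["empathy"], situation=s, answer_id=s.key
                ))
        matrix = build_occurrence(corpus, FOREST)
        fit = fit_type_model(matrix, "empathy")
        assert all(p > 0.99 for p in fit.probabilities.values())
        assert not fit.converged


class TestDerivedTables:
    def test_probability_recovery_correlates_with_truth(self, default_db):
        truth = leaf_table(default_db)
        spec = ExpertSimSpec(
            true_table=truth,
            true_lengths=default_db.lengths,
            n_experts=200,
            answers_per_situation=2,
            intercept_sd=0.5,
            seed=29,
        )
        table = derive_probability_table(
            simulate_expert_corpus(spec), default_db, level="leaf"
        )
        pairs = [
            (truth[k][n], table[k][n])
            for k in truth
            for n in truth[k]
            if n in table[k]
        ]
        t, f = zip(*pairs)
        assert np.corrcoef(t, f)[0, 1] > 0.9

    def test_type_confined_to_one_situation_near_zero_elsewhere(self):
        corpus = []
        for e in range(12):
            for s in enumerate_situations():
                types = (
                    ["note_pcl_rising", "empathy"]
                    if s == RISING_LOW else ["empathy"]
                )
                corpus.append(answer(f"e{e}", types, s, s.key))
        table = derive_probability_table(corpus, FOREST, min_count=5)
        assert table[RISING_LOW.key]["note_pcl_rising"] > 0.9
        others = [
            row["note_pcl_rising"]
            for key, row in table.items()
            if key != RISING_LOW.key
        ]
        assert max(others) < 0.05

    @pytest.mark.parametrize(
        "counts, expected",
        [([3, 3, 4], 3), ([4, 3], 4), ([4, 4, 4], 4)],
    )
    def test_length_table_rounds_half_up(self, counts, expected):
        corpus = []
        for s in enumerate_situations():
            for i, count in enumerate(counts):
                corpus.append(answer(
                    "e1", ["empathy"] * count, s, f"{s.key}#{i}"
                ))
        table = derive_length_table(corpus)
        assert all(v == expected for v in table.values())

    def test_length_table_requires_every_situation(self):
        with pytest.raises(KeyError):
            derive_length_table([answer("e1", ["empathy"])])


class TestRetainStatements:
    TABLE = {
        s.key: {"empathy": 0.04, "note_pcl": 0.5, "note_pcl_rising": 0.04}
        for s in enumerate_situations()
    }

    def test_rare_type_statements_excluded(self):
        corpus = [answer("e1", ["empathy"])]
        assert retain_statements(corpus, self.TABLE, FOREST) == []

    def test_boundary_just_above_threshold_retained(self):
        table = {k: dict(v) for k, v in self.TABLE.items()}
        table[RISING_LOW.key]["empathy"] = 0.06
        kept = retain_statements(
            [answer("e1", ["empathy"])], table, FOREST
        )
        assert [s.type_name for s in kept] == ["empathy"]

    def test_supertype_probability_rescues_leaf(self):
        # note_pcl_rising is rare itself but its super clears the bar
        kept = retain_statements(
            [answer("e1", ["note_pcl_rising"])], self.TABLE, FOREST
        )
        assert [s.type_name for s in kept] == ["note_pcl_rising"]

    def test_zero_threshold_keeps_all_and_deduplicates(self):
        corpus = [
            answer("e1", ["empathy"]),
            answer("e2", ["empathy"]),
        ]
        kept = retain_statements(corpus, self.TABLE, FOREST, threshold=0.0)
        assert len(kept) == 1  # identical texts deduplicated


class TestCohensKappa:
    def test_perfect_agreement(self):
        result = cohens_kappa(list("AABB"), list("AABB"))
        assert result.kappa == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        # po equals pe by construction -> kappa 0
        a = ["A", "A", "B", "B"]
        b = ["A", "B", "A", "B"]
        result = cohens_kappa(a, b)
        assert result.kappa == pytest.approx(0.0)

    def test_known_confusion_table(self):
        a = ["A"] * 25 + ["B"] * 25
        b = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        result = cohens_kappa(a, b)
        po = 35 / 50
        pe = (25 / 50) * (30 / 50) + (25 / 50) * (20 / 50)
        assert result.kappa == pytest.approx((po - pe) / (1 - pe))
        assert result.observed_agreement == pytest.approx(po)
        assert result.expected_agreement == pytest.approx(pe)

    def test_length_mismatch_and_degenerate(self):
        with pytest.raises(ValueError):
            cohens_kappa(["A"], ["A", "B"])
        with pytest.raises(ZeroDivisionError):
            cohens_kappa(["A", "A"], ["A", "A"])

    @given(
        labels=st.lists(
            st.tuples(st.sampled_from("ABCDE"), st.sampled_from("ABCDE")),
            min_size=5,
            max_size=60,
        )
    )
    def test_matches_sklearn_oracle(self, labels):
        a, b = zip(*labels)
        try:
            ours = cohens_kappa(a, b).kappa
        except ZeroDivisionError:
            return  # sklearn returns nan here; undefined by contract
        theirs = cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestLRT:
    def test_identical_models_give_null_result(self):
        result = lrt(-100.0, 3, -100.0, 5)
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_critical_value_at_df_one(self):
        result = lrt(-100.0, 3, -98.08, 4)
        assert result.statistic == pytest.approx(3.84)
        assert result.p_value == pytest.approx(
            stats.chi2.sf(3.84, 1), abs=1e-12
        )
        assert result.p_value == pytest.approx(0.05, abs=1e-3)

    def test_inverted_nesting_rejected(self):
        with pytest.raises(ValueError):
            lrt(-100.0, 5, -90.0, 5)
        with pytest.raises(ValueError):
            lrt(-90.0, 3, -100.0, 5)


class TestCorpusCSV:
    def test_round_trip(self, tmp_path, default_db):
        spec = ExpertSimSpec(
            true_table=leaf_table(default_db),
            true_lengths=default_db.lengths,
            n_experts=3,
            seed=5,
        )
        corpus = simulate_expert_corpus(spec)
        path = tmp_path / "corpus.csv"
        write_corpus_csv(corpus, path)
        loaded = read_corpus_csv(path)
        assert loaded == corpus
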