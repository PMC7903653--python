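"""Pairwise similarity scores, intra-series profiles, random baselines and
the best-partner analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddsn.corpus import Disease, PhenotypicSeries, build_corpus
from ddsn.errors import ConfigurationError
from ddsn.ontology import compute_ic
from ddsn.similarity import (
    SimilarityScorer,
    intra_ps_profile,
    max_partner,
    partner_crosstab,
    partner_summary,
    random_baseline,
)

from ._oracles import (
    corpus_from,
    dag_from_parents,
    naive_score,
    random_annotations,
    random_parents,
)

LOG32 = math.log(3 / 2) / math.log(3)


@pytest.fixture(scope="module")
def fig1_scorer(fig1):
    return SimilarityScorer(fig1["dag"], fig1["ic"], fig1["annotations"])


class TestScorePair:
    def test_worked_example(self, fig1_scorer):
        assert fig1_scorer.score("A", "C") == pytest.approx(LOG32 / 2, abs=1e-12)
        assert fig1_scorer.score("A", "B") == pytest.approx(LOG32 / 2, abs=1e-12)
        assert fig1_scorer.score("B", "C") == 0.0
        # self-score under the all-pairs rule can stay below 1
        assert fig1_scorer.score("A", "A") == pytest.approx(
            (LOG32 + 0 + 0 + 1) / 4, abs=1e-12
        )

    def test_unannotated_disease_rejected(self, fig1_scorer):
        with pytest.raises(ConfigurationError):
            fig1_scorer.score("A", "nope")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(300 + seed)
        parents = random_parents(rng, 40)
        dag = dag_from_parents(parents)
        annotations = random_annotations(rng, parents, 10)
        ic = compute_ic(dag, annotations)
        scorer = SimilarityScorer(dag, ic, annotations)
        ids = sorted(annotations)
        for i in range(len(ids)):
            for j in range(i, len(ids)):
                expected = naive_score(
                    parents, ic.ic, annotations[ids[i]], annotations[ids[j]]
                )
                assert scorer.score(ids[i], ids[j]) == pytest.approx(
                    expected, abs=1e-12
                )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        parents = random_parents(rng, 25)
        dag = dag_from_parents(parents)
        annotations = random_annotations(rng, parents, 6)
        ic = compute_ic(dag, annotations)
        scorer = SimilarityScorer(dag, ic, annotations)
        ids = sorted(annotations)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                s = scorer.score(ids[i], ids[j])
                assert s == scorer.score(ids[j], ids[i])
                assert 0.0 <= s <= 1.0


class TestIntraPSProfile:
    def test_worked_example(self, fig1, fig1_scorer):
        diseases = {d: Disease(id=d) for d in fig1["annotations"]}
        corpus = build_corpus(
            diseases, fig1["series"], fig1["annotations"], fig1["ic"]
        )
        profile = intra_ps_profile(fig1_scorer, corpus, "PS1")
        assert profile.per_disease == {
            "A": pytest.approx(LOG32 / 2),
            "B": pytest.approx(LOG32 / 2),
        }
        with pytest.raises(ConfigurationError):
            intra_ps_profile(fig1_scorer, corpus, "PS2")  # singleton series

    def test_identical_annotations_score_term_ic(self, fig1):
        annotations = {"X": {"3"}, "Y": {"3"}}
        ic = compute_ic(fig1["dag"], annotations)
        scorer = SimilarityScorer(fig1["dag"], ic, annotations)
        diseases = {d: Disease(id=d) for d in annotations}
        series = {"P": PhenotypicSeries(id="P", members={"X", "Y"})}
        corpus = build_corpus(diseases, series, annotations, ic)
        profile = intra_ps_profile(scorer, corpus, "P")
        assert profile.per_disease["X"] == pytest.approx(ic["3"])

    def test_matches_pairwise_mean_oracle(self):
        rng = np.random.default_rng(7)
        parents = random_parents(rng, 30)
        dag = dag_from_parents(parents)
        annotations = random_annotations(rng, parents, 4)
        ic = compute_ic(dag, annotations)
        scorer = SimilarityScorer(dag, ic, annotations)
        corpus = corpus_from(dag, annotations, ic, ps_size=4)
        profile = intra_ps_profile(scorer, corpus, "PS00")
        ids = sorted(annotations)
        for m in ids:
            expected = np.mean(
                [naive_score(parents, ic.ic, annotations[m], annotations[o])
                 for o in ids if o != m]
            )
            assert profile.per_disease[m] == pytest.approx(expected, abs=1e-12)


class TestRandomBaseline:
    def test_exhaustive_pool_is_seed_independent(self, fig1_scorer):
        pool = ["A", "B", "C"]
        a = random_baseline(fig1_scorer, pool, "A", 2, np.random.default_rng(1))
        b = random_baseline(fig1_scorer, pool, "A", 2, np.random.default_rng(99))
        assert a == b == pytest.approx((LOG32 / 2 + LOG32 / 2) / 2)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(11)
        parents = random_parents(rng, 30)
        dag = dag_from_parents(parents)
        annotations = random_annotations(rng, parents, 12)
        ic = compute_ic(dag, annotations)
        scorer = SimilarityScorer(dag, ic, annotations)
        pool = sorted(annotations)
        a = random_baseline(scorer, pool, pool[0], 5, np.random.default_rng(3))
        b = random_baseline(scorer, pool, pool[0], 5, np.random.default_rng(3))
        assert a == b

    def test_invalid_k(self, fig1_scorer):
        with pytest.raises(ConfigurationError):
            random_baseline(fig1_scorer, ["A", "B", "C"], "A", 0, np.random.default_rng(0))


class TestMaxPartner:
    def _corpus(self, fig1, extra=None):
        annotations = dict(fig1["annotations"])
        series = {
            "PS1": PhenotypicSeries(id="PS1", members={"A", "B"}),
            "PS2": PhenotypicSeries(id="PS2", members={"C", "D"}),
        }
        annotations["D"] = extra or {"3"}
        diseases = {d: Disease(id=d) for d in annotations}
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        scorer = SimilarityScorer(fig1["dag"], ic, annotations)
        return corpus, scorer

    def test_argmax_matches_bruteforce_scan(self, fig1):
        corpus, scorer = self._corpus(fig1)
        records = {r.disease: r for r in max_partner(corpus, scorer)}
        assert set(records) == {"A", "B", "C", "D"}
        for d, r in records.items():
            scores = {
                o: scorer.score(d, o) for o in records if o != d
            }
            assert r.score == max(scores.values())
            assert scores[r.partner] == r.score

    def test_multi_series_disease_excluded(self, fig1):
        annotations = dict(fig1["annotations"])
        series = {
            "PS1": PhenotypicSeries(id="PS1", members={"A", "B"}),
            "PS2": PhenotypicSeries(id="PS2", members={"A", "C"}),
        }
        diseases = {d: Disease(id=d) for d in annotations}
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        scorer = SimilarityScorer(fig1["dag"], ic, annotations)
        records = max_partner(corpus, scorer)
        assert all(r.disease != "A" for r in records)

    def test_tie_flag_and_smallest_partner(self, fig1):
        # Y and Z carry annotations identical to X, so X's best score ties
        annotations = {"X": {"1"}, "Y": {"1"}, "Z": {"1"}, "W": {"3"}}
        series = {
            "P1": PhenotypicSeries(id="P1", members={"X", "Y"}),
            "P2": PhenotypicSeries(id="P2", members={"Z", "W"}),
        }
        diseases = {d: Disease(id=d) for d in annotations}
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        scorer = SimilarityScorer(fig1["dag"], ic, annotations)
        record = next(r for r in max_partner(corpus, scorer) if r.disease == "X")
        assert record.tie is True
        assert record.partner == "Y"  # smallest identifier among the tied

    def test_summary_fractions(self, fig1):
        corpus, scorer = self._corpus(fig1)
        summary = partner_summary(max_partner(corpus, scorer))
        assert summary["n_diseases"] == 4
        assert summary["n_same_ps"] + summary["n_diff_ps"] == 4


class TestPartnerCrosstab:
    def test_partitions_and_drops(self, fig1):
        annotations = {"A": {"2"}, "B": {"3"}, "C": {"2"}, "D": {"3"}}
        series = {
            "PS1": PhenotypicSeries(id="PS1", members={"A", "B"}),
            "PS2": PhenotypicSeries(id="PS2", members={"C", "D"}),
        }
        diseases = {d: Disease(id=d) for d in annotations}
        diseases["A"].do_classes = {"nervous"}
        diseases["B"].do_classes = {"metabolic"}
        diseases["C"].do_classes = {"nervous"}
        diseases["D"].do_classes = {"nervous", "metabolic"}  # multi -> dropped
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        scorer = SimilarityScorer(fig1["dag"], ic, annotations)
        records = max_partner(corpus, scorer)
        table = partner_crosstab(records, corpus)
        assert table["n_records"] == 4
        assert table["n_dropped_do"] >= 1
        assert table["n_same_class"] + table["n_diff_class"] == table["n_inter_ps"]

    def test_all_intra_is_empty(self, fig1):
        annotations = {"A": {"1"}, "B": {"1"}}
        series = {"PS1": PhenotypicSeries(id="PS1", members={"A", "B"})}
        diseases = {d: Disease(id=d, do_classes={"nervous"}) for d in annotations}
        ic = compute_ic(fig1["dag"], annotations)
        corpus = build_corpus(diseases, series, annotations, ic)
        scorer = SimilarityScorer(fig1["dag"], ic, annotations)
        table = partner_crosstab(max_partner(corpus, scorer), corpus)
        assert table["n_inter_ps"] == 0
        assert table["same_class_freq"] == {}
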