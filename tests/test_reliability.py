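"""Agreement statistics: confusion matrices, percent agreement, Cohen's kappa
(hand-pinned fixtures, classical-form equivalence, sklearn cross-check)."""

import numpy as np
import pytest

from robast import (
    ConfusionMatrix3,
    Grade,
    KappaUndefined,
    canonical_rubric,
    cohen_kappa,
    confusion_matrix,
    corpus_reliability,
    per_study_domain_agreement,
    score_assessment,
)
from robast.reliability import format_percent
from robast.synthetic import SyntheticConfig, generate_paired_assessments

from conftest import make_assessment

L, M, H = Grade.LOW, Grade.MODERATE, Grade.HIGH

WEIGHTINGS = ["none", "linear", "quadratic"]


class TestConfusionMatrix:
    def test_direct_tally(self):
        m = confusion_matrix([(L, L), (H, H)])
        assert m.counts[0][0] == 1 and m.counts[2][2] == 1
        assert m.n_total == 2 and m.n_agree == 2

    def test_off_diagonal(self):
        m = confusion_matrix([(L, M)])
        assert m.counts[0][1] == 1
        assert m.n_agree == 0

    def test_pooling_arithmetic(self):
        # 10 studies x 6 domains pooled
        pairs = [(L, L)] * 60
        assert confusion_matrix(pairs).n_total == 60

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            confusion_matrix([])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix3(((1, -1, 0), (0, 0, 0), (0, 0, 0)))


class TestCohenKappa:
    """Fixture matrix ((4,1,0),(1,3,1),(0,1,4)): uniform marginals, p_o=11/15.

    Expected values computed by hand from the weighted-disagreement formula
    before implementation: 0.6 unweighted, 0.7 linear, 0.8 quadratic.
    """

    FIXTURE = ConfusionMatrix3(((4, 1, 0), (1, 3, 1), (0, 1, 4)))

    @pytest.mark.parametrize(
        "weighting,expected", [("none", 0.6), ("linear", 0.7), ("quadratic", 0.8)]
    )
    def test_pinned_fixture(self, weighting, expected):
        assert cohen_kappa(self.FIXTURE, weighting) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_perfect_diagonal_is_one(self, weighting):
        m = ConfusionMatrix3(((5, 0, 0), (0, 3, 0), (0, 0, 2)))
        assert cohen_kappa(m, weighting) == 1.0

    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_independence_is_zero(self, weighting):
        m = ConfusionMatrix3(((1, 1, 1), (1, 1, 1), (1, 1, 1)))
        assert cohen_kappa(m, weighting) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_transpose_symmetry(self, weighting):
        rng = np.random.default_rng(7)
        for _ in range(100):
            counts = tuple(tuple(int(x) for x in row) for row in rng.integers(0, 9, (3, 3)))
            m = ConfusionMatrix3(counts)
            if m.n_total == 0:
                continue
            k1, k2 = cohen_kappa(m, weighting), cohen_kappa(m.transpose(), weighting)
            if isinstance(k1, KappaUndefined):
                assert isinstance(k2, KappaUndefined)
            else:
                assert k1 == pytest.approx(k2, abs=1e-12)

    def test_classical_form_equivalence(self):
        """1 - sum(w o)/sum(w e) must equal (p_o - p_e)/(1 - p_e) computed on
        agreement weights 1 - w, to 1e-12, on 1000 random matrices."""
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 1000:
            arr = rng.integers(0, 20, (3, 3))
            m = ConfusionMatrix3(tuple(tuple(int(x) for x in row) for row in arr))
            if m.n_total == 0:
                continue
            o = m.array / m.n_total
            e = np.outer(o.sum(1), o.sum(0))
            i = np.arange(3)[:, None]
            j = np.arange(3)[None, :]
            for weighting, w in [
                ("none", (i != j).astype(float)),
                ("linear", np.abs(i - j) / 2),
                ("quadratic", ((i - j) / 2) ** 2),
            ]:
                got = cohen_kappa(m, weighting)
                p_o = float(((1 - w) * o).sum())
                p_e = float(((1 - w) * e).sum())
                if p_e == 1.0:
                    continue
                assert got == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)
            checked += 1

    def test_matches_sklearn(self):
        """Cross-check against scikit-learn on random label pairs."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(99)
        for weighting, sk_weights in [
            ("none", None),
            ("linear", "linear"),
            ("quadratic", "quadratic"),
        ]:
            for _ in range(20):
                a = rng.integers(0, 3, 60)
                b = rng.integers(0, 3, 60)
                if len(set(a) | set(b)) < 3:
                    continue
                m = confusion_matrix([(Grade(int(x)), Grade(int(y))) for x, y in zip(a, b)])
                expected = cohen_kappa_score(a, b, weights=sk_weights)
                assert cohen_kappa(m, weighting) == pytest.approx(expected, abs=1e-10)

    def test_unweighted_equals_zero_one_weighted(self):
        # internal consistency: "none" IS the 0/1 disagreement weighting;
        # verify against a literal 0/1 evaluation
        m = self.FIXTURE
        o = m.array / m.n_total
        e = np.outer(o.sum(1), o.sum(0))
        w = 1.0 - np.eye(3)
        assert cohen_kappa(m, "none") == pytest.approx(
            1 - (w * o).sum() / (w * e).sum(), abs=1e-15
        )

    def test_degenerate_marginals(self):
        # both reviewers rate everything high: zero observed AND chance
        # disagreement; the perfect-agreement convention applies
        m = ConfusionMatrix3(((0, 0, 0), (0, 0, 0), (0, 0, 5)))
        assert cohen_kappa(m, "none") == 1.0
        # fully discordant point-mass marginals stay defined (kappa = 0:
        # observed disagreement equals the chance-expected disagreement)
        m2 = ConfusionMatrix3(((0, 0, 5), (0, 0, 0), (0, 0, 0)))
        assert cohen_kappa(m2, "none") == pytest.approx(0.0, abs=1e-12)

    def test_empty_matrix_raises(self):
        m = ConfusionMatrix3(((0,) * 3,) * 3)
        with pytest.raises(ValueError):
            cohen_kappa(m, "none")

    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_kappa_bounded(self, weighting):
        rng = np.random.default_rng(4242)
        for _ in range(300):
            arr = rng.integers(0, 10, (3, 3))
            m = ConfusionMatrix3(tuple(tuple(int(x) for x in row) for row in arr))
            if m.n_total == 0:
                continue
            k = cohen_kappa(m, weighting)
            if not isinstance(k, KappaUndefined):
                assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12


class TestPerStudyAgreement:
    def _scored(self, rubric, grades, reviewer):
        a = make_assessment(rubric, grades, study_id="s1", reviewer_id=reviewer)
        return score_assessment(a, rubric)

    def test_four_of_six(self, rubric):
        # reviewer B disagrees on domains 1 and 6 (single-criterion flips)
        ga = {cid: L for cid in rubric.criterion_ids}
        gb = dict(ga)
        gb["1.1"] = H
        gb["6.1"] = H
        ra = self._scored(rubric, ga, "A")
        rb = self._scored(rubric, gb, "B")
        sa = per_study_domain_agreement(ra, rb)
        assert (sa.n_match, sa.n_compared) == (4, 6)
        assert format_percent(sa.fraction) == "66.7%"

    def test_identical_and_disjoint(self, rubric):
        ra = self._scored(rubric, L, "A")
        assert per_study_domain_agreement(ra, ra).fraction == 1.0
        rb = self._scored(rubric, H, "B")
        assert per_study_domain_agreement(ra, rb).fraction == 0.0

    def test_study_mismatch_raises(self, rubric):
        ra = self._scored(rubric, L, "A")
        rb = score_assessment(make_assessment(rubric, L, study_id="s2"), rubric)
        with pytest.raises(ValueError, match="mismatch"):
            per_study_domain_agreement(ra, rb)


class TestFormatPercent:
    @pytest.mark.parametrize(
        "fraction,text",
        [(4 / 6, "66.7%"), (5 / 6, "83.3%"), (1.0, "100.0%"), (0.0, "0.0%"), (0.005, "0.5%")],
    )
    def test_half_up_one_decimal(self, fraction, text):
        assert format_percent(fraction) == text


class TestCorpusReliability:
    def test_identical_reviewers(self, rubric):
        config = SyntheticConfig(n_studies=6, copy_probability=1.0, seed=3)
        a, b = generate_paired_assessments(config, rubric)
        rep = corpus_reliability(a, b, rubric, level="domain")
        assert rep.percent_agreement == 1.0
        assert rep.kappa_unweighted == 1.0
        assert rep.kappa_linear == 1.0
        assert rep.kappa_quadratic == 1.0
        assert all(sa.fraction == 1.0 for sa in rep.per_study_agreement.values())

    def test_domain_level_pools_six_pairs_per_study(self, rubric):
        config = SyntheticConfig(n_studies=10, seed=11)
        a, b = generate_paired_assessments(config, rubric)
        rep = corpus_reliability(a, b, rubric, level="domain")
        assert rep.pooled_matrix.n_total == 60
        assert all(sa.n_compared == 6 for sa in rep.per_study_agreement.values())
        assert rep.percent_agreement == pytest.approx(
            rep.pooled_matrix.n_agree / 60
        )

    def test_criterion_and_overall_levels(self, rubric):
        config = SyntheticConfig(n_studies=5, seed=2)
        a, b = generate_paired_assessments(config, rubric)
        rep_c = corpus_reliability(a, b, rubric, level="criterion")
        assert rep_c.pooled_matrix.n_total == 5 * 16
        rep_o = corpus_reliability(a, b, rubric, level="overall")
        assert rep_o.pooled_matrix.n_total == 5

    def test_percent_agreement_is_weighted_mean_of_per_study(self, rubric):
        config = SyntheticConfig(n_studies=8, seed=5, copy_probability=0.5)
        a, b = generate_paired_assessments(config, rubric)
        rep = corpus_reliability(a, b, rubric, level="domain")
        total_match = sum(sa.n_match for sa in rep.per_study_agreement.values())
        assert rep.percent_agreement == pytest.approx(total_match / rep.pooled_matrix.n_total)

    def test_study_set_mismatch_lists_difference(self, rubric):
        config = SyntheticConfig(n_studies=3, seed=1)
        a, b = generate_paired_assessments(config, rubric)
        with pytest.raises(ValueError, match="study_003"):
            corpus_reliability(a, b[:2], rubric)

    def test_degenerate_all_low_perfect_agreement(self, rubric):
        config = SyntheticConfig(n_studies=4, marginal=(1.0, 0.0, 0.0), seed=0)
        a, b = generate_paired_assessments(config, rubric)
        rep = corpus_reliability(a, b, rubric, level="domain")
        # everything agrees at 'low': zero observed and expected disagreement
        assert rep.percent_agreement == 1.0
        assert rep.kappa_unweighted == 1.0

    def test_report_serializes_to_json_dict(self, rubric):
        config = SyntheticConfig(n_studies=3, seed=9)
        a, b = generate_paired_assessments(config, rubric)
        rep = corpus_reliability(a, b, rubric)
        d = rep.to_dict()
        assert d["n_pairs"] == 18
        assert set(d["per_study_agreement"]) == {f"study_{i:03d}" for i in (1, 2, 3)}
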