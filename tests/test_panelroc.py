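"""Panel scoring and ROC machinery: pair-counting oracle, cut-offs, diagnostics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepsig.matrix import ExpressionMatrix, SampleAnnotation
from sepsig.panelroc import (DiagnosticMetrics, PanelDefinition, PanelTerm,
                             auc_ci, best_cutoff, composite_score,
                             correlate_markers, diagnostics_at, evaluate_panel,
                             hanley_mcneil_se, likelihood_ratios, load_presets,
                             roc_auc, threshold_for_target)


def _auc_pairs(scores, labels):
    """Exhaustive pair-counting oracle."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPanelDefinition:
    def test_parse_signs(self):
        p = PanelDefinition.parse("CETP+CMTM5+MIA-MPP3-PLA2G7")
        assert [t.gene for t in p.terms] == ["CETP", "CMTM5", "MIA", "MPP3", "PLA2G7"]
        assert [t.sign for t in p.terms] == [1, 1, 1, -1, -1]
        assert str(p) == "CETP+CMTM5+MIA-MPP3-PLA2G7"

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError):
            PanelDefinition.parse("A+B-A")

    def test_presets_catalogue(self):
        presets = load_presets()
        assert str(presets["IOI_2"]) == "FAM20A+OLAH"
        assert str(presets["SEPTICYTE"]) == "PLAC8-PLA2G7+LAMP1-CEACAM4"
        assert str(presets["SOS_5"]) == "CETP+CMTM5+MIA-MPP3-PLA2G7"
        # documented sign variant of the five-gene discriminator
        assert presets["SOS_5_ALT"].terms[3] == PanelTerm("MIA", -1)


def _small_matrix():
    vals = pd.DataFrame({"s1": [2.0, 0.5], "s2": [1.0, -1.0]},
                        index=["A", "B"])
    return ExpressionMatrix(vals)


class TestCompositeScore:
    def test_single_term_equals_gene_value(self):
        m = _small_matrix()
        s = composite_score(PanelDefinition.parse("A"), m)
        np.testing.assert_allclose(s.to_numpy(), [2.0, 1.0])

    def test_signed_arithmetic(self):
        m = _small_matrix()
        s = composite_score(PanelDefinition.parse("A-B"), m)
        assert s["s1"] == pytest.approx(1.5)
        assert s["s2"] == pytest.approx(2.0)

    def test_linearity_under_constant_shift(self):
        m = _small_matrix()
        panel = PanelDefinition.parse("A-B")
        base = composite_score(panel, m)
        shifted = m.copy()
        shifted.values.loc["A"] += 3.0
        np.testing.assert_allclose(composite_score(panel, shifted).to_numpy(),
                                   base.to_numpy() + 3.0)

    def test_unresolvable_gene_named_in_error(self):
        with pytest.raises(KeyError, match="MISSING"):
            composite_score(PanelDefinition.parse("A+MISSING"), _small_matrix())

    def test_best_auc_probe_collapse_picks_discriminative_probe(self):
        vals = pd.DataFrame(
            {"s1": [5.0, 0.1], "s2": [4.0, -0.1], "s3": [-5.0, 0.05],
             "s4": [-4.0, -0.02]},
            index=["g_p1", "g_p2"])
        m = ExpressionMatrix(vals, pd.Series(["G", "G"], index=vals.index))
        panel = PanelDefinition("p", [PanelTerm("G", +1)], probe_policy="best_auc")
        s = composite_score(panel, m, labels=np.array([1, 1, 0, 0]))
        np.testing.assert_allclose(s.to_numpy(), [5.0, 4.0, -5.0, -4.0])


class TestRocAuc:
    def test_worked_four_sample_example(self):
        roc = roc_auc([2.0, 0.0, 1.0, -1.0], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)
        assert roc.n_pos == 2 and roc.n_neg == 2

    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]).auc == 1.0

    def test_hanley_mcneil_worked_value(self):
        assert hanley_mcneil_se(0.5, 10, 10) == pytest.approx(
            np.sqrt((0.25 + 9 * (1 / 3 - 0.25) * 2) / 100))

    @settings(max_examples=80, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_matches_pair_counting_oracle(self, scores, rnd):
        scores = np.array(scores, dtype=float)
        labels = np.array([rnd.randint(0, 1) for _ in scores])
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(_auc_pairs(scores, labels), abs=1e-12)
        # label-flip symmetry
        assert roc_auc(scores, 1 - labels).auc == pytest.approx(1 - roc.auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestAucCi:
    def test_published_interval_reproduced(self):
        lo, hi = auc_ci(0.9758, 0.01067, 0.90)
        assert round(lo, 4) == 0.9582 and round(hi, 4) == 0.9934

    def test_zero_se_collapses(self):
        assert auc_ci(0.8, 0.0) == (0.8, 0.8)

    def test_95_level_z_value(self):
        lo, hi = auc_ci(0.5, 0.1, 0.95)
        assert lo == pytest.approx(0.3040, abs=5e-5)
        assert hi == pytest.approx(0.6960, abs=5e-5)


class TestLikelihoodRatios:
    def test_published_rows(self):
        assert likelihood_ratios(98.80, 96.67)[0] == pytest.approx(29.67, abs=0.005)
        assert likelihood_ratios(96.80, 89.74)[0] == pytest.approx(9.4347, abs=5e-5)

    def test_infinite_and_zero_limits(self):
        lr_pos, lr_neg = likelihood_ratios(100.0, 100.0)
        assert np.isinf(lr_pos) and lr_neg == 0.0
        assert np.isinf(likelihood_ratios(50.0, 0.0)[1])


class TestCutoffs:
    def test_tie_breaks_to_smallest_threshold(self):
        assert best_cutoff([2.0, 0.0, 1.0, -1.0], [1, 1, 0, 0]) == pytest.approx(-0.5)

    def test_perfect_separation_midpoint(self):
        cut = best_cutoff([1.0, 2.0, -1.0, 0.0], [1, 1, 0, 0])
        assert cut == pytest.approx(0.5)
        assert diagnostics_at([1.0, 2.0, -1.0, 0.0], [1, 1, 0, 0], cut).accuracy == 1.0

    def test_constant_scores_majority_rule(self):
        scores = [1.0] * 5
        labels = [1, 1, 1, 0, 0]
        cut = best_cutoff(scores, labels)
        d = diagnostics_at(scores, labels, cut)
        assert d.accuracy == pytest.approx(3 / 5)


class TestDiagnostics:
    def test_confusion_arithmetic(self):
        scores = np.r_[np.full(48, 2.0), np.full(2, 0.0),
                       np.full(2, 2.0), np.full(28, 0.0)]
        labels = np.r_[np.ones(50), np.zeros(30)].astype(int)
        d = diagnostics_at(scores, labels, 1.0)
        assert (d.tp, d.fn, d.fp, d.tn) == (48, 2, 2, 28)
        assert d.sensitivity == pytest.approx(0.96)
        assert d.specificity == pytest.approx(0.9333, abs=5e-5)
        assert d.ppv == pytest.approx(0.96)
        assert d.npv == pytest.approx(0.9333, abs=5e-5)
        assert d.lr_pos == pytest.approx(14.40, abs=0.005)
        assert d.lr_neg == pytest.approx(0.0429, abs=5e-5)
        ci_lo, ci_hi = d.sensitivity_ci
        assert 0 <= ci_lo < 0.96 < ci_hi <= 1

    def test_boundary_cutoffs(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1]
        low = diagnostics_at(scores, labels, -10.0)
        assert low.sensitivity == 1.0 and low.specificity == 0.0
        assert "npv" in low.undefined and np.isnan(low.npv)
        high = diagnostics_at(scores, labels, 10.0)
        assert high.sensitivity == 0.0 and high.specificity == 1.0
        assert np.isinf(high.lr_pos)

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=4, max_size=20),
           st.floats(-3.5, 3.5))
    def test_count_conservation_and_lr_identities(self, scores, cutoff):
        labels = np.array([1, 0] * (len(scores) // 2) + [1] * (len(scores) % 2))
        d = diagnostics_at(np.array(scores), labels, cutoff)
        assert d.tp + d.fn == labels.sum()
        assert d.tn + d.fp == (1 - labels).sum()
        if np.isfinite(d.lr_pos):
            assert d.lr_pos * (1 - d.specificity) == pytest.approx(d.sensitivity)
        if np.isfinite(d.lr_neg) and d.specificity > 0:
            assert d.lr_neg * d.specificity == pytest.approx(1 - d.sensitivity)


class TestThresholdForTarget:
    def test_perfect_separation_full_sensitivity(self):
        scores = np.array([2.0, 3.0, -1.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        cut = threshold_for_target(scores, labels, "ppv", 0.95)
        d = diagnostics_at(scores, labels, cut)
        assert d.ppv >= 0.95 and d.sensitivity == 1.0

    def test_unattainable_target_returns_none(self):
        scores = np.array([1.0, 1.0, 1.0, 1.0])
        labels = np.array([1, 0, 1, 0])
        assert threshold_for_target(scores, labels, "ppv", 0.99) is None

    def test_exhaustive_scan_agreement(self):
        scores = np.array([3.0, 2.0, 1.0, 2.0, 1.0, 0.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        cut = threshold_for_target(scores, labels, "npv", 0.66)
        d = diagnostics_at(scores, labels, cut)
        assert d.npv >= 0.66
        # no other qualifying threshold has higher specificity
        for t in np.arange(-1.0, 4.0, 0.25):
            alt = diagnostics_at(scores, labels, t)
            if not np.isnan(alt.npv) and alt.npv >= 0.66:
                assert alt.specificity <= d.specificity + 1e-12


class TestEvaluatePanel:
    def test_missing_gene_aborts_with_report(self, small_cohort):
        mat, ann = small_cohort
        panel = PanelDefinition.parse("UPGENE+NOSUCHGENE")
        rep = evaluate_panel(panel, mat, ann, (("SIRS", "ABDM", "PLMN"), ("CNTRL",)),
                             timepoint="D1")
        assert rep.missing_genes == ["NOSUCHGENE"]
        assert not rep.evaluated and rep.roc is None

    def test_planted_panel_discriminates(self, small_cohort):
        mat, ann = small_cohort
        panel = PanelDefinition.parse("UPGENE")
        rep = evaluate_panel(panel, mat, ann, (("SIRS", "ABDM", "PLMN"), ("CNTRL",)),
                             timepoint="D1")
        assert rep.roc.auc >= 0.95
        assert rep.best.accuracy >= 0.9
        if rep.ppv_cutoff is not None and rep.npv_cutoff is not None:
            lo, hi = rep.indeterminate_zone
            assert lo <= hi

    def test_repeat_evaluation_identical(self, small_cohort):
        mat, ann = small_cohort
        panel = PanelDefinition.parse("UPGENE-DOWNGENE")
        args = (panel, mat, ann, (("ABDM", "PLMN"), ("SIRS",)))
        r1 = evaluate_panel(*args, timepoint="D1")
        r2 = evaluate_panel(*args, timepoint="D1")
        assert r1.roc.auc == r2.roc.auc
        assert r1.best.cutoff == r2.best.cutoff


class TestCorrelateMarkers:
    def test_self_and_negated_correlation(self):
        vals = pd.DataFrame({"s1": [1.0, -1.0], "s2": [2.0, -2.0],
                             "s3": [3.0, -3.0], "s4": [0.0, 0.0]},
                            index=["A", "B"])
        m = ExpressionMatrix(vals)
        tab = correlate_markers(m, ["A", "B"])
        assert tab.loc["A", "A"] == 1.0
        assert tab.loc["A", "B"] == pytest.approx(-1.0)
        assert tab.loc["B", "A"] == tab.loc["A", "B"]

    def test_rank_formula_worked_example(self):
        vals = pd.DataFrame({"s1": [1.0, 1.0], "s2": [2.0, 3.0],
                             "s3": [3.0, 2.0], "s4": [4.0, 4.0]},
                            index=["X", "Y"])
        tab = correlate_markers(ExpressionMatrix(vals), ["X", "Y"])
        assert tab.loc["X", "Y"] == pytest.approx(0.8)

    def test_clinical_vector_joined(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(0, 1, (2, 10)),
                            index=["A", "B"],
                            columns=[f"s{i}" for i in range(10)])
        m = ExpressionMatrix(vals)
        crp = vals.loc["A"].to_numpy() * 2 + 1  # monotone in A
        tab = correlate_markers(m, ["A", "B"], extra={"CRP": crp})
        assert tab.loc["A", "CRP"] == pytest.approx(1.0)
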