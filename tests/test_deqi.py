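import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsmap.deqi import (QuestionnaireAnova, bonferroni_flags, intensity_matrix,
                        two_way_anova, CONDITION_ORDER)
from conftest import balanced_anova_oracle


def balanced_scores(rng, n_per_cell=25, means=None, integer=True):
    rows = []
    for si, stim in enumerate(("acupuncture", "tactile")):
        for li, loc in enumerate(("HT7", "PC6", "ST36", "SP10")):
            mu = means[si][li] if means is not None else 1.0
            for k in range(n_per_cell):
                score = rng.binomial(3, min(mu / 3.0, 1.0)) if integer \
                    else float(np.clip(rng.normal(mu, 0.5), 0, 3))
                rows.append({"subject_id": f"S{k}", "stimulus_type": stim,
                             "stimulus_location": loc, "item": 1, "score": score})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_all_identical_scores_degenerate(self):
        rng = np.random.default_rng(0)
        d = balanced_scores(rng, n_per_cell=4)
        d["score"] = 2
        res = two_way_anova(d)
        assert res["degenerate"]
        assert np.isnan(res["F_stimulus"])

    def test_additive_cell_means_zero_interaction(self):
        # deterministic additive layout with within-cell spread that is
        # identical in every cell -> interaction SS exactly 0
        rows = []
        for si, stim in enumerate(("acupuncture", "tactile")):
            for li, loc in enumerate(("HT7", "PC6", "ST36", "SP10")):
                base = 0.5 * si + 0.25 * li
                for delta in (-0.25, 0.25):
                    rows.append({"stimulus_type": stim, "stimulus_location": loc,
                                 "score": base + 1.0 + delta, "subject_id": "x"})
        res = two_way_anova(pd.DataFrame(rows))
        assert res["F_interaction"] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = balanced_scores(rng, n_per_cell=25)
        if d["score"].var() == 0:  # pragma: no cover - vanishingly unlikely
            return
        res = two_way_anova(d)
        ref = balanced_anova_oracle(d)
        for key, val in ref.items():
            assert res[key] == pytest.approx(val, rel=1e-8, abs=1e-10), key

    def test_ss_decomposition_additive(self):
        rng = np.random.default_rng(5)
        d = balanced_scores(rng)
        res = two_way_anova(d)
        parts = (res["ss_stimulus"] + res["ss_location"]
                 + res["ss_interaction"] + res["ss_within"])
        assert parts == pytest.approx(res["ss_total"], rel=1e-8)

    def test_invariance_to_shift_and_scale(self):
        rng = np.random.default_rng(6)
        d = balanced_scores(rng, integer=False)
        res = two_way_anova(d)
        d2 = d.copy()
        d2["score"] = d["score"] * 0.5 + 1.0  # stays inside the 0..3 range
        res2 = two_way_anova(d2)
        for eff in ("stimulus", "location", "interaction"):
            assert res2[f"F_{eff}"] == pytest.approx(res[f"F_{eff}"], rel=1e-8)

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(7)
        d = balanced_scores(rng, n_per_cell=3)
        d = d[~((d.stimulus_type == "tactile") & (d.stimulus_location == "SP10"))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(d)

    def test_single_factor_level_rejected(self):
        rng = np.random.default_rng(8)
        d = balanced_scores(rng, n_per_cell=3)
        with pytest.raises(ValueError, match="two levels"):
            two_way_anova(d[d.stimulus_type == "tactile"])

    def test_repeated_measures_variant_runs(self):
        rng = np.random.default_rng(9)
        d = balanced_scores(rng, n_per_cell=10)
        res = two_way_anova(d, repeated_measures=True)
        assert res["F_stimulus"] >= 0


class TestBonferroni:
    def test_strongly_significant_survives_correction(self):
        corr, uncorr = bonferroni_flags([0.0001], m=13, alpha=0.05)
        assert corr[0] and uncorr[0]  # 0.0001 < 0.05/13 = 0.00385

    def test_weakly_significant_is_uncorrected_only(self):
        corr, uncorr = bonferroni_flags([0.03], m=13, alpha=0.05)
        assert not corr[0] and uncorr[0]

    def test_nonsignificant_under_either(self):
        corr, uncorr = bonferroni_flags([1.0], m=13, alpha=0.05)
        assert not corr[0] and not uncorr[0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=13))
    def test_corrected_implies_uncorrected(self, ps):
        corr, uncorr = bonferroni_flags(ps, m=13)
        assert not (corr & ~uncorr).any()

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError, match="family size"):
            bonferroni_flags([0.1, 0.2], m=1)


class TestIntensityMatrix:
    def _q(self, scores_by_cell, n_items=2):
        rows = []
        for item in range(1, n_items + 1):
            for (stim, loc), scores in scores_by_cell.items():
                for sid, s in enumerate(scores):
                    rows.append({"subject_id": f"S{sid}", "stimulus_type": stim,
                                 "stimulus_location": loc, "item": item,
                                 "score": s})
        return pd.DataFrame(rows)

    def test_constant_scores(self):
        cells = {(s, l): [2, 2] for s in ("acupuncture", "tactile")
                 for l in ("HT7", "PC6", "ST36", "SP10")}
        means, sems = intensity_matrix(self._q(cells))
        assert (means.to_numpy() == 2.0).all()
        assert (sems.to_numpy() == 0.0).all()
        assert list(means.columns) == CONDITION_ORDER

    def test_mean_and_sem_arithmetic(self):
        cells = {(s, l): [0, 2] for s in ("acupuncture", "tactile")
                 for l in ("HT7", "PC6", "ST36", "SP10")}
        means, sems = intensity_matrix(self._q(cells, n_items=1))
        assert means.loc["Q1", "acupuncture:HT7"] == pytest.approx(1.0)
        assert sems.loc["Q1", "acupuncture:HT7"] == pytest.approx(1.0)

    def test_out_of_range_scores_rejected(self):
        cells = {("acupuncture", "HT7"): [5]}
        with pytest.raises(ValueError, match="0..3"):
            intensity_matrix(self._q(cells, n_items=1))

    def test_generator_recovers_published_cell_means(self):
        """Binomial score generator at n=25 recovers the target cell means
        of the 'numb' item within 3 SEM."""
        from bsmap.synthetic import StudyDesign, generate_study
        from bsmap.template import make_synthetic_template
        target = {("acupuncture", "HT7"): 1.2, ("acupuncture", "PC6"): 1.3,
                  ("acupuncture", "ST36"): 0.8, ("acupuncture", "SP10"): 0.8,
                  ("tactile", "HT7"): 0.4, ("tactile", "PC6"): 0.6,
                  ("tactile", "ST36"): 0.6, ("tactile", "SP10"): 0.6}
        design = StudyDesign(
            n_subjects=25, conditions=(), baseline_effects=(), noise_sd=0.0,
            gain_sigma=0.0,
            questionnaire_means={(2, s, l): mu for (s, l), mu in target.items()})
        tpl = make_synthetic_template(16, 16, "rectangle")
        ds, _ = generate_study(tpl, design, seed=123)
        means, sems = intensity_matrix(ds.questionnaire)
        for (stim, loc), mu in target.items():
            sem = max(float(sems.loc["Q2", f"{stim}:{loc}"]), 0.05)
            assert abs(float(means.loc["Q2", f"{stim}:{loc}"]) - mu) <= 3 * sem


def test_questionnaire_anova_estimator():
    rng = np.random.default_rng(77)
    frames = []
    for item in range(1, 14):
        d = balanced_scores(rng, n_per_cell=12)
        d["item"] = item
        frames.append(d)
    q = pd.concat(frames, ignore_index=True)
    qa = QuestionnaireAnova().fit(q)
    assert qa.m_ == 13
    assert len(qa.anova_table_) == 13
    t = qa.anova_table_
    for eff in ("stimulus", "location", "interaction"):
        assert ((t[f"bonferroni_{eff}"] & ~t[f"uncorrected_{eff}"]) == False).all()  # noqa: E712
    assert qa.cell_means_.shape == (13, 8)
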