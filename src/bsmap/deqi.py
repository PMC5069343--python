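"""Factorial analysis of the 13-item needling-sensation questionnaire.

Each item (dull, numb, spreading, ..., pricking) is scored 0 (nothing)
to 3 (extreme) after every stimulation session.  Per item, a classical
fixed-effects two-way ANOVA with interaction crosses stimulus type
(acupuncture vs. tactile, 2 levels) with stimulus location (HT7, PC6,
ST36, SP10; 4 levels); the Bonferroni family correction runs over the
m = 13 items.  A repeated-measures variant (subject as blocking factor)
is available behind a flag since the design is in fact within-subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator
from statsmodels.stats.anova import anova_lm

from .io import STIMULUS_LOCATIONS, STIMULUS_TYPES

#: canonical condition order: acupuncture HT7..SP10 then tactile HT7..SP10
CONDITION_ORDER = [f"{s}:{l}" for s in STIMULUS_TYPES for l in STIMULUS_LOCATIONS]

ITEM_LABELS = {
    1: "dull", 2: "numb", 3: "spreading", 4: "warm",
    5: "relief of tense or tight muscles", 6: "gentle touch", 7: "heavy",
    8: "compressing or pressing", 9: "refreshing or relieving",
    10: "activated digestion", 11: "streaming opening flow",
    12: "activated circulation", 13: "pricking",
}


def _validate_scores(scores: pd.Series) -> None:
    s = scores.astype(float)
    if ((s < 0) | (s > 3)).any():
        raise ValueError("scores must lie in 0..3")
    if not np.allclose(s, np.round(s)):
        warnings.warn("non-integer questionnaire scores accepted as-is",
                      RuntimeWarning, stacklevel=3)


def two_way_anova(scores: pd.DataFrame, repeated_measures: bool = False) -> dict:
    """Two-way fixed-effects ANOVA for one questionnaire item.

    ``scores`` is a long table with columns ``stimulus_type``,
    ``stimulus_location`` and ``score`` (plus ``subject_id`` for the
    repeated-measures variant, which adds the subject as a blocking
    factor).  Returns F/p/df and sums of squares for the two main
    effects and the interaction; a table with zero total variance is
    flagged degenerate (F undefined).
    """
    d = scores.copy()
    _validate_scores(d["score"])
    if d["stimulus_type"].nunique() < 2 or d["stimulus_location"].nunique() < 2:
        raise ValueError("both factors need at least two levels")
    cells = d.groupby(["stimulus_type", "stimulus_location"], observed=True)["score"]
    counts = cells.count()
    expected = d["stimulus_type"].nunique() * d["stimulus_location"].nunique()
    if len(counts) < expected or (counts < 2).any():
        raise ValueError("every stimulus x location cell needs >= 2 observations")

    out = {
        "cell_means": cells.mean().to_dict(),
        "cell_sems": cells.sem().to_dict(),
        "degenerate": False,
    }
    if float(d["score"].var()) == 0.0:
        out["degenerate"] = True
        for eff in ("stimulus", "location", "interaction"):
            out[f"F_{eff}"] = np.nan
            out[f"p_{eff}"] = np.nan
            out[f"ss_{eff}"] = 0.0
        out["ss_within"] = 0.0
        out["ss_total"] = 0.0
        return out

    formula = "score ~ C(stimulus_type) * C(stimulus_location)"
    if repeated_measures:
        formula += " + C(subject_id)"
    with warnings.catch_warnings():
        # zero within-cell variance inflates F to inf; keep the result
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(smf.ols(formula, data=d).fit(), typ=2)

    terms = {
        "stimulus": "C(stimulus_type)",
        "location": "C(stimulus_location)",
        "interaction": "C(stimulus_type):C(stimulus_location)",
    }
    for eff, term in terms.items():
        out[f"F_{eff}"] = float(table.loc[term, "F"])
        out[f"p_{eff}"] = float(table.loc[term, "PR(>F)"])
        out[f"ss_{eff}"] = float(table.loc[term, "sum_sq"])
        out[f"df_{eff}"] = int(table.loc[term, "df"])
    out["ss_within"] = float(table.loc["Residual", "sum_sq"])
    out["df_within"] = int(table.loc["Residual", "df"])
    out["ss_total"] = float(table["sum_sq"].sum())
    return out


def bonferroni_flags(p_values, m: int | None = None, alpha: float = 0.05
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(corrected, uncorrected) significance flags for a p-value family.

    Corrected flags use p < alpha/m with family size m (default: the
    number of p values); uncorrected flags use p < alpha.  Corrected
    significance implies uncorrected significance.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must cover all p values")
    return p < alpha / m, p < alpha


def intensity_matrix(questionnaire: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item x condition matrices of mean scores and SEMs.

    Rows Q1..Q13; columns in the canonical order acupuncture
    HT7/PC6/ST36/SP10 then tactile HT7/PC6/ST36/SP10.
    """
    q = questionnaire.copy()
    _validate_scores(q["score"])
    q["condition"] = q["stimulus_type"].astype(str) + ":" + q["stimulus_location"].astype(str)
    q["item"] = q["item"].astype(int)
    grouped = q.groupby(["item", "condition"], observed=True)["score"]
    means = grouped.mean().unstack("condition")
    sems = grouped.sem().unstack("condition")
    items = sorted(q["item"].unique())
    cols = [c for c in CONDITION_ORDER if c in means.columns]
    cols += [c for c in means.columns if c not in cols]
    means = means.reindex(index=items, columns=cols)
    sems = sems.reindex(index=items, columns=cols)
    means.index = [f"Q{i}" for i in items]
    sems.index = means.index
    return means, sems


class QuestionnaireAnova(BaseEstimator):
    """Per-item two-way ANOVA over a full questionnaire table.

    Parameters
    ----------
    alpha : float
        Uncorrected significance level.
    m : int or None
        Bonferroni family size; defaults to the number of items tested
        (13 for the full instrument).
    repeated_measures : bool
        Add the subject as a blocking factor (not the default; the
        classical fixed-effects analysis is the stated method even
        though the design is within-subject).

    Attributes (after ``fit``)
    --------------------------
    anova_table_ : DataFrame, one row per item (F/p/df/SS per effect plus
        Bonferroni and uncorrected flags on each effect's p value);
    cell_means_, cell_sems_ : item x condition DataFrames.
    """

    def __init__(self, alpha: float = 0.05, m: int | None = None,
                 repeated_measures: bool = False):
        self.alpha = alpha
        self.m = m
        self.repeated_measures = repeated_measures

    def fit(self, questionnaire: pd.DataFrame, y=None):
        items = sorted(questionnaire["item"].astype(int).unique())
        rows = []
        for item in items:
            sub = questionnaire[questionnaire["item"].astype(int) == item]
            res = two_way_anova(sub, repeated_measures=self.repeated_measures)
            row = {k: v for k, v in res.items() if not k.startswith("cell_")}
            row["item"] = f"Q{item}"
            rows.append(row)
        table = pd.DataFrame(rows).set_index("item")
        m = self.m if self.m is not None else len(items)
        for eff in ("stimulus", "location", "interaction"):
            p = table[f"p_{eff}"].to_numpy()
            corr, uncorr = bonferroni_flags(np.where(np.isnan(p), 1.0, p), m=m,
                                            alpha=self.alpha)
            table[f"bonferroni_{eff}"] = corr
            table[f"uncorrected_{eff}"] = uncorr
        self.m_ = m
        self.anova_table_ = table
        self.cell_means_, self.cell_sems_ = intensity_matrix(questionnaire)
        return self
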