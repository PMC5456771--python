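"""Age/sex comparison of tissue stiffness across a subject cohort.

Subjects fall into a young (18-36 y) and an old (49-65 y) group.  Per-group
descriptive statistics, Shapiro-Wilk normality screening with Q-Q
coordinates, and a two-way factorial ANOVA of the modulus on age group,
sex, and their interaction (Type II sums of squares, appropriate for the
unbalanced 13/17 design with a weak interaction) are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

YOUNG_RANGE = (18.0, 36.0)
OLD_RANGE = (49.0, 65.0)
DEFAULT_ALPHA = 0.05

SEXES = ("female", "male")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    modulus: float  # MPa, per-tissue linear modulus
    age_group: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        group = self.age_group or assign_age_group(self.age)
        object.__setattr__(self, "age_group", group)


def assign_age_group(age: float) -> str:
    """'young' for ages 18-36, 'old' for 49-65; anything else is outside
    the study population and rejected."""
    if YOUNG_RANGE[0] <= age <= YOUNG_RANGE[1]:
        return "young"
    if OLD_RANGE[0] <= age <= OLD_RANGE[1]:
        return "old"
    raise ValueError(f"age {age} outside the young (18-36) and old (49-65) ranges")


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        df = cohort.copy()
    else:
        df = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in cohort],
                "age_group": [s.age_group for s in cohort],
                "sex": [s.sex for s in cohort],
                "modulus": [s.modulus for s in cohort],
            }
        )
    required = {"age_group", "sex", "modulus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    return df


def group_stats(cohort) -> pd.DataFrame:
    """Sample mean, SD (n-1), n and standard error of the modulus per age
    group and per age x sex cell."""
    df = _as_frame(cohort)
    rows = []
    groupings = [("age_group",), ("age_group", "sex")]
    for keys in groupings:
        for label, sub in df.groupby(list(keys), observed=True):
            if len(sub) == 0:  # pragma: no cover
                logger.warning("empty group %s omitted", label)
                continue
            label = label if isinstance(label, tuple) else (label,)
            n = len(sub)
            sd = float(sub["modulus"].std(ddof=1)) if n > 1 else 0.0
            rows.append(
                {
                    "age_group": label[0],
                    "sex": label[1] if len(label) > 1 else "all",
                    "n": n,
                    "mean_MPa": float(sub["modulus"].mean()),
                    "sd_MPa": sd,
                    "se_MPa": sd / np.sqrt(n) if n > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(cohort, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Type II two-way ANOVA of modulus on age_group, sex and interaction.

    Returns the ANOVA table with columns sum_sq (MPa^2), df, F, PR(>F) and
    a boolean ``significant`` column at the given alpha.  If any age x sex
    cell is empty the interaction term is dropped with a warning.
    """
    df = _as_frame(cohort)
    for factor in ("age_group", "sex"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs both levels present")
    cells = df.groupby(["age_group", "sex"], observed=True).size()
    formula = "modulus ~ C(age_group) + C(sex) + C(age_group):C(sex)"
    if len(cells) < 4:
        logger.warning("empty age x sex cell: interaction dropped")
        formula = "modulus ~ C(age_group) + C(sex)"
    n_params = 4 if len(cells) == 4 else 3
    if len(df) <= n_params:
        raise ValueError("no residual degrees of freedom")
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(age_group)": "age_group",
            "C(sex)": "sex",
            "C(age_group):C(sex)": "age_group:sex",
            "Residual": "residual",
        }
    )
    table["significant"] = table["PR(>F)"] < alpha
    return table


def normality_check(values) -> dict:
    """Shapiro-Wilk test plus Q-Q coordinates for a modulus series.

    Returns ``{"statistic", "p_value", "theoretical_q", "sample_q"}``;
    the quantile pairs reproduce a normal Q-Q plot.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs n >= 3")
    stat, p = scipy.stats.shapiro(x)
    (theo, sample), _ = scipy.stats.probplot(x, dist="norm")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "theoretical_q": theo,
        "sample_q": sample,
    }
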