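"""Balanced three-way fixed-effects ANOVA and post-hoc home/away contrasts.

Each fitness component — nodule count (rhizobium fitness) and ln fruit count
(plant fitness) — is analysed with Medicago genotype (M), rhizobium mix (R)
and soil treatment (ST) as crossed fixed factors, all two-way interactions
and the three-way interaction.  By default uninoculated controls are
excluded (R has 2 levels, df = 1); an include-control mode adds the control
as a third rhizobium level, which is the only mode in which the soil main
effect on plant fitness becomes detectable.

Sums of squares come from an ordinary least-squares fit (statsmodels) with
sequential (type I) decomposition; on a balanced design sequential and
marginal sums of squares coincide, and the module refuses unbalanced input
rather than silently reporting order-dependent sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import (
    DegenerateAnovaError,
    InsufficientDataError,
    TransformDomainError,
)
from .io import CONTROL_MIX, check_balance

#: display order mirroring the conventional three-way table
SOURCE_ORDER = ("M", "R", "ST", "M x ST", "M x R", "R x ST", "M x R x ST", "Error")

_TERM_TO_SOURCE = {
    "C(medicago_genotype)": "M",
    "C(rhizobium_mix)": "R",
    "C(soil_treatment)": "ST",
    "C(medicago_genotype):C(rhizobium_mix)": "M x R",
    "C(medicago_genotype):C(soil_treatment)": "M x ST",
    "C(rhizobium_mix):C(soil_treatment)": "R x ST",
    "C(medicago_genotype):C(rhizobium_mix):C(soil_treatment)": "M x R x ST",
    "Residual": "Error",
}


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    f: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    """Source/df/SS/F/P rows plus the model R-squared."""

    rows: Tuple[AnovaRow, ...]
    r_squared: float
    response_label: str

    @property
    def total_df(self) -> int:
        return sum(r.df for r in self.rows)

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        from .io import anova_table_frame

        return anova_table_frame(self)


def ln_fruit(fruit_counts, policy: str = "plus_one") -> np.ndarray:
    """Log-transform fruit counts.

    ``plus_one`` (default) uses ln(y + 1) so that zero-fruit plants —
    plausible for uninoculated plants on carvacrol soil — remain usable;
    ``strict`` uses ln(y) and raises on any zero.
    """
    y = np.asarray(fruit_counts, dtype=float)
    if policy == "plus_one":
        return np.log1p(y)
    if policy == "strict":
        if (y <= 0).any():
            idx = int(np.flatnonzero(y <= 0)[0])
            raise TransformDomainError(
                f"strict ln transform undefined for zero fruit count (position {idx})"
            )
        return np.log(y)
    raise ValueError(f"unknown offset policy {policy!r}")


def _response(df: pd.DataFrame, response: str, offset_policy: str) -> pd.Series:
    if response in ("nodules", "nodule_count"):
        return df["nodule_count"].astype(float)
    if response == "ln_fruit":
        return pd.Series(
            ln_fruit(df["fruit_count"].to_numpy(), policy=offset_policy),
            index=df.index,
        )
    raise ValueError(f"unknown response {response!r}; use 'nodules' or 'ln_fruit'")


def anova_three_way(
    df: pd.DataFrame,
    response: str,
    *,
    include_control: bool = False,
    offset_policy: str = "plus_one",
) -> AnovaTable:
    """Three-way factorial ANOVA of one fitness component.

    With controls excluded (default) the full design gives df = 5 (M),
    1 (R), 1 (ST), 5 (M x ST), 5 (M x R), 1 (R x ST), 5 (M x R x ST) and 96
    error df on 120 plants.  Unbalanced subsets are refused with the
    offending cells listed; a constant response makes every F undefined and
    raises.
    """
    sub = df if include_control else df[df["rhizobium_mix"] != CONTROL_MIX]
    if len(sub) == 0:
        raise InsufficientDataError("no records to analyse")
    check_balance(sub).require()

    y = _response(sub, response, offset_policy)
    data = sub.assign(_y=y)
    if np.ptp(y.to_numpy()) == 0:
        raise DegenerateAnovaError("constant response: all F statistics undefined")

    model = smf.ols(
        "_y ~ C(medicago_genotype) * C(rhizobium_mix) * C(soil_treatment)", data=data
    ).fit()
    table = anova_lm(model, typ=1)

    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = int(table.loc["Residual", "df"])
    if resid_df == 0 or resid_ss <= 0:
        raise DegenerateAnovaError(
            "zero residual degrees of freedom or zero error sum of squares: "
            "F statistics undefined"
        )

    by_source = {}
    for term, row in table.iterrows():
        source = _TERM_TO_SOURCE[term]
        f = None if source == "Error" else float(row["F"])
        p = None if source == "Error" else float(row["PR(>F)"])
        by_source[source] = AnovaRow(
            source=source, df=int(row["df"]), ss=float(row["sum_sq"]), f=f, p=p
        )
    rows = tuple(by_source[s] for s in SOURCE_ORDER)

    total_ss = sum(r.ss for r in rows)
    r_squared = (total_ss - resid_ss) / total_ss
    return AnovaTable(rows=rows, r_squared=float(r_squared), response_label=response)


@dataclass(frozen=True)
class ContrastResult:
    """Two-group post-hoc comparison on plant-level responses."""

    label: str
    t: float
    df: float
    p: float
    group_means: Tuple[Tuple[str, float, int], Tuple[str, float, int]]


def contrast_home_away(
    df: pd.DataFrame,
    plant_genotypes: Sequence[str],
    split_factor: str,
    response: str,
    *,
    offset_policy: str = "plus_one",
    welch: bool = False,
) -> ContrastResult:
    """Two-sample t contrast between the two levels of ``split_factor``.

    Restricted to the named genotypes, uninoculated controls dropped.  A
    pooled-variance t is the default (the conventional post-hoc under an
    ANOVA); ``welch=True`` switches to unequal-variance.  The t statistic is
    level_1 minus level_2 in sorted label order.
    """
    sub = df[
        df["medicago_genotype"].isin(list(plant_genotypes))
        & (df["rhizobium_mix"] != CONTROL_MIX)
    ]
    levels = sorted(sub[split_factor].unique())
    if len(levels) != 2:
        raise InsufficientDataError(
            f"contrast needs exactly two levels of {split_factor}, found {levels}"
        )
    y = _response(sub, response, offset_policy)
    a = y[sub[split_factor] == levels[0]].to_numpy()
    b = y[sub[split_factor] == levels[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each contrast group needs at least 2 observations")

    res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return ContrastResult(
        label=f"{split_factor}: {levels[0]} vs {levels[1]} ({response})",
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        group_means=(
            (str(levels[0]), float(a.mean()), int(len(a))),
            (str(levels[1]), float(b.mean()), int(len(b))),
        ),
    )
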