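"""Case-vs-control group statistics for repertoire descriptors.

Per-feature two-sample t-tests (pooled variance by default, Welch behind a
flag) with step-down Holm–Šídák correction over the full feature family,
plus a classical two-factor ANOVA for per-donor single-feature values
(e.g. lysine occurrence with factors condition x chain).

The Holm–Šídák adjustment of sorted p-values p(1) <= ... <= p(m) is

    adj(i) = max_{j <= i} min(1, 1 - (1 - p(j))^(m - j + 1)),

returned in the input order; it is never smaller than the raw value and
never larger than the Bonferroni adjustment.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .composition import (
    AMINO_ACIDS,
    Weighting,
    aa_occurrence,
    percent_change,
    positional_occurrence,
    segment_usage,
)
from .io import Repertoire

log = logging.getLogger(__name__)


class InsufficientReplicationError(ValueError):
    """Fewer than two donors in an arm for some feature."""


class StratificationError(ValueError):
    """A comparison was asked to pool repertoires from different strata."""


class DesignError(ValueError):
    """Invalid factorial layout (e.g. an empty cell)."""


@dataclasses.dataclass
class GroupComparison:
    """One feature's case/control contrast."""

    feature: object
    case_mean: float
    control_mean: float
    case_n: int
    control_n: int
    difference: float           # percentage points, case - control
    percent_change: float | None
    p_raw: float
    p_adj: float

    @property
    def stars(self) -> str:
        if self.p_adj < 0.01:
            return "**"
        if self.p_adj < 0.05:
            return "*"
        return ""


@dataclasses.dataclass
class AnovaResult:
    """Two-factor ANOVA decomposition with interaction.

    ``table`` rows: the two factors, their interaction (when estimable) and
    the residual; columns ``sum_sq``, ``df``, ``F``, ``p``.
    """

    factors: tuple[str, str]
    table: pd.DataFrame

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def sum_sq(self, term: str) -> float:
        return float(self.table.loc[term, "sum_sq"])


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def holm_sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm–Šídák adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    step = 1.0 - (1.0 - ranked) ** (m - np.arange(m))
    adjusted_sorted = np.minimum(1.0, np.maximum.accumulate(step))
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def _pooled_or_welch_p(
    case: np.ndarray, control: np.ndarray, equal_var: bool
) -> float:
    if case.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        # zero variance in both arms: p = 1 when means agree, else 0
        if case.mean() == control.mean():
            log.info("zero variance in both arms with equal means; p set to 1")
            return 1.0
        return 0.0
    res = sps.ttest_ind(case, control, equal_var=equal_var)
    return float(res.pvalue)


def multiple_t_tests(
    case_values: Mapping[object, Sequence[float]],
    control_values: Mapping[object, Sequence[float]],
    equal_var: bool = True,
) -> list[GroupComparison]:
    """One two-sample t-test per feature, Holm–Šídák corrected as a family.

    The family is exactly the feature set passed in; feature sets of the
    two arms must be identical and every arm needs at least two donors.
    """
    if set(case_values) != set(control_values):
        raise ValueError("case and control feature sets differ")
    features = list(case_values)
    p_raw = []
    summaries = []
    for feature in features:
        case = np.asarray(case_values[feature], dtype=float)
        control = np.asarray(control_values[feature], dtype=float)
        if len(case) < 2 or len(control) < 2:
            raise InsufficientReplicationError(
                f"feature {feature!r}: need >=2 donors per arm "
                f"(got {len(case)} case, {len(control)} control)"
            )
        p_raw.append(_pooled_or_welch_p(case, control, equal_var))
        summaries.append((feature, case, control))
    p_adj = holm_sidak_adjust(p_raw)

    out = []
    for (feature, case, control), praw, padj in zip(summaries, p_raw, p_adj):
        cm, km = float(case.mean()), float(control.mean())
        out.append(
            GroupComparison(
                feature=feature,
                case_mean=cm,
                control_mean=km,
                case_n=len(case),
                control_n=len(control),
                difference=cm - km,
                percent_change=percent_change(cm, km) if min(cm, km) >= 0 else None,
                p_raw=float(praw),
                p_adj=float(padj),
            )
        )
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def two_way_anova(
    data: pd.DataFrame,
    response: str = "value",
    factors: tuple[str, str] = ("condition", "chain"),
) -> AnovaResult:
    """Classical two-factor ANOVA with interaction on a complete layout.

    Requires every factor-level combination to be observed; with a single
    replicate per cell the interaction is not estimable and an additive
    model is fitted with a warning.  Fitted by ordinary least squares
    (type-II sums of squares, identical to the classical decomposition on
    balanced designs).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    a, b = factors
    for col in (response, a, b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    cells = data.groupby([a, b], observed=True).size()
    n_a = data[a].nunique()
    n_b = data[b].nunique()
    if len(cells) < n_a * n_b:
        raise DesignError("incomplete design: at least one empty factor cell")
    with_interaction = (cells >= 2).all()
    if not with_interaction:
        warnings.warn(
            "single replicate per cell: interaction not estimable, "
            "fitting additive model", stacklevel=2,
        )
    rhs = f"C(Q('{a}')) {'*' if with_interaction else '+'} C(Q('{b}'))"
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)

    rename = {}
    for row in table.index:
        name = row
        name = name.replace(f"C(Q('{a}'))", a).replace(f"C(Q('{b}'))", b)
        rename[row] = name
    table = table.rename(index=rename).rename(
        columns={"PR(>F)": "p", "F": "F"}
    )
    table = table.loc[:, ["sum_sq", "df", "F", "p"]]
    return AnovaResult(factors=(a, b), table=table)


# ---------------------------------------------------------------------------
# end-to-end descriptor comparison
# ---------------------------------------------------------------------------

Descriptor = Literal["aa_occurrence", "positional", "segment_usage"]


def compare_composition(
    cohort: Sequence[Repertoire],
    descriptor: Descriptor = "aa_occurrence",
    weighting: Weighting = "diversity",
    *,
    positional_aa: str | None = None,
    max_position: int = 15,
    conditional_positional: bool = False,
    segment_class: Literal["V", "J"] = "V",
    equal_var: bool = True,
    min_clonotypes: int = 50,
) -> list[GroupComparison]:
    """Descriptor-per-donor t-test comparison between case and control arms.

    The correction family is the descriptor's natural feature set: all 20
    residues for composition, all positions of the queried residue for the
    positional profile, all observed segments for usage.  Repertoires with
    fewer than ``min_clonotypes`` clonotypes are excluded (logged).  The
    result is ordered by adjusted p-value, then feature.
    """
    strata = {(r.subset, r.chain) for r in cohort}
    if len(strata) != 1:
        raise StratificationError(
            f"cohort mixes strata {sorted(strata)}; compare one subset/chain at a time"
        )
    usable = []
    for rep in cohort:
        if rep.diversity < min_clonotypes:
            log.warning(
                "excluding %s: %d clonotypes < minimum %d",
                rep.sample_key, rep.diversity, min_clonotypes,
            )
            continue
        usable.append(rep)
    arms: dict[str, list[Repertoire]] = {"case": [], "control": []}
    for rep in usable:
        if rep.condition not in arms:
            raise StratificationError(f"unknown condition {rep.condition!r}")
        arms[rep.condition].append(rep)
    if len(arms["case"]) < 2 or len(arms["control"]) < 2:
        raise InsufficientReplicationError(
            f"need >=2 donors per arm after gating "
            f"(got {len(arms['case'])} case, {len(arms['control'])} control)"
        )

    def donor_features(rep: Repertoire) -> dict[object, float]:
        if descriptor == "aa_occurrence":
            occ = aa_occurrence(rep, weighting).occurrence
            return {aa: occ.get(aa, 0.0) for aa in AMINO_ACIDS}
        if descriptor == "positional":
            if positional_aa is None:
                raise ValueError("positional descriptor needs positional_aa")
            prof = positional_occurrence(
                rep, weighting, max_position=max_position,
                conditional=conditional_positional,
            )
            return {
                (p, positional_aa): prof.at(p, positional_aa)
                for p in range(1, max_position + 1)
            }
        if descriptor == "segment_usage":
            return dict(segment_usage(rep, segment_class, weighting).usage)
        raise ValueError(f"unknown descriptor {descriptor!r}")

    per_arm: dict[str, list[dict]] = {
        arm: [donor_features(rep) for rep in reps] for arm, reps in arms.items()
    }
    features: list[object] = sorted(
        {f for profs in per_arm.values() for prof in profs for f in prof},
        key=str,
    )
    case_values = {
        f: [prof.get(f, 0.0) for prof in per_arm["case"]] for f in features
    }
    control_values = {
        f: [prof.get(f, 0.0) for prof in per_arm["control"]] for f in features
    }
    comparisons = multiple_t_tests(case_values, control_values, equal_var=equal_var)
    comparisons.sort(key=lambda c: (c.p_adj, str(c.feature)))
    return comparisons


def comparison_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tidy report table with significance stars at 0.05 / 0.01."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "feature": c.feature if isinstance(c.feature, str) else str(c.feature),
                "case_mean": c.case_mean,
                "control_mean": c.control_mean,
                "case_n": c.case_n,
                "control_n": c.control_n,
                "difference": c.difference,
                "percent_change": "" if c.percent_change is None else c.percent_change,
                "p_raw": c.p_raw,
                "p_adj": c.p_adj,
                "significance": c.stars,
            }
        )
    return pd.DataFrame(rows)
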