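"""Enzyme-inhibition inference: % inhibition, IC50 and Tukey group letters.

Dose-response designs in extract screening are small — here three extract
concentrations per enzyme — so the IC50 (the concentration inhibiting half of
the enzyme activity) is obtained from a straight line of % inhibition against
log10 concentration, read off at 50%. Group comparisons between samples use
one-way ANOVA with Tukey's HSD reconstructed from summary statistics
(mean, SD, n), because replicate-level IC50s are rarely published.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, NoCrossingError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DosePoint:
    concentration: float  # ug/mL
    inhibition_pct: float
    replicate: int


@dataclass
class DoseResponseSeries:
    """Inhibition measurements for one enzyme across extract concentrations."""

    enzyme: str
    points: list[DosePoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.points:
            if p.concentration <= 0:
                raise ValidationError(f"non-positive concentration {p.concentration}")

    @classmethod
    def from_arrays(
        cls,
        enzyme: str,
        concentrations: Sequence[float],
        inhibitions: Sequence[float],
        replicates: Sequence[int] | None = None,
    ) -> "DoseResponseSeries":
        if replicates is None:
            replicates = [1] * len(concentrations)
        pts = [
            DosePoint(float(c), float(i), int(r))
            for c, i, r in zip(concentrations, inhibitions, replicates)
        ]
        return cls(enzyme=enzyme, points=pts)


@dataclass(frozen=True)
class IC50Result:
    """Log-linear IC50 estimate.

    ``extrapolated`` is True when the 50% crossing lies outside the tested
    concentration range; ``se`` is a delta-method standard error (nan when the
    fit has no residual degrees of freedom).
    """

    enzyme: str
    ic50: float
    se: float
    slope: float
    intercept: float
    r2: float
    extrapolated: bool
    n_points: int


@dataclass
class GroupSummary:
    """IC50 summary for one sample in one enzyme column."""

    label: str
    mean: float
    sd: float
    n: int
    letter: str = ""


def inhibition_percent(a_control: float, a_sample: float) -> float:
    """Control-relative inhibition 100*(A_control - A_sample)/A_control.

    Values outside [0, 100] (sample absorbing more than the control, or
    negative readings) are clipped with a warning.
    """
    if a_control <= 0:
        raise ValidationError("control absorbance must be positive")
    pct = 100.0 * (a_control - a_sample) / a_control
    if pct < 0 or pct > 100:
        logger.warning("inhibition %.2f%% outside [0, 100]; clipped", pct)
        pct = min(max(pct, 0.0), 100.0)
    return pct


def ic50_loglinear(series: DoseResponseSeries) -> IC50Result:
    """IC50 from OLS of % inhibition on log10 concentration.

    All replicate points enter one regression; IC50 = 10^((50 - b0)/b1). The
    standard error follows from the delta method on (b0, b1); the result is
    flagged ``extrapolated`` when outside [min conc, max conc].

    Raises
    ------
    InsufficientDataError
        Fewer than 2 distinct concentrations with finite inhibition.
    NoCrossingError
        Non-positive slope: inhibition does not increase with dose, so the
        line never crosses 50% from below.
    """
    conc = np.asarray([p.concentration for p in series.points], dtype=float)
    inh = np.asarray([p.inhibition_pct for p in series.points], dtype=float)
    keep = np.isfinite(inh)
    conc, inh = conc[keep], inh[keep]
    if len(np.unique(conc)) < 2:
        raise InsufficientDataError(
            f"{series.enzyme}: need >= 2 distinct concentrations, got {len(np.unique(conc))}"
        )
    x = np.log10(conc)
    design = sm.add_constant(x)
    model = sm.OLS(inh, design).fit()
    b0, b1 = float(model.params[0]), float(model.params[1])
    if b1 <= 0:
        raise NoCrossingError(
            f"{series.enzyme}: non-positive dose slope ({b1:.3g}); no 50% crossing"
        )
    g = (50.0 - b0) / b1
    ic50 = 10.0**g
    if model.df_resid > 0:
        cov = np.asarray(model.cov_params())
        grad = np.array([-1.0 / b1, -g / b1])
        var_g = float(grad @ cov @ grad)
        se = math.log(10.0) * ic50 * math.sqrt(max(var_g, 0.0))
    else:
        se = math.nan
    extrapolated = not (conc.min() <= ic50 <= conc.max())
    r2 = float(model.rsquared) if model.df_resid > 0 else 1.0
    return IC50Result(
        enzyme=series.enzyme,
        ic50=float(ic50),
        se=se,
        slope=b1,
        intercept=b0,
        r2=r2,
        extrapolated=extrapolated,
        n_points=len(conc),
    )


def _tukey_p(mean_i, mean_j, msw, n_i, n_j, df, n_groups) -> float:
    se = math.sqrt(msw * (1.0 / n_i + 1.0 / n_j) / 2.0)
    if se == 0:
        return 0.0 if mean_i != mean_j else 1.0
    q = abs(mean_i - mean_j) / se
    return float(stats.studentized_range.sf(q, n_groups, df))


def tukey_letters(
    groups: Sequence[GroupSummary], alpha: float = 0.05
) -> list[GroupSummary]:
    """Assign compact-letter-display letters by Tukey HSD from summary stats.

    One-way ANOVA is reconstructed from (mean, sd, n) per group; all pairwise
    comparisons use the studentized range with the pooled within-group
    variance. Letters are assigned with the insert-and-absorb algorithm,
    ordered from the smallest mean: groups that are not significantly
    different (p > alpha) share a letter, significantly different pairs never
    do. Groups with n < 2 are excluded with a warning.
    """
    usable = []
    for g in groups:
        if g.n < 2:
            logger.warning("group %s excluded from ANOVA: n = %d < 2", g.label, g.n)
            continue
        if g.sd < 0:
            raise ValidationError(f"group {g.label}: negative SD")
        usable.append(g)
    if len(usable) < 2:
        raise InsufficientDataError("need at least 2 groups with n >= 2")

    n_tot = sum(g.n for g in usable)
    df_within = n_tot - len(usable)
    msw = sum((g.n - 1) * g.sd**2 for g in usable) / df_within

    order = sorted(range(len(usable)), key=lambda i: usable[i].mean)
    significant: set[tuple[int, int]] = set()
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            p = _tukey_p(
                usable[i].mean, usable[j].mean, msw,
                usable[i].n, usable[j].n, df_within, len(usable),
            )
            if p <= alpha:
                significant.add((a, b))

    # insert-and-absorb on positions in mean order
    classes: list[set[int]] = [set(range(len(order)))]
    for a, b in sorted(significant):
        new_classes: list[set[int]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.append(cls - {a})
                new_classes.append(cls - {b})
            else:
                new_classes.append(cls)
        # absorb: drop classes contained in another
        classes = [
            c for c in new_classes
            if c and not any(c < other for other in new_classes)
        ]
        # dedupe
        seen, deduped = [], []
        for c in classes:
            if c not in seen:
                seen.append(c)
                deduped.append(c)
        classes = deduped

    classes.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters_by_pos: dict[int, str] = {p: "" for p in range(len(order))}
    for idx, cls in enumerate(classes):
        for p in cls:
            letters_by_pos[p] += alphabet[idx % len(alphabet)]

    out = []
    for pos, i in enumerate(order):
        out.append(replace_letter(usable[i], "".join(sorted(letters_by_pos[pos]))))
    # return in the original input order (excluded groups keep empty letters)
    by_label = {g.label: g for g in out}
    result = []
    for g in groups:
        if g.label in by_label:
            result.append(by_label[g.label])
        else:
            result.append(replace_letter(g, ""))
    return result


def replace_letter(group: GroupSummary, letter: str) -> GroupSummary:
    return replace(group, letter=letter)
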