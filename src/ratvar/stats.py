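"""Factorial statistics for 2x2 (diabetes x renal denervation) cohorts.

The group comparison layer: unbalanced two-way ANOVA with Type-III sums of
squares under sum-to-zero contrasts (each effect has one degree of
freedom in a 2x2 design, so the Type-III test of an effect is the F-test
of its sum-coded regression coefficient), the Student-Newman-Keuls
stepwise post-hoc on the four cell means, the log transform used for
urinary albumin, the per-membrane densitometric normalization, and the
small derived-quantity arithmetic (percent differences, fold changes,
pooled summaries) used when comparing against printed group tables.

A two-way ANOVA is fully determined by the four cell means, SDs and
counts; :func:`anova_from_summary` exploits this sufficiency to reproduce
the exact raw-data table from printed summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: default significance level
ALPHA = 0.05

EFFECTS = ("denervation", "diabetes", "interaction")


class EmptyCellError(ValueError):
    """A design cell has fewer than two observations."""


@dataclass(frozen=True)
class SummaryCell:
    """Printed 'mean +- SD (n)' summary of one design cell."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a summary cell needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class AnovaEffect:
    ss: float
    df: int
    f: float
    p: float


@dataclass(frozen=True)
class AnovaTable:
    """Type-III two-way ANOVA: one row per effect plus the residual."""

    denervation: AnovaEffect
    diabetes: AnovaEffect
    interaction: AnovaEffect
    residual_ms: float
    residual_df: int

    def effect(self, name: str) -> AnovaEffect:
        if name not in EFFECTS:
            raise KeyError(name)
        return getattr(self, name)

    def p(self, name: str) -> float:
        return self.effect(name).p

    def to_frame(self) -> pd.DataFrame:
        rows = {name: vars(self.effect(name)) for name in EFFECTS}
        df = pd.DataFrame(rows).T
        df.loc["residual"] = {"ss": self.residual_ms * self.residual_df,
                              "df": self.residual_df, "f": np.nan,
                              "p": np.nan}
        return df


def two_way_anova(records: pd.DataFrame, outcome: str,
                  diabetes_col: str = "diabetes",
                  denervation_col: str = "denervation") -> AnovaTable:
    """Unbalanced 2x2 factorial ANOVA, Type-III SS, sum-to-zero contrasts.

    ``records`` needs boolean (or 0/1) factor columns and a numeric outcome.
    Rows with a missing outcome are dropped; every cell must retain at
    least two observations.
    """
    data = records[[diabetes_col, denervation_col, outcome]].dropna()
    y = data[outcome].to_numpy(dtype=float)
    a = np.where(data[denervation_col].to_numpy(dtype=bool), 1.0, -1.0)
    b = np.where(data[diabetes_col].to_numpy(dtype=bool), 1.0, -1.0)
    for da in (1.0, -1.0):
        for db in (1.0, -1.0):
            if np.sum((a == da) & (b == db)) < 2:
                raise EmptyCellError(
                    "each design cell needs at least 2 observations")
    n = y.size
    X = np.column_stack([np.ones(n), a, b, a * b])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - 4
    mse = rss / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)

    def effect(j: int) -> AnovaEffect:
        ss = float(beta[j] ** 2 / xtx_inv[j, j])
        if mse == 0.0:
            if ss == 0.0:
                return AnovaEffect(ss=0.0, df=1, f=0.0, p=1.0)
            raise ZeroDivisionError("zero residual variance")
        f = ss / mse
        p = float(sps.f.sf(f, 1, df_resid))
        return AnovaEffect(ss=ss, df=1, f=f, p=p)

    return AnovaTable(denervation=effect(1), diabetes=effect(2),
                      interaction=effect(3), residual_ms=mse,
                      residual_df=df_resid)


def _exact_sample(mean: float, sd: float, n: int) -> np.ndarray:
    """A deterministic sample with exactly the given mean and SD (ddof=1)."""
    if n == 2:
        z = np.array([-1.0, 1.0])
    else:
        z = np.linspace(-1.0, 1.0, n)
    z = z - z.mean()
    s = z.std(ddof=1)
    z = z / s if s > 0 else z
    return mean + sd * z


def anova_from_summary(cells: dict[tuple[bool, bool], SummaryCell]) -> AnovaTable:
    """Two-way ANOVA reconstructed from the four printed cell summaries.

    ``cells`` maps ``(diabetes, denervation)`` to a :class:`SummaryCell`.
    The cell means/SDs/counts are sufficient statistics for the factorial
    model, so the result equals :func:`two_way_anova` on any raw data with
    those summaries.
    """
    keys = {(False, False), (False, True), (True, False), (True, True)}
    if set(cells) != keys:
        raise ValueError("cells must cover the full 2x2 grid")
    rows = []
    for (diab, den), cell in cells.items():
        for v in _exact_sample(cell.mean, cell.sd, cell.n):
            rows.append({"diabetes": diab, "denervation": den, "y": v})
    return two_way_anova(pd.DataFrame(rows), "y")


# ---------------------------------------------------------------------------
# Student-Newman-Keuls post-hoc
# ---------------------------------------------------------------------------

def snk_posthoc(records: pd.DataFrame, outcome: str,
                group_col: str = "group", alpha: float = ALPHA,
                ) -> pd.DataFrame:
    """Student-Newman-Keuls stepwise comparison of group means.

    Means are ranked; extreme pairs of each span are compared against the
    studentized-range critical value whose parameter is the span size, and
    a non-significant span is homogenized (nothing inside it is tested, so
    no significant pair is ever nested inside a non-significant span).
    The standard error uses the pooled within-group mean square and the
    harmonic mean of the two group sizes.

    Returns a symmetric boolean DataFrame of significant pairs.
    """
    data = records[[group_col, outcome]].dropna()
    groups = data.groupby(group_col)[outcome]
    labels = list(groups.groups)
    k = len(labels)
    if k < 2:
        raise ValueError("SNK needs at least 2 groups")
    means = groups.mean()
    ns = groups.count()
    if (ns < 2).any():
        raise EmptyCellError("every group needs at least 2 observations")
    # pooled within-group variance
    sse = float(((data[outcome] - data[group_col].map(means)) ** 2).sum())
    df_resid = int(ns.sum() - k)
    mse = sse / df_resid

    order = means.sort_values().index.to_list()
    sig = pd.DataFrame(False, index=labels, columns=labels)
    if mse == 0.0:
        # degenerate: all-equal groups are never significant; any mean
        # difference is infinitely significant
        for i, gi in enumerate(order):
            for gj in order[i + 1:]:
                different = means[gi] != means[gj]
                sig.loc[gi, gj] = sig.loc[gj, gi] = bool(different)
        return sig

    # stepwise from the widest span down; a span nested inside a
    # non-significant span is homogenized without testing
    nonsig_spans: list[tuple[int, int]] = []
    for r in range(k, 1, -1):
        q_crit = sps.studentized_range.ppf(1.0 - alpha, r, df_resid)
        for lo in range(0, k - r + 1):
            hi = lo + r - 1
            if any(lo >= L and hi <= H for L, H in nonsig_spans):
                continue
            gi, gj = order[lo], order[hi]
            n_h = 2.0 / (1.0 / ns[gi] + 1.0 / ns[gj])
            q_obs = abs(means[gj] - means[gi]) / math.sqrt(mse / n_h)
            if q_obs > q_crit:
                sig.loc[gi, gj] = sig.loc[gj, gi] = True
            else:
                nonsig_spans.append((lo, hi))
    return sig


# ---------------------------------------------------------------------------
# transforms and normalization
# ---------------------------------------------------------------------------

def log_transform_outcome(records: pd.DataFrame, outcome: str,
                          id_col: str = "animal_id") -> pd.DataFrame:
    """Natural-log transform of a strictly positive outcome column.

    Returns a copy; a non-positive value raises an error naming the animal.
    """
    out = records.copy()
    values = out[outcome]
    bad = values <= 0
    if bad.any():
        who = (out.loc[bad, id_col].iloc[0] if id_col in out.columns
               else out.index[bad][0])
        raise ValueError(
            f"cannot log-transform {outcome!r}: non-positive value for "
            f"animal {who!r}")
    out[outcome] = np.log(values)
    return out


def normalize_densitometry(values: np.ndarray, control_flags: np.ndarray,
                           batches: np.ndarray | None = None) -> np.ndarray:
    """Scale densitometric values so each batch's control mean is 100.

    ``batches`` identifies membranes; every batch must contain at least one
    control.  With no batches given, all values form a single batch.
    """
    values = np.asarray(values, dtype=float)
    control_flags = np.asarray(control_flags, dtype=bool)
    if batches is None:
        batches = np.zeros(values.size, dtype=int)
    batches = np.asarray(batches)
    out = np.empty_like(values)
    for batch in np.unique(batches):
        mask = batches == batch
        ctrl = values[mask & control_flags]
        if ctrl.size == 0:
            raise ValueError(f"batch {batch!r} has no control values")
        ctrl_mean = float(np.mean(ctrl))
        if ctrl_mean <= 0:
            raise ValueError(f"batch {batch!r} control mean must be positive")
        out[mask] = values[mask] * (100.0 / ctrl_mean)
    return out


# ---------------------------------------------------------------------------
# derived-quantity arithmetic
# ---------------------------------------------------------------------------

def percent_difference(reference_mean: float, comparison_mean: float,
                       rounding=None) -> float:
    """Signed percent difference 100*(comparison - reference)/reference.

    ``rounding`` is an optional callable applied to the result (display
    convention: nearest integer).
    """
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean must be non-zero")
    value = 100.0 * (comparison_mean - reference_mean) / reference_mean
    return rounding(value) if rounding is not None else value


def fold_change(reference_mean: float, comparison_mean: float,
                direction: str = "auto") -> float:
    """Fold change between two positive means.

    ``direction='reduction'`` gives reference/comparison (an x-fold drop),
    ``'elevation'`` gives comparison/reference, and ``'auto'`` whichever is
    >= 1.
    """
    if reference_mean <= 0 or comparison_mean <= 0:
        raise ValueError("fold change needs positive means")
    if direction == "reduction":
        return reference_mean / comparison_mean
    if direction == "elevation":
        return comparison_mean / reference_mean
    if direction == "auto":
        ratio = comparison_mean / reference_mean
        return ratio if ratio >= 1.0 else 1.0 / ratio
    raise ValueError("direction must be 'reduction', 'elevation' or 'auto'")


def pooled_summary(cells: list[SummaryCell]) -> tuple[float, float]:
    """n-weighted grand mean and pooled SD across summary cells."""
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to pool")
    ns = np.array([c.n for c in cells], dtype=float)
    means = np.array([c.mean for c in cells])
    sds = np.array([c.sd for c in cells])
    grand_mean = float(np.sum(ns * means) / np.sum(ns))
    pooled_var = float(np.sum((ns - 1) * sds ** 2) / np.sum(ns - 1))
    return grand_mean, math.sqrt(pooled_var)
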