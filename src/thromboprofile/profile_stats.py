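"""Multiparameter data processing: scaling, heatmaps and effect sizes.

The per-run parameter values from a flow-chamber study are compared
across genotype (or treatment) groups as follows:

* **0-10 scaling.**  For the complete database of runs, each parameter is
  linearly normalized so that its database minimum maps to 0 and its
  maximum to 10.
* **Group heatmaps.**  Cell (group, parameter) holds the group mean of
  the scaled values.
* **Subtraction ("gene effect") heatmaps.**  The reference-group (wild
  type) row is subtracted from every other row, giving signed changes in
  scaled units.
* **Effect sizes.**  On the *raw* (unscaled) per-run data, Cohen's
  d = (mean1 - mean2) / s with the pooled standard deviation
  s = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)), converted to a
  bounded coefficient r = d / sqrt(d^2 + a) with the unequal-sample-size
  correction a = (n1 + n2)^2 / (n1 n2)  (a = 4 when n1 = n2).
* **Significance filtering.**  Two-sided equal-variance t-tests at
  alpha = 0.05, optionally Benjamini-Hochberg adjusted across the
  parameter family; heatmap cells failing significance or a minimum
  effect size are masked as "not relevant" (distinct from a true zero).

Nonparametric wrappers (Mann-Whitney U, Kruskal-Wallis) are provided for
pipeline parity with group comparisons of single parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_EFFECT_R = 0.3  # Cohen's conventional "moderate" correlation

__all__ = [
    "ScaledMatrix",
    "EffectSizeResult",
    "DifferentialHeatmap",
    "scale_0_10",
    "group_heatmap",
    "subtraction_heatmap",
    "cohens_d",
    "effect_r",
    "significance_filter",
    "bh_adjust",
    "effect_size_table",
    "effect_filtered_heatmap",
    "mann_whitney_u",
    "kruskal_wallis",
]


@dataclass
class ScaledMatrix:
    """Group x parameter matrix of 0-10 scaled means plus scaling metadata."""

    values: pd.DataFrame  # rows: group labels, cols: parameter ids
    scaling_meta: pd.DataFrame  # per parameter: min, max, degenerate


@dataclass(frozen=True)
class EffectSizeResult:
    """Effect size of one parameter between two groups."""

    parameter: str | None
    d: float
    s_pooled: float
    n1: int
    n2: int
    a: float | None = None
    r: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    significant: bool | None = None


@dataclass
class DifferentialHeatmap:
    """Subtraction or effect-size heatmap with an explicit relevance mask.

    ``mask`` is True where a cell was filtered out; such cells are NaN in
    ``values`` so they can never be confused with a true zero effect.
    """

    values: pd.DataFrame
    mask: pd.DataFrame | None = None
    filter_meta: dict = field(default_factory=dict)


def scale_0_10(values: Sequence[float] | np.ndarray) -> tuple[np.ndarray, dict]:
    """Linearly normalize one parameter's database values to 0-10.

    ``v -> 10 (v - min) / (max - min)``.  A degenerate column (all values
    equal) maps to all zeros with ``degenerate=True`` in the metadata,
    preserving the "0 = database minimum" reading.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot scale an empty value list")
    vmin, vmax = float(arr.min()), float(arr.max())
    if vmin == vmax:
        return np.zeros_like(arr), {"min": vmin, "max": vmax, "degenerate": True}
    return 10.0 * (arr - vmin) / (vmax - vmin), {"min": vmin, "max": vmax,
                                                 "degenerate": False}


def _scale_frame(wide: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    scaled = {}
    meta = {}
    for col in wide.columns:
        scaled[col], meta[col] = scale_0_10(wide[col].to_numpy())
    return (pd.DataFrame(scaled, index=wide.index),
            pd.DataFrame(meta).T.rename_axis("parameter"))


def group_heatmap(wide: pd.DataFrame, grouping: pd.Series | Sequence) -> ScaledMatrix:
    """Scaled group-mean heatmap over the complete run database.

    ``wide`` holds one row per run and one column per parameter;
    ``grouping`` assigns each run to exactly one group.  Scaling is
    performed database-wide *before* group averaging.
    """
    grouping = pd.Series(np.asarray(grouping), index=wide.index, name="group")
    if grouping.isna().any():
        raise ValueError("every run must be assigned to a group")
    scaled, meta = _scale_frame(wide)
    means = scaled.groupby(grouping, sort=False).mean()
    if (means.index.value_counts() == 0).any():  # pragma: no cover - guarded above
        raise ValueError("empty group")
    return ScaledMatrix(values=means, scaling_meta=meta)


def subtraction_heatmap(matrix: ScaledMatrix, reference_group: str) -> DifferentialHeatmap:
    """Gene-effect heatmap: group means minus the reference-group means.

    The reference row is removed from the output; remaining cells lie in
    scaled units within [-10, 10].
    """
    if reference_group not in matrix.values.index:
        raise ValueError(f"reference group {reference_group!r} not in heatmap rows")
    ref = matrix.values.loc[reference_group]
    diff = matrix.values.drop(index=reference_group) - ref
    return DifferentialHeatmap(values=diff,
                               filter_meta={"reference_group": reference_group,
                                            "kind": "subtraction"})


def cohens_d(x1: Sequence[float], x2: Sequence[float],
             parameter: str | None = None) -> EffectSizeResult:
    """Cohen's d with the pooled standard deviation, on raw per-run data.

    ``d = (mean(x1) - mean(x2)) / s`` with
    ``s = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))`` using
    unbiased (ddof=1) group variances.

    Raises
    ------
    ValueError
        If either group has fewer than two values, values are not finite,
        or the pooled standard deviation is zero (d undefined).
    """
    a1 = np.asarray(x1, dtype=float)
    a2 = np.asarray(x2, dtype=float)
    n1, n2 = a1.size, a2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two values")
    if not (np.isfinite(a1).all() and np.isfinite(a2).all()):
        raise ValueError("group values must be finite")
    s2 = ((n1 - 1) * a1.var(ddof=1) + (n2 - 1) * a2.var(ddof=1)) / (n1 + n2 - 2)
    s = float(np.sqrt(s2))
    if s == 0.0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    d = float((a1.mean() - a2.mean()) / s)
    return EffectSizeResult(parameter=parameter, d=d, s_pooled=s, n1=n1, n2=n2)


def effect_r(d: float, n1: int, n2: int) -> tuple[float, float]:
    """Convert d to the bounded coefficient r with unequal-n correction.

    ``a = (n1 + n2)^2 / (n1 n2)`` and ``r = d / sqrt(d^2 + a)``; with
    equal group sizes a = 4 exactly, recovering the classical d-to-r
    conversion.  |r| < 1 always, and sign(r) = sign(d).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    a = (n1 + n2) ** 2 / (n1 * n2)
    return float(a), float(d / np.sqrt(d * d + a))


def significance_filter(x1: Sequence[float], x2: Sequence[float],
                        alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided equal-variance t-test p-value and an alpha decision.

    When both groups have zero variance the p-value is 1 if the means are
    equal (no evidence of any difference) and 0 otherwise (the difference
    is deterministic); this keeps degenerate simulated parameters from
    producing NaNs.  Family-level multiplicity correction is applied by
    the callers that know the family (see ``effect_size_table``).
    """
    a1 = np.asarray(x1, dtype=float)
    a2 = np.asarray(x2, dtype=float)
    if a1.size < 2 or a2.size < 2:
        raise ValueError("each group needs at least two values")
    if a1.var(ddof=1) == 0.0 and a2.var(ddof=1) == 0.0:
        p = 1.0 if a1.mean() == a2.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a1, a2, equal_var=True).pvalue)
    return p, bool(p < alpha)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values) for one family."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def effect_size_table(
    wide: pd.DataFrame,
    grouping: pd.Series | Sequence,
    group: str,
    reference_group: str,
    alpha: float = 0.05,
    correction: str | None = "bh",
) -> pd.DataFrame:
    """Per-parameter effect sizes of ``group`` vs ``reference_group``.

    Works on the raw (unscaled) run table.  Returns one row per parameter
    with n1, n2, d, s_pooled, a, r, p, q and the significance decision;
    when ``correction='bh'`` the decision compares the BH-adjusted q to
    alpha across the parameter family, with ``correction=None`` the raw p
    is used.
    """
    grouping = pd.Series(np.asarray(grouping), index=wide.index)
    rows = []
    for col in wide.columns:
        x1 = wide.loc[grouping == group, col].to_numpy(dtype=float)
        x2 = wide.loc[grouping == reference_group, col].to_numpy(dtype=float)
        res = cohens_d(x1, x2, parameter=col)
        a, r = effect_r(res.d, res.n1, res.n2)
        p, _ = significance_filter(x1, x2, alpha=alpha)
        rows.append({"parameter": col, "n1": res.n1, "n2": res.n2, "d": res.d,
                     "s_pooled": res.s_pooled, "a": a, "r": r, "p": p})
    table = pd.DataFrame(rows).set_index("parameter")
    if correction == "bh":
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < alpha
    elif correction is None:
        table["q"] = table["p"]
        table["significant"] = table["p"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table


def effect_filtered_heatmap(
    wide: pd.DataFrame,
    grouping: pd.Series | Sequence,
    reference_group: str,
    mode: str = "signed_r",
    min_effect: float = DEFAULT_MIN_EFFECT_R,
    alpha: float = 0.05,
    correction: str | None = "bh",
) -> DifferentialHeatmap:
    """Effect-size heatmap of every group vs the reference, with filtering.

    Cells that are not significant at ``alpha`` (after the configured
    multiplicity correction, applied per comparison across the parameter
    family) or whose |effect| falls below ``min_effect`` are masked; the
    remaining cells carry the signed effect (r by default, d with
    ``mode='signed_d'``).
    """
    if mode not in ("signed_r", "signed_d"):
        raise ValueError(f"unknown mode {mode!r}")
    grouping = pd.Series(np.asarray(grouping), index=wide.index)
    groups = [g for g in pd.unique(grouping) if g != reference_group]
    if reference_group not in set(grouping):
        raise ValueError(f"reference group {reference_group!r} has no runs")
    values = pd.DataFrame(index=pd.Index(groups, name="group"),
                          columns=wide.columns, dtype=float)
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    for g in groups:
        table = effect_size_table(wide, grouping, g, reference_group,
                                  alpha=alpha, correction=correction)
        effect = table["r"] if mode == "signed_r" else table["d"]
        keep = table["significant"] & (effect.abs() >= min_effect)
        values.loc[g] = effect.where(keep, np.nan)
        mask.loc[g] = ~keep
    return DifferentialHeatmap(values=values, mask=mask,
                               filter_meta={"mode": mode, "min_effect": min_effect,
                                            "alpha": alpha, "correction": correction,
                                            "reference_group": reference_group})


def age_pooling_pretest(wide: pd.DataFrame, age_grouping: pd.Series | Sequence,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-parameter pretest of whether two age groups may be pooled.

    Runs a two-sided equal-variance t-test between the two age groups for
    every parameter; pooling ages before a genotype comparison is
    defensible when (almost) no parameter differs between them.  Returns a
    per-parameter table of p-values and decisions; the ``poolable``
    attribute of the result is True when at most one parameter differs.
    """
    ages = pd.Series(np.asarray(age_grouping), index=wide.index)
    levels = pd.unique(ages)
    if len(levels) != 2:
        raise ValueError("age pretest expects exactly two age groups")
    rows = []
    for col in wide.columns:
        p, sig = significance_filter(
            wide.loc[ages == levels[0], col], wide.loc[ages == levels[1], col],
            alpha=alpha)
        rows.append({"parameter": col, "p": p, "differs": sig})
    out = pd.DataFrame(rows).set_index("parameter")
    out.attrs["poolable"] = bool(out["differs"].sum() <= 1)
    return out


def mann_whitney_u(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value (tie-corrected asymptotic/exact).

    Identical samples (all values tied across both groups) return p = 1,
    where the tie-corrected statistic is otherwise undefined.
    """
    a1, a2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    combined = np.concatenate([a1, a2])
    if np.all(combined == combined[0]):
        return 1.0
    return float(stats.mannwhitneyu(a1, a2, alternative="two-sided").pvalue)


def kruskal_wallis(*groups: Sequence[float]) -> float:
    """Kruskal-Wallis p-value across >= 2 groups; identical data give p = 1."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    combined = np.concatenate(arrays)
    if np.all(combined == combined[0]):
        return 1.0
    return float(stats.kruskal(*arrays).pvalue)
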