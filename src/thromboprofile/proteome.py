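"""Differential analysis of label-free platelet proteome ratio tables.

Post-quantification workflow for comparing a knockout platelet proteome
against wild type:

1. remove known platelet contaminant proteins (user-supplied accession
   list) and median-center each sample column in log2 space;
2. per protein, compute the log2 ratio (median of test replicates minus
   median of reference replicates), a two-sided t-test p-value across
   replicates, and Benjamini-Hochberg q-values across all tested
   proteins (FDR 0.05);
3. classify regulation by the > 1.5-fold rule: ``up`` iff
   log2 ratio > log2(1.5), ``down`` iff log2 ratio < -log2(1.5), the
   boundary itself counting as unchanged;
4. cross-comparison overlap counts (Venn-style joint up/down sets) and
   per-function-class regulation summaries.

Tables are pandas DataFrames with a ``protein_id`` column and one column
per replicate sample holding log2 abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profile_stats import bh_adjust

FOLD_THRESHOLD = 1.5

__all__ = [
    "OverlapResult",
    "remove_contaminants_and_normalize",
    "differential_stats",
    "classify_regulation",
    "overlap_counts",
    "function_class_summary",
]


@dataclass(frozen=True)
class OverlapResult:
    """Per-direction marginal and joint regulated-protein counts."""

    labels: tuple[str, ...]
    up_counts: Mapping[str, int]
    down_counts: Mapping[str, int]
    joint_up: int
    joint_down: int

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "up_counts": dict(self.up_counts),
            "down_counts": dict(self.down_counts),
            "joint_up": self.joint_up,
            "joint_down": self.joint_down,
        }


def remove_contaminants_and_normalize(
    table: pd.DataFrame,
    contaminant_ids: Iterable[str],
    sample_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Drop contaminant proteins and median-center each sample column.

    ``sample_columns`` names the replicate log2-abundance columns; by
    default every float column except recognized metadata is used.
    Median-centering in log space removes per-sample loading offsets,
    the standard normalization for label-free ratio data.

    Raises
    ------
    ValueError
        If no proteins remain after contaminant removal.
    """
    contaminants = set(contaminant_ids)
    out = table.loc[~table["protein_id"].isin(contaminants)].copy()
    if out.empty:
        raise ValueError("no proteins left after contaminant removal")
    if sample_columns is None:
        skip = {"true_log2_effect"}
        sample_columns = [c for c in out.columns
                         if c not in skip and pd.api.types.is_float_dtype(out[c])]
    for col in sample_columns:
        out[col] = out[col] - out[col].median()
    return out


def classify_regulation(log2_ratio, fold_threshold: float = FOLD_THRESHOLD):
    """Classify log2 ratios by the strict > ``fold_threshold`` rule.

    ``up`` iff ratio > threshold-fold, ``down`` iff ratio < 1/threshold-fold;
    a ratio exactly at the boundary is ``unchanged``.  Accepts a scalar or
    an array and returns the matching shape.
    """
    boundary = np.log2(fold_threshold)
    arr = np.asarray(log2_ratio, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("log2 ratios must be finite")
    out = np.where(arr > boundary, "up", np.where(arr < -boundary, "down", "unchanged"))
    if np.isscalar(log2_ratio) or arr.ndim == 0:
        return str(out)
    return out


def differential_stats(
    table: pd.DataFrame,
    test_columns: Sequence[str],
    ref_columns: Sequence[str],
    equal_var: bool = True,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein log2 ratio, t-test p, BH q and regulation class.

    The log2 ratio is the median of the test replicates minus the median
    of the reference replicates (all columns already in log2).  P-values
    come from a two-sided t-test across replicates (equal-variance by
    default, Welch with ``equal_var=False``); q-values are BH-adjusted
    across all tested proteins.  Zero-variance proteins get p = 1 when
    the group means are equal and p = 0 otherwise, flagged in the
    ``zero_variance`` column.

    Requires at least two replicates per group.
    """
    if len(test_columns) < 2 or len(ref_columns) < 2:
        raise ValueError("need at least two replicates per group")
    out = table.copy()
    test = out[list(test_columns)].to_numpy(dtype=float)
    ref = out[list(ref_columns)].to_numpy(dtype=float)

    out["log2_ratio"] = np.median(test, axis=1) - np.median(ref, axis=1)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows trip scipy's precision-loss warning; they are
        # replaced by the documented convention just below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(test, ref, axis=1, equal_var=equal_var).pvalue
    zero_var = (test.var(axis=1, ddof=1) == 0) & (ref.var(axis=1, ddof=1) == 0)
    if zero_var.any():
        equal_means = np.isclose(test.mean(axis=1), ref.mean(axis=1))
        p = np.where(zero_var, np.where(equal_means, 1.0, 0.0), p)
    out["p_value"] = p
    out["zero_variance"] = zero_var
    out["q_value"] = bh_adjust(p)
    out["significant"] = out["q_value"] < alpha
    out["regulation"] = classify_regulation(out["log2_ratio"].to_numpy(), fold_threshold)
    return out


def overlap_counts(tables: Mapping[str, pd.DataFrame],
                   require_significant: bool = False) -> OverlapResult:
    """Joint up/down regulated-protein counts across comparisons.

    Each table must carry ``protein_id`` and ``regulation`` columns over a
    shared protein universe; with ``require_significant=True`` only
    proteins also passing the FDR filter count as regulated.  Duplicated
    protein ids within a table raise.
    """
    labels = tuple(tables)
    up_sets: dict[str, set] = {}
    down_sets: dict[str, set] = {}
    for label, tab in tables.items():
        if tab["protein_id"].duplicated().any():
            dupes = tab.loc[tab["protein_id"].duplicated(), "protein_id"].unique()
            raise ValueError(f"duplicated protein ids in {label!r}: {list(dupes)[:5]}")
        reg = tab["regulation"].to_numpy()
        keep = np.ones(len(tab), dtype=bool)
        if require_significant:
            keep = tab["significant"].to_numpy(dtype=bool)
        ids = tab["protein_id"].to_numpy()
        up_sets[label] = set(ids[(reg == "up") & keep])
        down_sets[label] = set(ids[(reg == "down") & keep])
    joint_up = set.intersection(*up_sets.values()) if up_sets else set()
    joint_down = set.intersection(*down_sets.values()) if down_sets else set()
    return OverlapResult(
        labels=labels,
        up_counts={k: len(v) for k, v in up_sets.items()},
        down_counts={k: len(v) for k, v in down_sets.items()},
        joint_up=len(joint_up),
        joint_down=len(joint_down),
    )


def function_class_summary(table: pd.DataFrame,
                           class_map: Mapping[str, str]) -> pd.DataFrame:
    """Regulation x function-class contingency table.

    ``class_map`` maps protein ids to one of the assumed function classes
    (22 in the standard annotation); proteins without an entry are
    reported under ``unassigned``.  Rows are classes, columns are the
    ``up`` / ``down`` / ``unchanged`` counts.
    """
    classes = table["protein_id"].map(lambda pid: class_map.get(pid, "unassigned"))
    summary = (
        pd.crosstab(classes.rename("function_class"), table["regulation"])
        .reindex(columns=["up", "down", "unchanged"], fill_value=0)
    )
    return summary
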