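"""Detection-pattern filters and differential statistics.

Two branches mirror the two label-free experiments:

* **Total proteome** — complete-case filtering (a protein is tested only when
  detected in all samples, so no value is ever imputed), a paired two-sided
  t-test on log2 intensities within litter pairs, and Benjamini-Hochberg
  q-values; a protein is called decreased/increased at ``q < alpha_q``.

* **Glycosites** — control-anchored filtering (testable when detected in at
  least ``min_control`` of the control samples), a two-sided unpaired t-test
  (Welch by default) on the *detected* log2 values only, significance at
  ``p < alpha_p`` with no FDR step, plus an exclusive-detection rule: a
  feature seen in >= ``min_exclusive`` samples of one genotype and zero of the
  other is reported as ``exclusive_control`` / ``exclusive_mutant`` without a
  test.

Missing values are never replaced by numbers anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CONTROL, MUTANT, QuantMatrix, validate_design

DECREASED = "decreased"
INCREASED = "increased"
UNCHANGED = "unchanged"
EXCLUSIVE_CONTROL = "exclusive_control"
EXCLUSIVE_MUTANT = "exclusive_mutant"
FILTERED_OUT = "filtered_out"

RESULT_COLUMNS = [
    "feature_id",
    "log2_fold_change",
    "p_value",
    "q_value",
    "status",
    "n_detected_control",
    "n_detected_mutant",
    "flag",
]


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def filter_complete_cases(matrix: QuantMatrix) -> tuple[QuantMatrix, list[str]]:
    """Keep rows detected in every sample; everything else is filtered out."""
    complete = matrix.values.notna().all(axis=1)
    retained = matrix.subset(matrix.values.index[complete])
    dropped = list(matrix.values.index[~complete])
    return retained, dropped


def median_center(log2_values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's median log2 intensity (optional normalization)."""
    return log2_values - log2_values.median(axis=0, skipna=True)


def paired_protein_test(
    matrix: QuantMatrix,
    alpha_q: float = 0.05,
    normalize: bool = False,
) -> pd.DataFrame:
    """Paired two-sided t-test per protein with BH q-values.

    Requires a complete-case matrix (run :func:`filter_complete_cases` first)
    and a valid pairing — one control and one mutant sample per pair_id.
    log2 fold change is mutant minus control, averaged over pairs.
    """
    validate_design(matrix.design, paired=True)
    if matrix.values.isna().any().any():
        raise ValueError("paired test requires a complete-case matrix")
    log2 = matrix.log2()
    if normalize:
        log2 = median_center(log2)
    ctrl_by_pair = {s.pair_id: s.sample_id for s in matrix.design if s.genotype == CONTROL}
    mut_by_pair = {s.pair_id: s.sample_id for s in matrix.design if s.genotype == MUTANT}
    pairs = sorted(ctrl_by_pair)
    ctrl = log2[[ctrl_by_pair[p] for p in pairs]].to_numpy()
    mut = log2[[mut_by_pair[p] for p in pairs]].to_numpy()
    diffs = mut - ctrl
    lfc = diffs.mean(axis=1)

    n_features = len(matrix)
    if n_features == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(mut, ctrl, axis=1)
    flag = np.full(n_features, "", dtype=object)
    # tolerance absorbs float noise in log2 of identical ratios
    degenerate = diffs.std(axis=1, ddof=1) < 1e-9
    if degenerate.any():
        # zero-variance differences: p=1 for a flat zero shift, else the
        # smallest representable p, both flagged rather than silently NaN
        zero_shift = degenerate & (np.abs(lfc) < 1e-9)
        p = np.where(zero_shift, 1.0, p)
        p = np.where(degenerate & ~zero_shift, np.finfo(float).tiny, p)
        flag[degenerate] = "degenerate_zero_variance"
    q = bh_qvalues(p)
    status = np.full(n_features, UNCHANGED, dtype=object)
    status[(q < alpha_q) & (lfc < 0)] = DECREASED
    status[(q < alpha_q) & (lfc > 0)] = INCREASED

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2_fold_change": lfc,
            "p_value": p,
            "q_value": q,
            "status": status,
            "n_detected_control": matrix.n_detected(CONTROL).to_numpy(),
            "n_detected_mutant": matrix.n_detected(MUTANT).to_numpy(),
            "flag": flag,
        }
    )


@dataclass
class GlycoPartition:
    """Disjoint split of a glycosite matrix by detection pattern."""

    testable: QuantMatrix
    exclusive_control: list[str]
    exclusive_mutant: list[str]
    filtered_out: list[str]

    def counts(self) -> dict[str, int]:
        return {
            "testable": len(self.testable),
            "exclusive_control": len(self.exclusive_control),
            "exclusive_mutant": len(self.exclusive_mutant),
            "filtered_out": len(self.filtered_out),
        }


def filter_glyco_sites(
    matrix: QuantMatrix,
    min_control: int = 3,
    min_exclusive: int = 3,
) -> GlycoPartition:
    """Partition glycosite features by their detection pattern.

    * ``exclusive_control`` — zero mutant detections, >= *min_exclusive*
      control detections (bypasses the t-test);
    * ``exclusive_mutant`` — the mirror image;
    * ``testable`` — >= *min_control* control detections (and not exclusive);
    * ``filtered_out`` — the rest.

    Every feature lands in exactly one bucket.
    """
    n_ctrl = matrix.n_detected(CONTROL).to_numpy()
    n_mut = matrix.n_detected(MUTANT).to_numpy()
    idx = matrix.values.index
    excl_ctrl = (n_mut == 0) & (n_ctrl >= min_exclusive)
    excl_mut = (n_ctrl == 0) & (n_mut >= min_exclusive)
    testable = (n_ctrl >= min_control) & ~excl_ctrl & ~excl_mut
    rest = ~(excl_ctrl | excl_mut | testable)
    return GlycoPartition(
        testable=matrix.subset(idx[testable]),
        exclusive_control=list(idx[excl_ctrl]),
        exclusive_mutant=list(idx[excl_mut]),
        filtered_out=list(idx[rest]),
    )


def glyco_site_test(
    partition: GlycoPartition,
    alpha_p: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Unpaired two-sided t-test per glycosite on detected log2 values.

    Welch's form by default (``equal_var=False``); at least two detected
    values per genotype are required to test, otherwise the feature is left
    ``unchanged`` with a ``low_coverage`` flag. Exclusive-detection features
    are appended with their own status and no p-value; q_value is undefined
    throughout this branch (the glyco experiment is thresholded on raw p).
    """
    matrix = partition.testable
    log2 = matrix.log2()
    ctrl = log2[matrix.control_columns].to_numpy()
    mut = log2[matrix.mutant_columns].to_numpy()
    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    n_mut = (~np.isnan(mut)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        lfc = np.nanmean(mut, axis=1) - np.nanmean(ctrl, axis=1)

    n = len(matrix)
    p = np.full(n, np.nan)
    flag = np.full(n, "", dtype=object)
    status = np.full(n, UNCHANGED, dtype=object)
    can_test = (n_ctrl >= 2) & (n_mut >= 2)
    if can_test.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                mut[can_test],
                ctrl[can_test],
                axis=1,
                equal_var=equal_var,
                nan_policy="omit",
            )
        p_sub = np.asarray(res.pvalue, dtype=float)
        # identical values in both groups: define p = 1 (no evidence of change)
        degen = np.isnan(p_sub)
        p_sub[degen] = 1.0
        p[can_test] = p_sub
        if degen.any():
            flag_idx = np.flatnonzero(can_test)[degen]
            flag[flag_idx] = "degenerate_zero_variance"
    flag[~can_test] = "low_coverage"
    sig = can_test & (p < alpha_p)
    status[sig & (lfc < 0)] = DECREASED
    status[sig & (lfc > 0)] = INCREASED

    tested = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2_fold_change": lfc,
            "p_value": p,
            "q_value": np.nan,
            "status": status,
            "n_detected_control": n_ctrl,
            "n_detected_mutant": n_mut,
            "flag": flag,
        }
    )
    extras = []
    for feature_ids, excl_status in (
        (partition.exclusive_control, EXCLUSIVE_CONTROL),
        (partition.exclusive_mutant, EXCLUSIVE_MUTANT),
    ):
        if not feature_ids:
            continue
        # counts are recovered from the original (pre-partition) matrix rows
        extras.append(
            pd.DataFrame(
                {
                    "feature_id": feature_ids,
                    "log2_fold_change": np.nan,
                    "p_value": np.nan,
                    "q_value": np.nan,
                    "status": excl_status,
                    "n_detected_control": partition_counts(partition, feature_ids, CONTROL),
                    "n_detected_mutant": partition_counts(partition, feature_ids, MUTANT),
                    "flag": "",
                }
            )
        )
    if extras:
        tested = pd.concat([tested, *extras], ignore_index=True)
    return tested


def partition_counts(
    partition: GlycoPartition, feature_ids: list[str], genotype: str
) -> np.ndarray:
    """Detection counts for exclusive features (kept on the partition object)."""
    counts = getattr(partition, "_detection_counts", None)
    if counts is None:
        return np.zeros(len(feature_ids), dtype=int)
    return counts.loc[feature_ids, genotype].to_numpy()


def attach_detection_counts(partition: GlycoPartition, matrix: QuantMatrix) -> GlycoPartition:
    """Record per-genotype detection counts of the *full* matrix on the partition
    so exclusive features keep their true counts in the result table."""
    counts = pd.DataFrame(
        {
            CONTROL: matrix.n_detected(CONTROL),
            MUTANT: matrix.n_detected(MUTANT),
        }
    )
    partition._detection_counts = counts  # type: ignore[attr-defined]
    return partition


def partition_and_test(
    matrix: QuantMatrix,
    min_control: int = 3,
    min_exclusive: int = 3,
    alpha_p: float = 0.05,
    equal_var: bool = False,
) -> tuple[GlycoPartition, pd.DataFrame]:
    """Convenience wrapper: filter, keep exclusive counts, test."""
    partition = attach_detection_counts(
        filter_glyco_sites(matrix, min_control, min_exclusive), matrix
    )
    return partition, glyco_site_test(partition, alpha_p=alpha_p, equal_var=equal_var)
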