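"""Inter-rater reliability via two-way mixed-model consistency ICCs.

For each item the subjects x raters score matrix is reduced to complete cases
and decomposed by a two-way (subject + rater) ANOVA without interaction.
Consistency ICCs ignore rater main effects (fixed raters, model 3):

    ICC(3,1) = (MS_B - MS_E) / (MS_B + (k - 1) MS_E)
    ICC(3,k) = (MS_B - MS_E) / MS_B

with MS_B the between-subject and MS_E the residual mean square. ICC(3,k) is
the reliability of the k-rater mean and is what the screening threshold is
applied to; the two are linked by the Spearman-Brown relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExclusionLog, ExclusionStage, RatingsTable

_EPS = 1e-12


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class IccResult:
    item: str
    icc31: float
    icc3k: float
    k: int
    n: int
    ms_between_subjects: float
    ms_error: float
    degenerate: bool = False


def icc_twoway_consistency(matrix: np.ndarray | pd.DataFrame, item: str = "") -> IccResult:
    """Consistency ICCs from a complete subjects x raters matrix."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x raters matrix")
    if np.isnan(x).any():
        raise ValueError("matrix must be complete; reduce to complete cases first")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(f"need >=2 subjects and >=2 raters, got {n}x{k}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_b = ss_rows / (n - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    if ms_b < _EPS and ms_e < _EPS:
        return IccResult(item, np.nan, np.nan, k, n, ms_b, ms_e, degenerate=True)
    icc31 = (ms_b - ms_e) / (ms_b + (k - 1) * ms_e)
    icc3k = (ms_b - ms_e) / ms_b if ms_b > _EPS else -np.inf
    return IccResult(item, float(icc31), float(icc3k), k, n, float(ms_b), float(ms_e))


def _complete_case_matrix(ratings: RatingsTable, item: str) -> pd.DataFrame:
    m = ratings.item_matrix(item)
    m = m.loc[:, m.notna().any(axis=0)]  # raters who rated at least one subject
    return m.dropna(axis=0, how="any")


def screen_items_by_reliability(
    ratings: RatingsTable, threshold: float = 0.40
) -> tuple[list[str], ExclusionLog, dict[str, IccResult], dict[str, float]]:
    """Retain items with ICC(3,k) strictly above the threshold.

    The strict inequality means items exactly at the cut-off are dropped
    (the screen removes "<= threshold"). Degenerate items (no between-subject
    variance) are excluded as unreliable. Returns retained items, the
    exclusion log, per-item ICC results and a mean/sd summary over retained
    items for both ICC forms.
    """
    log = ExclusionLog()
    results: dict[str, IccResult] = {}
    retained: list[str] = []
    for item in ratings.items:
        mat = _complete_case_matrix(ratings, item)
        if mat.shape[0] < 2 or mat.shape[1] < 2:
            raise InsufficientDataError(
                f"item {item!r}: fewer than 2 subjects or raters after "
                f"complete-case reduction ({mat.shape[0]}x{mat.shape[1]})"
            )
        res = icc_twoway_consistency(mat.to_numpy(), item=item)
        results[item] = res
        if res.degenerate or not res.icc3k > threshold:
            log.add(item, ExclusionStage.LOW_ICC, res.icc3k, threshold)
        else:
            retained.append(item)
    kept = [results[i] for i in retained]
    summary = {
        "icc31_mean": float(np.mean([r.icc31 for r in kept])) if kept else np.nan,
        "icc31_sd": float(np.std([r.icc31 for r in kept], ddof=1)) if len(kept) > 1 else np.nan,
        "icc3k_mean": float(np.mean([r.icc3k for r in kept])) if kept else np.nan,
        "icc3k_sd": float(np.std([r.icc3k for r in kept], ddof=1)) if len(kept) > 1 else np.nan,
    }
    return retained, log, results, summary


def icc_report(results: dict[str, IccResult], retained: list[str]) -> pd.DataFrame:
    """Per-item ICC report in the layout of the supplementary reliability tables."""
    keep = set(retained)
    rows = [
        {
            "item": r.item,
            "icc31": r.icc31,
            "icc3k": r.icc3k,
            "n": r.n,
            "k": r.k,
            "retained": r.item in keep,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows).set_index("item")
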