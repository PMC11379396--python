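"""Pairwise cross-group comparison of factor loading matrices.

Loading matrices are restricted to their shared items, the source matrix is
orthogonally Procrustes-rotated toward the target, and every factor pair is
scored with Tucker's congruence coefficient and the Pearson correlation of
loadings. Congruence magnitudes are binned with the conventional labels
(good >= 0.95, fair 0.85-0.94, a 0.80 working cut-off, poor around 0.72).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BINS = ("good", "fair", "above-cutoff", "poor", "incongruent")


def congruence_bin(phi: float) -> str:
    """Label a congruence magnitude; labels are descriptive only."""
    a = abs(phi)
    if np.isnan(a):
        return "undefined"
    if a >= 0.95:
        return "good"
    if a >= 0.85:
        return "fair"
    if a >= 0.80:
        return "above-cutoff"
    if a >= 0.70:
        return "poor"
    return "incongruent"


@dataclass
class ComparisonReport:
    pair: tuple[str, str]               # (target id, rotated source id)
    shared_items: list[str]
    phi_matrix: pd.DataFrame            # source factors x target factors
    r_matrix: pd.DataFrame
    bins: pd.DataFrame
    rotation_direction: str = "source->target"

    def to_frame(self) -> pd.DataFrame:
        """Interleaved phi/r layout, one row per source factor."""
        cols = []
        for c in self.phi_matrix.columns:
            cols.append(self.phi_matrix[c].rename(f"{c} (phi)"))
            cols.append(self.r_matrix[c].rename(f"{c} (r)"))
        return pd.concat(cols, axis=1)


def restrict_to_shared_items(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-align two loading matrices on their common items (A's row order)."""
    shared = [i for i in a.index if i in set(b.index)]
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared item(s); need at least 2")
    return a.loc[shared], b.loc[shared]


def procrustes_align(source: pd.DataFrame, target: pd.DataFrame) -> pd.DataFrame:
    """Orthogonal least-squares rotation of ``source`` toward ``target``.

    With M = S'T and SVD M = U D V', the rotation is Q = U V'. A narrower
    matrix is padded with zero columns before rotation so the rotation is
    square. The rotated columns land in the target's factor order; each is
    relabelled with the source factor it is most congruent with (one-to-one,
    by optimal assignment), so reports keep the source's own factor names.
    """
    if not source.index.equals(target.index):
        raise ValueError("matrices must be row-aligned; use restrict_to_shared_items")
    S, T = source.to_numpy(float), target.to_numpy(float)
    ks, kt = S.shape[1], T.shape[1]
    if ks < kt:
        S = np.hstack([S, np.zeros((S.shape[0], kt - ks))])
    elif kt < ks:
        T = np.hstack([T, np.zeros((T.shape[0], ks - kt))])
    M = S.T @ T
    U, _, Vt = np.linalg.svd(M)
    rotated = (S @ U @ Vt)[:, : max(ks, kt)]
    names = _match_names(rotated, source.to_numpy(float), list(source.columns))
    return pd.DataFrame(rotated, index=source.index, columns=names)


def _match_names(rotated: np.ndarray, original: np.ndarray, names: list) -> list:
    """Assign each rotated column the nearest original factor name (1-1)."""
    from scipy.optimize import linear_sum_assignment

    kr, ko = rotated.shape[1], original.shape[1]
    cost = np.zeros((kr, ko))
    for i in range(kr):
        for j in range(ko):
            c = tucker_congruence(rotated[:, i], original[:, j])
            cost[i, j] = -abs(c) if not np.isnan(c) else 0.0
    rows, cols = linear_sum_assignment(cost)
    out = [f"unassigned-{i + 1}" for i in range(kr)]
    for i, j in zip(rows, cols):
        out[i] = names[j]
    return out


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's coefficient: the cosine between two loading vectors."""
    nx, ny = np.sqrt(np.sum(x**2)), np.sqrt(np.sum(y**2))
    if nx == 0 or ny == 0:
        return np.nan
    return float(np.sum(x * y) / (nx * ny))


def compare_loadings(
    source_rotated: pd.DataFrame,
    target: pd.DataFrame,
    pair: tuple[str, str] = ("target", "source"),
) -> ComparisonReport:
    """Congruence, loading correlation and bin for every factor pair."""
    if not source_rotated.index.equals(target.index):
        raise ValueError("matrices must be row-aligned")
    # unassigned rotated columns (a narrower source padded up to the target's
    # factor count) are genuine mixtures of the source factors; keep them
    src_names = list(source_rotated.columns)
    phi = pd.DataFrame(index=src_names, columns=target.columns, dtype=float)
    r = phi.copy()
    for sc in src_names:
        x = source_rotated[sc].to_numpy(float)
        for tc in target.columns:
            y = target[tc].to_numpy(float)
            phi.loc[sc, tc] = tucker_congruence(x, y)
            r.loc[sc, tc] = (
                np.nan if x.std() == 0 or y.std() == 0 else float(np.corrcoef(x, y)[0, 1])
            )
    bins = phi.map(congruence_bin)
    return ComparisonReport(
        pair=pair,
        shared_items=list(target.index),
        phi_matrix=phi,
        r_matrix=r,
        bins=bins,
    )


def compare_solution_pair(
    loadings_target: pd.DataFrame,
    loadings_source: pd.DataFrame,
    pair: tuple[str, str] = ("target", "source"),
) -> ComparisonReport:
    """Full pipeline for one pair: shared items, Procrustes, congruence."""
    t, s = restrict_to_shared_items(loadings_target, loadings_source)
    s_rot = procrustes_align(s, t)
    report = compare_loadings(s_rot, t, pair=pair)
    order = [c for c in loadings_source.columns if c in report.phi_matrix.index]
    order += [c for c in report.phi_matrix.index if c not in order]
    report.phi_matrix = report.phi_matrix.loc[order]
    report.r_matrix = report.r_matrix.loc[order]
    report.bins = report.bins.loc[order]
    return report
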