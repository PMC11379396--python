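"""ten Berge correlation-preserving factor scores.

Unlike regression scores, ten Berge scores are constructed so that the
correlations among the score columns equal the inter-factor correlation
matrix of the model: with standardized data Z, pattern L and factor
correlations Phi,

    A = L Phi^{1/2}
    C = R^{-1/2} A (A' R^{-1} A)^{-1/2}
    W = R^{-1/2} C Phi^{1/2}
    scores = Z W

Matrix square roots are symmetric eigendecompositions with a small
eigenvalue floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .efa import FactorSolution

_EIG_FLOOR = 1e-10


@dataclass
class ScoreMatrix:
    scores: pd.DataFrame        # subjects x factors
    method: str = "tenberge"
    dropped_subjects: tuple[str, ...] = ()
    ridge_flag: bool = False

    @property
    def subjects(self) -> list[str]:
        return list(self.scores.index)

    @property
    def factors(self) -> list[str]:
        return list(self.scores.columns)


def _sym_power(mat: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, _EIG_FLOOR, None)
    return (vecs * vals**power) @ vecs.T


def tenberge_factor_scores(m, solution: FactorSolution) -> ScoreMatrix:
    """Score every subject with complete data on the solution's items."""
    data = m.values[list(solution.items)]
    complete = data.dropna(axis=0, how="any")
    dropped = tuple(i for i in data.index if i not in complete.index)
    X = complete.to_numpy(float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    ridge = False
    if np.linalg.eigvalsh(R).min() < _EIG_FLOOR:
        ridge = True
    L = solution.loadings.to_numpy(float)
    phi = solution.phi.to_numpy(float)
    phi_half = _sym_power(phi, 0.5)
    r_inv_half = _sym_power(R, -0.5)
    r_inv = _sym_power(R, -1.0)
    A = L @ phi_half
    C = r_inv_half @ A @ _sym_power(A.T @ r_inv @ A, -0.5)
    W = r_inv_half @ C @ phi_half
    scores = pd.DataFrame(Z @ W, index=complete.index, columns=solution.loadings.columns)
    return ScoreMatrix(scores=scores, dropped_subjects=dropped, ridge_flag=ridge)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def score_correlation_matrix(a: ScoreMatrix, b: ScoreMatrix):
    """Pearson correlations between two score matrices on shared subjects.

    Returns (r matrix, two-sided p values uncorrected for multiple
    comparisons, star annotations). Subjects missing from either matrix are
    dropped; zero-variance columns give NaN.
    """
    shared = a.scores.index.intersection(b.scores.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared subjects")
    A, B = a.scores.loc[shared], b.scores.loc[shared]
    r = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    p = r.copy()
    for fa in A.columns:
        for fb in B.columns:
            x, y = A[fa].to_numpy(), B[fb].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r.loc[fa, fb] = np.nan
                p.loc[fa, fb] = np.nan
            else:
                res = sps.pearsonr(x, y)
                r.loc[fa, fb] = res.statistic
                p.loc[fa, fb] = res.pvalue
    stars = p.map(_stars)
    return r, p, stars
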