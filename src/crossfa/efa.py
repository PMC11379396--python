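"""Exploratory factor analysis: minres extraction with oblimin rotation.

The extraction minimizes the sum of squared off-diagonal residuals of
R - Lambda Lambda' over the uniquenesses (minres / unweighted least squares);
given uniquenesses u^2, the loadings are the scaled top-k eigenvectors of
R - diag(u^2). Rotation is quartimin (oblimin with gamma = 0) by gradient
projection. The number of factors is voted by parallel analysis, empirical
BIC and very-simple-structure (complexity 1), with the median taken when they
disagree. An exclusion loop removes items with inadequate sampling adequacy
(MSA < 0.50) or out-of-range communalities (<= 0.4 or >= 0.99) and refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import ExclusionLog, ExclusionStage, MeanRatingsMatrix

HEYWOOD_FLOOR = 1e-3


class SingularCorrelationError(ValueError):
    pass


class UnderIdentifiedError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationModel:
    items: tuple[str, ...]
    R: np.ndarray          # items x items Pearson correlations
    n: int                 # minimum pairwise-complete sample size

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.items, columns=self.items)


@dataclass(frozen=True)
class FactorCountVote:
    k_parallel: int
    k_ebic: int
    k_vss: int

    @property
    def k_chosen(self) -> int:
        return int(np.median([self.k_parallel, self.k_ebic, self.k_vss]))


@dataclass
class FactorSolution:
    items: tuple[str, ...]
    k: int
    loadings: pd.DataFrame            # pattern matrix, items x factors
    phi: pd.DataFrame                 # inter-factor correlations
    communalities: pd.Series
    uniquenesses: pd.Series
    variance_proportions: pd.Series
    cumulative_variance: float
    rmsr: float
    rmsr_df_corrected: float
    root_sum_sq_resid: float
    alpha: float
    omega_total: float
    msa: pd.Series
    heywood_items: tuple[str, ...] = ()
    warnings_: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        out = self.loadings.copy()
        out["h2"] = self.communalities
        out["u2"] = self.uniquenesses
        out["msa"] = self.msa
        out.to_csv(path, index_label="item")


def correlation_model(m: MeanRatingsMatrix) -> CorrelationModel:
    """Pairwise-complete Pearson correlations of the rater-averaged matrix."""
    vals = m.values
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    constant = [c for c in vals.columns if vals[c].nunique(dropna=True) <= 1]
    if constant:
        raise ValueError(f"constant column(s): {', '.join(map(str, constant))}")
    R = vals.corr(min_periods=2).to_numpy()
    notna = vals.notna().to_numpy().astype(int)
    pair_n = notna.T @ notna
    return CorrelationModel(tuple(vals.columns), R, int(pair_n.min()))


def smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations of each item with all the others."""
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(R)
    return 1.0 - 1.0 / np.diag(inv)


def kmo_msa(cm: CorrelationModel, ridge_fallback: bool = True):
    """Per-item measure of sampling adequacy and the overall KMO index.

    MSA_j compares item j's squared marginal correlations against its squared
    anti-image (partial) correlations; values near 1 mean the correlation
    structure is dominated by shared variance and is factorable.
    """
    R = cm.R
    flagged = False
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        if not ridge_fallback:
            raise SingularCorrelationError("correlation matrix is singular")
        inv = np.linalg.inv(R + 1e-8 * np.eye(len(R)))
        flagged = True
    d = 1.0 / np.sqrt(np.diag(inv))
    Q = -inv * np.outer(d, d)          # anti-image partial correlations
    np.fill_diagonal(Q, 0.0)
    R0 = R - np.diag(np.diag(R))
    r2 = (R0**2).sum(axis=0)
    q2 = (Q**2).sum(axis=0)
    with np.errstate(invalid="ignore"):
        msa = r2 / (r2 + q2)
    overall = r2.sum() / (r2.sum() + q2.sum()) if (r2.sum() + q2.sum()) > 0 else np.nan
    msa_s = pd.Series(msa, index=cm.items, name="msa")
    return msa_s, float(overall), flagged


def model_df(p: int, k: int) -> int:
    """Residual degrees of freedom of a k-factor model on p items."""
    return p * (p - 1) // 2 - p * k + k * (k - 1) // 2


def _eig_loadings(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R - np.diag(psi))
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _offdiag_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    L = _eig_loadings(R, psi, k)
    E = R - L @ L.T
    np.fill_diagonal(E, 0.0)
    return float(np.sum(E**2))


def fit_minres(cm: CorrelationModel, k: int):
    """Unrotated minres loadings.

    Returns (loadings, uniquenesses, objective, heywood_flags). Columns are
    ordered by explained variance, signed so each column sum is non-negative.
    Uniquenesses hitting the lower bound are clamped and flagged (Heywood).
    """
    R, p = cm.R, len(cm.items)
    if k < 1:
        raise ValueError("k must be >= 1")
    if model_df(p, k) < 0:
        raise UnderIdentifiedError(f"negative degrees of freedom for p={p}, k={k}")
    start = np.clip(1.0 - smc(R), HEYWOOD_FLOOR, 1.0)
    res = optimize.minimize(
        _offdiag_objective,
        start,
        args=(R, k),
        method="L-BFGS-B",
        bounds=[(HEYWOOD_FLOOR, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"minres failed to converge: {res.message}")
    psi = res.x
    L = _eig_loadings(R, psi, k)
    # order by column sum of squares, then fix signs
    order = np.argsort((L**2).sum(axis=0))[::-1]
    L = L[:, order]
    L *= np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    heywood = psi <= HEYWOOD_FLOOR + 1e-12
    return L, psi, float(res.fun), heywood


def _quartimin_vgq(L: np.ndarray):
    L2 = L**2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    f = np.sum(L2 * (L2 @ N)) / 4.0
    G = L * (L2 @ N)
    return f, G


def rotate_oblimin(L0: np.ndarray, max_iter: int = 1000, tol: float = 1e-7):
    """Quartimin rotation by oblique gradient projection from the identity.

    Returns (pattern, phi, criterion_trace). For a single factor the input is
    returned unchanged with phi = [[1]].
    """
    p, k = L0.shape
    if k == 1:
        return L0.copy(), np.ones((1, 1)), [0.0]
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = L0 @ Ti.T
    f, Gq = _quartimin_vgq(L)
    G = -(L.T @ Gq @ Ti).T
    trace = [f]
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            Tt = X / np.sqrt((X**2).sum(axis=0))
            Ti = np.linalg.inv(Tt)
            L = L0 @ Ti.T
            ft, Gq = _quartimin_vgq(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        else:
            break  # step size exhausted: no further descent possible
        T, f = Tt, ft
        G = -(L.T @ Gq @ Ti).T
        trace.append(f)
    else:
        raise RuntimeError(f"oblimin did not converge; criterion trace {trace[-5:]}")
    phi = T.T @ T
    return L, phi, trace


def _normalize_solution(L: np.ndarray, phi: np.ndarray):
    """Order factors by explained variance (descending) and fix column signs."""
    try:
        C = np.linalg.cholesky(phi)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(phi)
        C = vecs * np.sqrt(np.clip(vals, 0, None))
    ss = ((L @ C) ** 2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    L = L * signs
    phi = phi * np.outer(signs, signs)
    return L, phi


def fit_factor_model(cm: CorrelationModel, k: int):
    """Minres extraction followed by quartimin rotation, normalized."""
    L0, psi, obj, heywood = fit_minres(cm, k)
    L, phi, _ = rotate_oblimin(L0)
    L, phi = _normalize_solution(L, phi)
    return L, phi, psi, obj, heywood


def residual_correlations(R: np.ndarray, L: np.ndarray, phi: np.ndarray | None = None) -> np.ndarray:
    model = L @ (phi if phi is not None else np.eye(L.shape[1])) @ L.T
    E = R - model
    np.fill_diagonal(E, 0.0)
    return E


def parallel_analysis(
    m: MeanRatingsMatrix | CorrelationModel,
    n_iter: int = 20,
    seed: int | np.random.Generator = 0,
    n: int | None = None,
    quantile: float | None = 95.0,
) -> int:
    """Factor count by comparing reduced-matrix eigenvalues to random data.

    Observed eigenvalues come from R with squared multiple correlations on the
    diagonal; the reference comes from ``n_iter`` standard-normal datasets of
    the same shape, processed identically, summarized at ``quantile`` (the
    mean when ``quantile`` is None; the percentile reference keeps the false-
    positive rate on pure noise near the nominal level, which the mean
    reference cannot). The count is the number of leading observed
    eigenvalues above their random counterpart.
    """
    if isinstance(m, CorrelationModel):
        R, n_obs = m.R, n or m.n
    else:
        cm = correlation_model(m)
        R, n_obs = cm.R, cm.n
    p = R.shape[0]
    if n_obs < 20:
        raise ValueError("need n >= 20 subjects for a stable reference distribution")

    def reduced_eigs(mat: np.ndarray) -> np.ndarray:
        red = mat.copy()
        np.fill_diagonal(red, smc(mat))
        return np.sort(np.linalg.eigvalsh(red))[::-1]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = np.empty((n_iter, p))
    for i in range(n_iter):
        X = rng.standard_normal((n_obs, p))
        sims[i] = reduced_eigs(np.corrcoef(X, rowvar=False))
    ref = sims.mean(axis=0) if quantile is None else np.percentile(sims, quantile, axis=0)
    obs = reduced_eigs(R)
    above = obs > ref
    k = 0
    for flag in above:
        if not flag:
            break
        k += 1
    return max(k, 1)


def vss_complexity1(cm: CorrelationModel, k_max: int):
    """Very-simple-structure criterion keeping one loading per item.

    For each candidate k the rotated pattern is simplified to its largest
    absolute entry per row and the fit of the simplified model is
    1 - sum(resid^2) / sum(offdiag r^2). Returns (per-k statistic, argmax).
    """
    if k_max >= len(cm.items) / 2:
        raise ValueError("k_max must be below items/2")
    denom = np.sum((cm.R - np.diag(np.diag(cm.R))) ** 2)
    stats: dict[int, float] = {}
    for k in range(1, k_max + 1):
        try:
            L, phi, *_ = fit_factor_model(cm, k)
        except RuntimeError as err:  # pragma: no cover - rare non-convergence
            warnings.warn(f"VSS: skipping k={k}: {err}")
            continue
        Ls = np.zeros_like(L)
        idx = np.abs(L).argmax(axis=1)
        rows = np.arange(L.shape[0])
        Ls[rows, idx] = L[rows, idx]
        E = residual_correlations(cm.R, Ls, phi)
        stats[k] = 1.0 - np.sum(E**2) / denom
    if not stats:
        raise RuntimeError("VSS failed at every candidate k")
    best = max(stats.values())
    k_vss = min(k for k, v in stats.items() if v >= best - 1e-9)  # ties -> parsimony
    return stats, k_vss


def empirical_bic(cm: CorrelationModel, k_max: int):
    """Empirical BIC over k: residual chi-square minus df * ln(n).

    eChisq_k = n * sum of squared off-diagonal residual correlations of the
    k-factor fit; the argmin over k with positive df is returned.
    """
    p, n = len(cm.items), cm.n
    stats: dict[int, float] = {}
    any_df = False
    for k in range(1, k_max + 1):
        df = model_df(p, k)
        if df <= 0:
            continue
        any_df = True
        L0, *_ = fit_minres(cm, k)
        E = residual_correlations(cm.R, L0)
        echisq = n * np.sum(E[np.triu_indices(p, 1)] ** 2)
        stats[k] = echisq - df * np.log(n)
    if not any_df:
        raise UnderIdentifiedError("no candidate k has positive degrees of freedom")
    k_ebic = min(stats, key=stats.get)
    return stats, k_ebic


def choose_n_factors(k_parallel: int, k_ebic: int, k_vss: int) -> FactorCountVote:
    return FactorCountVote(k_parallel, k_ebic, k_vss)


def vote_n_factors(
    cm: CorrelationModel, k_max: int, seed: int | np.random.Generator = 0,
    pa_iter: int = 20,
) -> FactorCountVote:
    k_pa = parallel_analysis(cm, n_iter=pa_iter, seed=seed)
    _, k_vss = vss_complexity1(cm, k_max)
    _, k_ebic = empirical_bic(cm, k_max)
    return choose_n_factors(k_pa, k_ebic, k_vss)


def model_fit_stats(cm: CorrelationModel, L: np.ndarray, phi: np.ndarray, psi: np.ndarray):
    """RMSR (plain and df-corrected), alpha, omega_total, variance shares."""
    R, p = cm.R, len(cm.items)
    k = L.shape[1]
    E = residual_correlations(R, L, phi)
    ssr = float(np.sum(E[np.triu_indices(p, 1)] ** 2))
    rmsr = np.sqrt(ssr / (p * (p - 1) / 2))
    df = model_df(p, k)
    rmsr_df = np.sqrt(ssr / df) if df > 0 else np.nan
    total = float(R.sum())
    alpha = p / (p - 1) * (1.0 - p / total)
    omega_total = 1.0 - float(psi.sum()) / total
    try:
        C = np.linalg.cholesky(phi)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(phi)
        C = vecs * np.sqrt(np.clip(vals, 0, None))
    var_prop = ((L @ C) ** 2).sum(axis=0) / p
    return {
        "rmsr": float(rmsr),
        "rmsr_df_corrected": float(rmsr_df),
        "root_sum_sq_resid": float(np.sqrt(ssr)),
        "alpha": float(alpha),
        "omega_total": float(omega_total),
        "variance_proportions": var_prop,
        "cumulative_variance": float(var_prop.sum()),
    }


@dataclass(frozen=True)
class EfaConfig:
    msa_threshold: float = 0.50
    communality_low: float = 0.40
    communality_high: float = 0.99
    residual_check: float = 0.10
    k_max: int = 8
    max_iterations: int = 10
    freeze_k: int | None = None
    pa_iter: int = 20


def item_exclusion_loop(
    m: MeanRatingsMatrix,
    config: EfaConfig = EfaConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[FactorSolution, ExclusionLog, FactorCountVote]:
    """MSA / communality screening loop around the factor fit.

    Each pass drops items with MSA below threshold, (re-)votes the factor
    count, fits minres + quartimin, then drops items whose communality is at
    or below the lower bound or at or above the upper bound. The loop stops at
    a fixed point (or after ``max_iterations``), then checks that every
    retained item has adequate MSA and that the root sum of squared residual
    correlations is below the configured bound, warning otherwise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    work = m.values.copy()
    log = ExclusionLog()
    vote: FactorCountVote | None = None
    notes: list[str] = []
    for _ in range(config.max_iterations):
        cm = correlation_model(MeanRatingsMatrix(work, m.n_raters_per_cell[work.columns]))
        msa, _, _ = kmo_msa(cm)
        low_msa = msa[msa < config.msa_threshold]
        if len(low_msa):
            for item, v in low_msa.items():
                log.add(item, ExclusionStage.LOW_MSA, v, config.msa_threshold)
            work = work.drop(columns=list(low_msa.index))
            cm = correlation_model(MeanRatingsMatrix(work, m.n_raters_per_cell[work.columns]))
            msa, _, _ = kmo_msa(cm)
        k_max = min(config.k_max, (len(cm.items) - 1) // 2)
        if config.freeze_k is not None:
            k = config.freeze_k
            vote = vote or FactorCountVote(k, k, k)
        else:
            vote = vote_n_factors(cm, k_max, seed=rng, pa_iter=config.pa_iter)
            k = vote.k_chosen
        if len(cm.items) < 3 * k:
            raise UnderIdentifiedError(
                f"only {len(cm.items)} items left for k={k} factors"
            )
        L, phi, psi, _, heywood = fit_factor_model(cm, k)
        h2 = 1.0 - psi
        bad_low = [i for i, v in zip(cm.items, h2) if v <= config.communality_low]
        bad_high = [i for i, v in zip(cm.items, h2) if v >= config.communality_high]
        if not bad_low and not bad_high:
            break
        for item in bad_low:
            log.add(item, ExclusionStage.LOW_COMMUNALITY,
                    h2[cm.items.index(item)], config.communality_low)
        for item in bad_high:
            log.add(item, ExclusionStage.HIGH_COMMUNALITY,
                    h2[cm.items.index(item)], config.communality_high)
        work = work.drop(columns=bad_low + bad_high)
    else:
        notes.append("exclusion loop hit the iteration cap before reaching a fixed point")

    stats = model_fit_stats(cm, L, phi, psi)
    if (msa < config.msa_threshold).any():
        notes.append("final model has items with MSA below threshold")
    if stats["root_sum_sq_resid"] >= config.residual_check:
        notes.append(
            f"root sum of squared residuals {stats['root_sum_sq_resid']:.3f} "
            f"exceeds {config.residual_check}"
        )
    for msg in notes:
        warnings.warn(msg)
    factors = [f"F{i + 1}" for i in range(L.shape[1])]
    solution = FactorSolution(
        items=cm.items,
        k=L.shape[1],
        loadings=pd.DataFrame(L, index=cm.items, columns=factors),
        phi=pd.DataFrame(phi, index=factors, columns=factors),
        communalities=pd.Series(1.0 - psi, index=cm.items, name="h2"),
        uniquenesses=pd.Series(psi, index=cm.items, name="u2"),
        variance_proportions=pd.Series(stats["variance_proportions"], index=factors),
        cumulative_variance=stats["cumulative_variance"],
        rmsr=stats["rmsr"],
        rmsr_df_corrected=stats["rmsr_df_corrected"],
        root_sum_sq_resid=stats["root_sum_sq_resid"],
        alpha=stats["alpha"],
        omega_total=stats["omega_total"],
        msa=msa,
        heywood_items=tuple(i for i, h in zip(cm.items, heywood) if h),
        warnings_=notes,
    )
    return solution, log, vote
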