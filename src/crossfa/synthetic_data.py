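"""Synthetic multi-rater ratings with known latent personality structure.

The generator emulates the design of a multi-site rating study: several
species groups of 77-150 subjects, 4-5 raters per site with occasional
skipped (rater, subject) pairs, ~50 survey items with an oblique
simple-structure factor model, and a paired second rating situation whose
latent factor scores correlate with the first at a configurable rho.

The measurement chain per record is

    score = true_value + rater_bias(rater, item) + noise

optionally discretized to a 1-7 scale and per-rater mean-centered. Rater
bias is constant over subjects, which is exactly the structure that
consistency ICCs are designed to ignore, so the reliability module's
contract is directly testable. True values have unit variance, hence the
closed-form single-rater reliability 1 / (1 + noise_sd^2) on the continuous
scale; discretization attenuation is estimated by Monte Carlo and stored in
the truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MeanRatingsMatrix, RatingsTable, Situation, load_catalogs
from .factor_scores import _sym_power

_CUTS = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])


@dataclass(frozen=True)
class GroupSpec:
    group_id: str
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for one synthetic dataset."""

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("rhesus", 150, 5),
        GroupSpec("longtailed", 101, 4),
        GroupSpec("bonnet", 77, 5),
    )
    items: tuple[str, ...] | None = None        # default: the packaged general catalog
    true_k: int = 5
    loading: float | tuple[float, ...] = (0.8, 0.85, 0.9)
    phi_offdiag: float = 0.2
    rater_bias_sd: float = 0.3
    rater_noise_sd: float = 1.4
    missing_rater_prob: float = 0.10
    scale: str = "1-7"                          # or "continuous"
    rater_center: bool = True
    cross_situation_rho: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rater_prob < 1:
            raise ValueError("missing_rater_prob must be in [0, 1)")
        if not -1 <= self.cross_situation_rho <= 1:
            raise ValueError("cross_situation_rho must be in [-1, 1]")
        if self.scale not in ("1-7", "continuous"):
            raise ValueError("scale must be '1-7' or 'continuous'")
        if self.true_k < 1:
            raise ValueError("true_k must be >= 1")

    def resolved_items(self) -> tuple[str, ...]:
        if self.items is not None:
            return tuple(self.items)
        return tuple(load_catalogs()[Situation.GENERAL].items)


@dataclass
class Truth:
    """Everything the generator knows that an analyst would have to infer."""

    loadings: pd.DataFrame              # items x factors, generating pattern
    phi: np.ndarray
    uniquenesses: pd.Series
    latents: dict[str, pd.DataFrame]    # group -> subjects x factors ("general")
    latents_human: dict[str, pd.DataFrame] = field(default_factory=dict)
    expected_icc31: float = np.nan      # continuous-scale closed form
    attenuation_item_mean: float = np.nan   # multiplies a true cross-situation r
    expected_item_cross_r: float = np.nan
    config: GeneratorConfig | None = None


def _build_model(cfg: GeneratorConfig):
    items = cfg.resolved_items()
    p, k = len(items), cfg.true_k
    mags = np.resize(np.atleast_1d(np.asarray(cfg.loading, float)), p)
    primary = np.arange(p) % k
    lam = np.zeros((p, k))
    lam[np.arange(p), primary] = mags
    phi = np.full((k, k), cfg.phi_offdiag)
    np.fill_diagonal(phi, 1.0)
    if np.linalg.eigvalsh(phi).min() <= 0:
        raise ValueError("phi_offdiag gives a non-positive-definite factor correlation")
    h2 = np.einsum("ij,jk,ik->i", lam, phi, lam)
    if (h2 >= 1).any():
        raise ValueError("communalities reach 1; lower the loadings")
    u2 = 1.0 - h2
    return items, lam, phi, u2


def _discretize(x: np.ndarray) -> np.ndarray:
    return (np.digitize(x, _CUTS) + 1).astype(float)


def _rate_group(
    true_vals: np.ndarray,
    spec: GroupSpec,
    items: tuple[str, ...],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    situation: Situation,
) -> RatingsTable:
    n, p = true_vals.shape
    subjects = [f"{spec.group_id}-s{j:03d}" for j in range(n)]
    frames = []
    present = np.ones((spec.n_raters, n), dtype=bool)
    if cfg.missing_rater_prob > 0:
        present = rng.random((spec.n_raters, n)) >= cfg.missing_rater_prob
        none_left = ~present.any(axis=0)
        present[rng.integers(0, spec.n_raters, size=n), np.arange(n)] |= none_left
    for r in range(spec.n_raters):
        bias = rng.normal(0.0, cfg.rater_bias_sd, size=p)
        noise = rng.normal(0.0, cfg.rater_noise_sd, size=(n, p))
        scores = true_vals + bias + noise
        if cfg.scale == "1-7":
            scores = _discretize(scores)
        if cfg.rater_center:
            scores = scores - scores[present[r]].mean()
        mask = present[r]
        frames.append(
            pd.DataFrame(
                {
                    "rater": f"{spec.group_id}-r{r}",
                    "subject": np.repeat(np.asarray(subjects)[mask], p),
                    "item": np.tile(items, mask.sum()),
                    "score": scores[mask].ravel(),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return RatingsTable(site_id=spec.group_id, situation=situation, records=records)


def _mc_attenuation(cfg: GeneratorConfig, k_raters: float, rho: float) -> float:
    """Monte-Carlo ratio (observed item cross-r) / rho under the full chain."""
    rng = np.random.default_rng(12345)  # internal, independent of data seeds
    n = 200_000
    k = max(int(round(k_raters)), 1)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    t = rng.multivariate_normal([0, 0], cov, size=n)
    means = np.zeros((n, 2))
    for side in range(2):
        acc = np.zeros(n)
        for r in range(k):
            y = t[:, side] + rng.normal(0, cfg.rater_bias_sd) + rng.normal(
                0, cfg.rater_noise_sd, size=n
            )
            if cfg.scale == "1-7":
                y = _discretize(y)
            acc += y
        means[:, side] = acc / k
    r_obs = np.corrcoef(means[:, 0], means[:, 1])[0, 1]
    return float(r_obs / rho) if rho != 0 else np.nan


def generate_ratings_dataset(
    cfg: GeneratorConfig,
) -> tuple[dict[str, RatingsTable], Truth]:
    """One-situation dataset: per-group ratings tables plus the truth record."""
    items, lam, phi, u2 = _build_model(cfg)
    rng = np.random.default_rng(cfg.seed)
    chol = np.linalg.cholesky(phi)
    tables: dict[str, RatingsTable] = {}
    latents: dict[str, pd.DataFrame] = {}
    for spec in cfg.groups:
        F = rng.standard_normal((spec.n_subjects, cfg.true_k)) @ chol.T
        unique = rng.standard_normal((spec.n_subjects, len(items))) * np.sqrt(u2)
        true_vals = F @ lam.T + unique
        tables[spec.group_id] = _rate_group(true_vals, spec, items, cfg, rng, Situation.GENERAL)
        latents[spec.group_id] = pd.DataFrame(
            F,
            index=[f"{spec.group_id}-s{j:03d}" for j in range(spec.n_subjects)],
            columns=[f"T{i + 1}" for i in range(cfg.true_k)],
        )
    factors = [f"T{i + 1}" for i in range(cfg.true_k)]
    k_eff = np.mean([g.n_raters for g in cfg.groups]) * (1 - cfg.missing_rater_prob)
    truth = Truth(
        loadings=pd.DataFrame(lam, index=items, columns=factors),
        phi=phi,
        uniquenesses=pd.Series(u2, index=items, name="u2"),
        latents=latents,
        expected_icc31=1.0 / (1.0 + cfg.rater_noise_sd**2),
        attenuation_item_mean=1.0 / (1.0 + cfg.rater_noise_sd**2 / k_eff)
        if cfg.scale == "continuous"
        else _mc_attenuation(cfg, k_eff, 0.7),
        config=cfg,
    )
    truth.expected_item_cross_r = cfg.cross_situation_rho * truth.attenuation_item_mean
    return tables, truth


def generate_paired_situation_dataset(
    cfg: GeneratorConfig,
) -> tuple[dict[str, RatingsTable], dict[str, RatingsTable], Truth]:
    """Paired general + human-situation ratings with correlated latents.

    The two situations share the generating loadings; their factor scores
    (and item-unique parts) are jointly normal with correlation
    ``cross_situation_rho``, so the true cross-situation correlation of an
    item's value equals rho exactly. The human catalog drops the eight items
    excluded from human-situation rating.
    """
    items, lam, phi, u2 = _build_model(cfg)
    catalogs = load_catalogs()
    human_excluded = catalogs[Situation.GENERAL].excluded_from_human
    human_idx = [i for i, it in enumerate(items) if it not in human_excluded]
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.cross_situation_rho
    k = cfg.true_k
    joint_phi = np.block([[phi, rho * phi], [rho * phi, phi]])
    chol = np.linalg.cholesky(joint_phi + 1e-12 * np.eye(2 * k))
    gen_tables: dict[str, RatingsTable] = {}
    hum_tables: dict[str, RatingsTable] = {}
    latents_g: dict[str, pd.DataFrame] = {}
    latents_h: dict[str, pd.DataFrame] = {}
    for spec in cfg.groups:
        F = rng.standard_normal((spec.n_subjects, 2 * k)) @ chol.T
        Fg, Fh = F[:, :k], F[:, k:]
        z = rng.standard_normal((spec.n_subjects, len(items), 2))
        eg = z[:, :, 0]
        eh = rho * z[:, :, 0] + np.sqrt(1 - rho**2) * z[:, :, 1]
        true_g = Fg @ lam.T + eg * np.sqrt(u2)
        true_h = Fh @ lam.T + eh * np.sqrt(u2)
        gen_tables[spec.group_id] = _rate_group(true_g, spec, items, cfg, rng, Situation.GENERAL)
        hum_tables[spec.group_id] = _rate_group(
            true_h[:, human_idx],
            spec,
            tuple(items[i] for i in human_idx),
            cfg,
            rng,
            Situation.HUMAN,
        )
        subj = [f"{spec.group_id}-s{j:03d}" for j in range(spec.n_subjects)]
        cols = [f"T{i + 1}" for i in range(k)]
        latents_g[spec.group_id] = pd.DataFrame(Fg, index=subj, columns=cols)
        latents_h[spec.group_id] = pd.DataFrame(Fh, index=subj, columns=cols)
    k_eff = np.mean([g.n_raters for g in cfg.groups]) * (1 - cfg.missing_rater_prob)
    truth = Truth(
        loadings=pd.DataFrame(lam, index=items, columns=[f"T{i + 1}" for i in range(k)]),
        phi=phi,
        uniquenesses=pd.Series(u2, index=items, name="u2"),
        latents=latents_g,
        latents_human=latents_h,
        expected_icc31=1.0 / (1.0 + cfg.rater_noise_sd**2),
        attenuation_item_mean=1.0 / (1.0 + cfg.rater_noise_sd**2 / k_eff)
        if cfg.scale == "continuous"
        else _mc_attenuation(cfg, k_eff, rho if rho else 0.7),
        config=cfg,
    )
    truth.expected_item_cross_r = rho * truth.attenuation_item_mean
    return gen_tables, hum_tables, truth


def expected_score_validity(truth: Truth, group: GroupSpec, items: list[str] | None = None) -> np.ndarray:
    """Population correlation of ten Berge scores with the true latents.

    Derived analytically from the generating parameters on the continuous
    scale: the population correlation matrix of rater-averaged items is
    Lambda Phi Lambda' + diag(u^2 + noise^2 / k) rescaled to unit diagonal,
    and the score weights follow the ten Berge construction on that matrix.
    """
    cfg = truth.config
    lam_full = truth.loadings
    if items is not None:
        lam_full = lam_full.loc[items]
    lam = lam_full.to_numpy(float)
    u2 = truth.uniquenesses.loc[lam_full.index].to_numpy(float)
    phi = truth.phi
    k_eff = group.n_raters * (1 - cfg.missing_rater_prob)
    sig2 = cfg.rater_noise_sd**2 / k_eff
    cov = lam @ phi @ lam.T + np.diag(u2 + sig2)
    d = np.sqrt(np.diag(cov))
    Rpop = cov / np.outer(d, d)
    lam_std = lam / d[:, None]
    phi_half = _sym_power(phi, 0.5)
    r_inv_half = _sym_power(Rpop, -0.5)
    r_inv = _sym_power(Rpop, -1.0)
    A = lam_std @ phi_half
    C = r_inv_half @ A @ _sym_power(A.T @ r_inv @ A, -0.5)
    W = r_inv_half @ C @ phi_half
    cov_sf = W.T @ (lam_std @ phi)          # cov(score, latent), factors x factors
    var_s = np.diag(W.T @ Rpop @ W)
    return np.diag(cov_sf) / np.sqrt(var_s)


def aggregate_all(tables: dict[str, RatingsTable]) -> dict[str, MeanRatingsMatrix]:
    from .data_model import aggregate_mean_ratings

    return {g: aggregate_mean_ratings(t) for g, t in tables.items()}
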