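"""End-to-end orchestration: screen, fit, compare, intersect, score.

``run_full_pipeline`` takes ratings per (group, situation), applies the
reliability screen, rater averaging and the EFA exclusion loop per branch,
then runs all pairwise structural comparisons within each situation, the
fuzzy-set stage when a mapping is supplied, and cross-situation ten Berge
score correlations per group. Each branch failure is logged and the other
branches continue.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    ExclusionLog,
    MeanRatingsMatrix,
    RatingsTable,
    Situation,
    aggregate_mean_ratings,
    iter_pairs,
)
from .efa import EfaConfig, FactorCountVote, FactorSolution, item_exclusion_loop
from .factor_scores import ScoreMatrix, score_correlation_matrix, tenberge_factor_scores
from .fuzzy_sets import FactorMapping, FuzzySet, build_fuzzy_sets, permutation_salience_threshold
from .reliability import screen_items_by_reliability
from .structure_compare import ComparisonReport, compare_solution_pair


@dataclass(frozen=True)
class PipelineConfig:
    icc_threshold: float = 0.40
    msa_threshold: float = 0.50
    communality_low: float = 0.40
    communality_high: float = 0.99
    residual_check: float = 0.10
    fuzzy_salience: float = 0.40
    n_perm: int = 1000
    percentile: float = 95.0
    seed: int = 0
    k_override: dict | None = None      # group id -> frozen k
    k_max: int = 8
    pa_iter: int = 20

    def __post_init__(self):
        for name in ("icc_threshold", "msa_threshold", "communality_low",
                     "communality_high", "residual_check", "fuzzy_salience"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def efa_config(self, group: str) -> EfaConfig:
        freeze = (self.k_override or {}).get(group)
        return EfaConfig(
            msa_threshold=self.msa_threshold,
            communality_low=self.communality_low,
            communality_high=self.communality_high,
            residual_check=self.residual_check,
            k_max=self.k_max,
            freeze_k=freeze,
            pa_iter=self.pa_iter,
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class BranchResult:
    solution: FactorSolution
    exclusions: ExclusionLog
    vote: FactorCountVote
    icc_summary: dict
    mean_matrix: MeanRatingsMatrix


@dataclass
class PipelineBundle:
    config: PipelineConfig
    branches: dict[tuple[str, str], BranchResult] = field(default_factory=dict)
    comparisons: dict[tuple[str, str, str], ComparisonReport] = field(default_factory=dict)
    fuzzy: dict[tuple[str, str], FuzzySet] = field(default_factory=dict)
    salience_thresholds: dict[str, float] = field(default_factory=dict)
    scores: dict[tuple[str, str], ScoreMatrix] = field(default_factory=dict)
    score_correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def note(self, stage: str, message: str, **extra) -> None:
        self.log.append({"stage": stage, "message": message, **extra})


def run_full_pipeline(
    ratings: dict[tuple[str, str], RatingsTable],
    config: PipelineConfig = PipelineConfig(),
    fuzzy_mappings: dict[str, list[FactorMapping]] | None = None,
) -> PipelineBundle:
    """Run every stage for every (group, situation) branch.

    ``ratings`` is keyed by (group id, situation value). Deterministic for a
    fixed seed: per-branch RNG streams are spawned from the configured seed.
    """
    if not ratings:
        raise ValueError("need at least one ratings table")
    bundle = PipelineBundle(config=config)
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(ratings) + 1)
    for stream, (key, table) in zip(streams, sorted(ratings.items())):
        group, situation = key
        try:
            retained, icc_log, icc_results, icc_summary = screen_items_by_reliability(
                table, threshold=config.icc_threshold
            )
            kept = table.records[table.records["item"].isin(retained)]
            screened = RatingsTable(table.site_id, table.situation, kept.reset_index(drop=True))
            mean = aggregate_mean_ratings(screened)
            solution, efa_log, vote = item_exclusion_loop(
                mean, config.efa_config(group), seed=np.random.default_rng(stream)
            )
            icc_log.extend(efa_log)
            bundle.branches[key] = BranchResult(
                solution=solution,
                exclusions=icc_log,
                vote=vote,
                icc_summary=icc_summary,
                mean_matrix=mean,
            )
            bundle.note(
                "efa", f"{group}/{situation}: k={solution.k}, "
                f"{len(solution.items)} items retained", group=group
            )
        except Exception as err:  # noqa: BLE001 - branch isolation is the contract
            bundle.note("branch-error", f"{group}/{situation}: {err}", group=group)

    # pairwise structural comparisons within each situation
    for situation in sorted({s for _, s in bundle.branches}):
        groups = sorted(g for g, s in bundle.branches if s == situation)
        if len(groups) < 2:
            bundle.note("compare", f"{situation}: fewer than two groups, comparisons skipped")
            continue
        for ga, gb in iter_pairs(groups):
            a = bundle.branches[(ga, situation)].solution.loadings
            b = bundle.branches[(gb, situation)].solution.loadings
            bundle.comparisons[(situation, ga, gb)] = compare_solution_pair(
                a, b, pair=(ga, gb)
            )

    # fuzzy sets per situation family when a mapping is supplied
    if fuzzy_mappings:
        families = {}
        for situation in sorted({s for _, s in bundle.branches}):
            families[situation] = {
                g: bundle.branches[(g, situation)].solution.loadings
                for g, s in bundle.branches
                if s == situation
            }
        bundle.salience_thresholds = permutation_salience_threshold(
            families,
            n_perm=config.n_perm,
            percentile=config.percentile,
            seed=np.random.default_rng(streams[-1]),
        )
        for situation, mappings in fuzzy_mappings.items():
            if situation not in families:
                continue
            sets = build_fuzzy_sets(
                families[situation], mappings, salience_threshold=config.fuzzy_salience
            )
            for name, fs in sets.items():
                bundle.fuzzy[(situation, name)] = fs
    elif bundle.branches:
        bundle.note("fuzzy", "no set mapping supplied; fuzzy stage skipped")

    # ten Berge scores and cross-situation correlations per group
    for (group, situation), branch in bundle.branches.items():
        try:
            bundle.scores[(group, situation)] = tenberge_factor_scores(
                branch.mean_matrix, branch.solution
            )
        except Exception as err:  # noqa: BLE001
            bundle.note("scores-error", f"{group}/{situation}: {err}", group=group)
    for group in sorted({g for g, _ in bundle.scores}):
        kg = (group, Situation.GENERAL.value)
        kh = (group, Situation.HUMAN.value)
        if kg in bundle.scores and kh in bundle.scores:
            r, p, stars = score_correlation_matrix(bundle.scores[kg], bundle.scores[kh])
            annotated = r.round(2).astype(str) + stars
            bundle.score_correlations[group] = annotated
            bundle.score_correlations[f"{group}__r"] = r
            bundle.score_correlations[f"{group}__p"] = p
    return bundle


def write_report(bundle: PipelineBundle, out_dir: str | Path) -> list[Path]:
    """Serialize every artifact with provenance (config hash, seed, version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(path: Path):
        written.append(path)
        return path

    for (group, situation), branch in bundle.branches.items():
        stem = f"{situation}_{group}"
        branch.solution.to_csv(save(out / f"solution_{stem}.csv"))
        branch.exclusions.to_csv(save(out / f"exclusions_{stem}.csv"))
        sidecar = {
            "k": branch.solution.k,
            "phi": branch.solution.phi.to_numpy().tolist(),
            "vote": {
                "k_parallel": branch.vote.k_parallel,
                "k_ebic": branch.vote.k_ebic,
                "k_vss": branch.vote.k_vss,
                "k_chosen": branch.vote.k_chosen,
            },
            "fit": {
                "rmsr": branch.solution.rmsr,
                "rmsr_df_corrected": branch.solution.rmsr_df_corrected,
                "root_sum_sq_resid": branch.solution.root_sum_sq_resid,
                "alpha": branch.solution.alpha,
                "omega_total": branch.solution.omega_total,
                "cumulative_variance": branch.solution.cumulative_variance,
                "variance_proportions": branch.solution.variance_proportions.tolist(),
            },
            "icc_summary": branch.icc_summary,
            "warnings": branch.solution.warnings_,
        }
        save(out / f"solution_{stem}.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True, allow_nan=True)
        )
    for (situation, ga, gb), report in bundle.comparisons.items():
        report.to_frame().to_csv(save(out / f"compare_{situation}_{ga}_vs_{gb}.csv"))
    if bundle.fuzzy:
        for (situation, name), fs in bundle.fuzzy.items():
            safe = name.replace("/", "-")
            fs.table().to_csv(save(out / f"fuzzy_{situation}_{safe}.csv"), index_label="item")
    else:
        bundle.note("report", "fuzzy report omitted: no fuzzy sets in bundle")
    for (group, situation), sm in bundle.scores.items():
        sm.scores.to_csv(save(out / f"scores_{situation}_{group}.csv"), index_label="subject")
    for group, frame in bundle.score_correlations.items():
        if "__" in group:
            continue
        frame.to_csv(save(out / f"score_correlations_{group}.csv"))
    provenance = {
        "config": asdict(bundle.config),
        "config_hash": bundle.config.digest(),
        "seed": bundle.config.seed,
        "version": __version__,
        "salience_thresholds": bundle.salience_thresholds,
    }
    save(out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    with save(out / "pipeline_log.jsonl").open("w") as fh:
        for entry in bundle.log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return written
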