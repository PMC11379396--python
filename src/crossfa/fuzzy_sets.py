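"""Fuzzy-set intersections of factor loadings across groups.

Factors judged to represent the same construct in several groups are mapped
into a named set (with optional reverse scoring so all groups point the same
way). The intersection value of an item is the minimum absolute loading over
the groups whose final model retained the item, carrying the aligned sign —
a conservative estimate of how strongly the item belongs to the construct
everywhere. Items reliable in only some groups use that known information.
Salience is judged against a permutation null: random factors are drawn per
group, their per-item minima pooled, and the 95th percentile of absolute
values taken as the data-driven threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FactorMapping:
    """One named cross-group set: group id -> (factor name, reversed)."""

    set_name: str
    assignment: dict[str, tuple[str, bool]]

    def groups(self) -> list[str]:
        return list(self.assignment)


@dataclass
class FuzzySet:
    set_name: str
    values: pd.Series                   # signed intersection per item
    provenance: dict[str, list[str]]    # item -> contributing groups
    sign_conflicts: list[str] = field(default_factory=list)
    salient: pd.Series | None = None

    def table(self) -> pd.DataFrame:
        out = self.values.to_frame("value")
        out["groups"] = [";".join(self.provenance[i]) for i in out.index]
        out["sign_conflict"] = [i in self.sign_conflicts for i in out.index]
        if self.salient is not None:
            out["salient"] = self.salient
        return out


def align_factor_directions(
    loadings: dict[str, pd.DataFrame], mapping: FactorMapping
) -> dict[str, pd.Series]:
    """Per-group loading vectors for one set, reversals applied."""
    aligned: dict[str, pd.Series] = {}
    for group, (factor, reversed_) in mapping.assignment.items():
        if group not in loadings:
            raise KeyError(f"no loading matrix for group {group!r}")
        mat = loadings[group]
        if factor not in mat.columns:
            raise KeyError(f"group {group!r} has no factor {factor!r}")
        col = mat[factor].astype(float)
        aligned[group] = -col if reversed_ else col
    return aligned


def fuzzy_intersections(aligned: dict[str, pd.Series], set_name: str = "set") -> FuzzySet:
    """Signed minimum-absolute-loading intersection over contributing groups.

    Ties in |loading| resolve to the first group in mapping order; groups
    disagreeing in sign after alignment are flagged, the value keeping the
    sign of the minimum-|loading| group.
    """
    if not aligned:
        raise ValueError("empty set: no contributing groups")
    items: list[str] = []
    for s in aligned.values():
        items.extend(i for i in s.index if i not in items)
    values: dict[str, float] = {}
    provenance: dict[str, list[str]] = {}
    conflicts: list[str] = []
    for item in items:
        contrib = [(g, s[item]) for g, s in aligned.items() if item in s.index]
        provenance[item] = [g for g, _ in contrib]
        vals = np.array([v for _, v in contrib], dtype=float)
        values[item] = float(vals[np.argmin(np.abs(vals))])
        signs = np.sign(vals[vals != 0])
        if len(set(signs)) > 1:
            conflicts.append(item)
    return FuzzySet(
        set_name=set_name,
        values=pd.Series(values, name=set_name),
        provenance=provenance,
        sign_conflicts=conflicts,
    )


def build_fuzzy_sets(
    loadings: dict[str, pd.DataFrame],
    mappings: list[FactorMapping],
    salience_threshold: float = 0.40,
) -> dict[str, FuzzySet]:
    out: dict[str, FuzzySet] = {}
    for mapping in mappings:
        aligned = align_factor_directions(loadings, mapping)
        fs = fuzzy_intersections(aligned, set_name=mapping.set_name)
        fs.salient = salient_items(fs, salience_threshold)
        out[mapping.set_name] = fs
    return out


def salient_items(fs: FuzzySet, threshold: float = 0.40) -> pd.Series:
    """Inclusive absolute-value salience flag per item."""
    return fs.values.abs() >= threshold


def _pooled_min_scores(
    loadings: dict[str, pd.DataFrame], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation pool for one model family (one random factor per group)."""
    groups = list(loadings)
    mats = {g: loadings[g].to_numpy(float) for g in groups}
    item_index: dict[str, int] = {}
    for g in groups:
        for i in loadings[g].index:
            item_index.setdefault(i, len(item_index))
    n_items = len(item_index)
    # absolute loadings padded with +inf where an item is absent from a group
    abs_l = np.full((len(groups), n_items, max(m.shape[1] for m in mats.values())), np.inf)
    for gi, g in enumerate(groups):
        rows = [item_index[i] for i in loadings[g].index]
        abs_l[gi, rows, : mats[g].shape[1]] = np.abs(mats[g])
    n_factors = np.array([mats[g].shape[1] for g in groups])
    pool = np.empty((n_perm, n_items))
    for t in range(n_perm):
        cols = rng.integers(0, n_factors)
        pool[t] = np.min(abs_l[np.arange(len(groups)), :, cols], axis=0)
    return pool.ravel()


def permutation_salience_threshold(
    families: dict[str, dict[str, pd.DataFrame]],
    n_perm: int = 1000,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """95th-percentile null threshold for fuzzy intersection salience.

    ``families`` maps a family name (e.g. general / human) to that family's
    per-group loading matrices. Each iteration draws one factor per group and
    pools the per-item minimum absolute loadings over the groups retaining the
    item. Per-family thresholds are returned alongside an ``aggregated`` value
    over the union of all families' pooled scores.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pools: dict[str, np.ndarray] = {}
    for fam, loadings in families.items():
        if not loadings or any(m.shape[1] < 1 for m in loadings.values()):
            raise ValueError(f"family {fam!r} needs at least one factor per group")
        pools[fam] = _pooled_min_scores(loadings, n_perm, rng)
    out = {fam: float(np.percentile(np.abs(p), percentile)) for fam, p in pools.items()}
    out["aggregated"] = float(
        np.percentile(np.abs(np.concatenate(list(pools.values()))), percentile)
    )
    return out
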