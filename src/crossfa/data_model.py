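"""Core data structures for multi-rater personality ratings.

A ratings dataset is long-format: one record per (rater, subject, item) with a
numeric score, tied to one site (species group) and one rating situation
(``general`` conspecific behaviour, or behaviour in interactions with humans).
Items are drawn from a fixed survey catalog; the human-situation catalog is the
general catalog minus eight items dropped during rater training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("site", "situation", "rater", "subject", "item", "score")


class Situation(str, Enum):
    GENERAL = "general"
    HUMAN = "human"


class ExclusionStage(str, Enum):
    """Why an item left the analysis; labels mirror the report annotations."""

    LOW_ICC = "Low ICC"
    LOW_MSA = "Low MSA"
    LOW_COMMUNALITY = "Low Communality"
    HIGH_COMMUNALITY = "High Communality"


def _canon(name: str) -> str:
    """Canonical item key: trimmed, case-folded."""
    return " ".join(str(name).strip().split()).casefold()


class FormatError(ValueError):
    """Input file does not have the expected layout."""


class ValidationError(ValueError):
    """Input parses but violates a catalog or uniqueness constraint."""


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered survey item list for one rating situation."""

    situation: Situation
    items: tuple[str, ...]
    excluded_from_human: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        keys = [_canon(i) for i in self.items]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate item names in catalog")

    def __contains__(self, item: str) -> bool:
        return _canon(item) in {_canon(i) for i in self.items}

    def __len__(self) -> int:
        return len(self.items)

    def resolve(self, item: str) -> str:
        """Map an arbitrarily-cased name to its canonical catalog spelling."""
        lookup = {_canon(i): i for i in self.items}
        try:
            return lookup[_canon(item)]
        except KeyError:
            raise ValidationError(f"item not in {self.situation.value} catalog: {item!r}")


def load_catalogs() -> dict[Situation, ItemCatalog]:
    """The packaged survey catalogs: 51 general items, 43 human-situation items."""
    raw = json.loads(
        resources.files("crossfa.data").joinpath("catalogs.json").read_text("utf-8")
    )
    general_items = tuple(raw["general_items"])
    excluded = frozenset(raw["excluded_from_human"])
    human_items = tuple(i for i in general_items if i not in excluded)
    return {
        Situation.GENERAL: ItemCatalog(Situation.GENERAL, general_items, excluded),
        Situation.HUMAN: ItemCatalog(Situation.HUMAN, human_items, excluded),
    }


@dataclass
class ExclusionLog:
    """Bookkeeping of every item dropped on the way to a final solution."""

    entries: list[tuple[str, ExclusionStage, float, float]] = field(default_factory=list)

    def add(self, item: str, stage: ExclusionStage, value: float, threshold: float) -> None:
        self.entries.append((item, stage, float(value), float(threshold)))

    @property
    def items(self) -> list[str]:
        return [e[0] for e in self.entries]

    def extend(self, other: "ExclusionLog") -> None:
        self.entries.extend(other.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["item", "stage", "statistic", "threshold"]
        ).assign(stage=lambda d: [s.value for s in d["stage"]])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RatingsTable:
    """Long-format ratings for one site and one situation.

    ``records`` has columns rater, subject, item, score with at most one row
    per (rater, subject, item).
    """

    site_id: str
    situation: Situation
    records: pd.DataFrame
    subject_metadata: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = self.records.duplicated(["rater", "subject", "item"])
        if dup.any():
            offender = self.records.loc[dup.idxmax(), ["rater", "subject", "item"]]
            raise ValidationError(f"duplicate record for {tuple(offender)}")

    @property
    def raters(self) -> list[str]:
        return sorted(self.records["rater"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.records["subject"].unique())

    @property
    def items(self) -> list[str]:
        return list(pd.unique(self.records["item"]))

    def item_matrix(self, item: str) -> pd.DataFrame:
        """Subjects x raters score matrix for one item (NaN where unrated)."""
        sub = self.records[self.records["item"] == item]
        return sub.pivot(index="subject", columns="rater", values="score")

    def write_csv(self, path: str | Path) -> None:
        out = self.records.copy()
        out.insert(0, "situation", self.situation.value)
        out.insert(0, "site", self.site_id)
        out.to_csv(path, index=False)


@dataclass
class MeanRatingsMatrix:
    """Subject x item matrix of rater-averaged scores."""

    values: pd.DataFrame            # subjects x items, NaN = no rater covered the cell
    n_raters_per_cell: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def items(self) -> list[str]:
        return list(self.values.columns)

    def missing_cells(self) -> list[tuple[str, str]]:
        mask = self.values.isna()
        rows, cols = np.nonzero(mask.to_numpy())
        return [(self.values.index[r], self.values.columns[c]) for r, c in zip(rows, cols)]


def load_ratings(path: str | Path, catalog: ItemCatalog) -> RatingsTable:
    """Read and validate a long-format ratings CSV against a catalog."""
    df = pd.read_csv(path, dtype={"site": str, "rater": str, "subject": str, "item": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if not np.issubdtype(df["score"].dtype, np.number):
        bad = df.loc[pd.to_numeric(df["score"], errors="coerce").isna(), "score"]
        raise ValidationError(f"non-numeric score value(s): {bad.unique()[:5].tolist()}")
    known = {_canon(i): i for i in catalog.items}
    unknown = sorted({i for i in df["item"].unique() if _canon(i) not in known})
    if unknown:
        raise ValidationError(
            f"item(s) not in {catalog.situation.value} catalog: {', '.join(unknown)}"
        )
    df["item"] = [known[_canon(i)] for i in df["item"]]
    sites = df["site"].unique()
    if len(sites) != 1:
        raise ValidationError(f"expected a single site per file, got {sites.tolist()}")
    situations = df["situation"].unique()
    if len(situations) != 1 or situations[0] != catalog.situation.value:
        raise ValidationError(
            f"situation column {situations.tolist()} does not match catalog "
            f"{catalog.situation.value!r}"
        )
    return RatingsTable(
        site_id=sites[0],
        situation=catalog.situation,
        records=df[["rater", "subject", "item", "score"]].reset_index(drop=True),
    )


def aggregate_mean_ratings(ratings: RatingsTable) -> MeanRatingsMatrix:
    """Average each subject's scores over the raters who rated it.

    Missing (rater, subject, item) cells are simply left out of the mean; a
    cell no rater covered is NaN and reported via ``missing_cells``.
    """
    g = ratings.records.groupby(["subject", "item"])["score"]
    means = g.mean().unstack("item")
    counts = g.size().unstack("item").fillna(0).astype(int)
    # preserve first-appearance item order rather than alphabetical
    order = [i for i in ratings.items if i in means.columns]
    return MeanRatingsMatrix(values=means[order], n_raters_per_cell=counts[order])


def item_cross_situation_correlation(
    general: MeanRatingsMatrix, human: MeanRatingsMatrix
) -> pd.DataFrame:
    """Per-item Pearson correlation of rater-averaged scores across situations.

    Returns a frame indexed by shared item with columns r and n_subjects; items
    with zero variance on either side get NaN. Subjects missing in either
    situation are dropped pairwise per item.
    """
    shared_items = [i for i in general.items if i in set(human.items)]
    shared_subj = general.values.index.intersection(human.values.index)
    if len(shared_subj) < 3:
        raise ValidationError("need at least 3 shared subjects")
    rows = {}
    for item in shared_items:
        x = general.values.loc[shared_subj, item]
        y = human.values.loc[shared_subj, item]
        ok = x.notna() & y.notna()
        x, y = x[ok], y[ok]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            rows[item] = (np.nan, len(x))
        else:
            rows[item] = (float(np.corrcoef(x, y)[0, 1]), len(x))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "n_subjects"])
    out.index.name = "item"
    return out


def summarize_cross_situation(corr: pd.DataFrame) -> tuple[float, float]:
    """Mean and sd of the defined per-item cross-situation correlations."""
    r = corr["r"].dropna()
    return float(r.mean()), float(r.std(ddof=1))


def iter_pairs(ids: Iterable[str]):
    ids = list(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            yield ids[i], ids[j]
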