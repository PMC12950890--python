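"""Likert-rating summaries and the Delphi consensus rule.

Expert panels rate each candidate item on an integer Likert scale (the
default study design: 19 raters, items on 1-10 where 1 = strongly disagree
and 10 = strongly agree).  Per item we report the median and quartiles
(P25-P75, the conventional non-parametric summary for ordinal ratings) and
the percentage of raters at or above an agreement cutoff.  Consensus is
declared when that proportion reaches a threshold — by default at least 80%
of respondents rating the item 7 or higher.

Quantiles use linear interpolation between closest order statistics
(position ``1 + q*(n-1)``, numpy's default): with 19 raters this places the
quartiles at positions 5.5 and 14.5, producing the half-point values (6.5,
8.5) typical of published Delphi summaries.  The consensus proportion is
compared as an exact rational, never on the rounded percentage, so a panel
sitting exactly on the threshold (4 of 5) counts as consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import ConfigError, RatingError

__all__ = [
    "RatingScale",
    "RatingMatrix",
    "ItemSummary",
    "ConsensusRule",
    "summarize_item",
    "summarize_matrix",
    "is_consensus",
    "read_ratings_csv",
]


@dataclass(frozen=True)
class RatingScale:
    """Integer rating scale ``[lowest, highest]``; width ``c`` categories."""

    lowest: int
    highest: int

    def __post_init__(self) -> None:
        if self.highest <= self.lowest:
            raise ConfigError(
                f"scale highest ({self.highest}) must exceed lowest "
                f"({self.lowest})"
            )

    @property
    def width(self) -> int:
        return self.highest - self.lowest + 1

    def contains(self, rating: int) -> bool:
        return self.lowest <= rating <= self.highest

    def validate(self, ratings: Iterable[int], context: str = "") -> None:
        bad = [r for r in ratings if not self.contains(int(r))]
        if bad:
            where = f" ({context})" if context else ""
            raise RatingError(
                f"rating(s) outside scale [{self.lowest}, {self.highest}]"
                f"{where}: {bad[:5]}"
            )


#: The ten-point agreement scale used in the Delphi rounds.
LIKERT_1_10 = RatingScale(1, 10)


@dataclass(frozen=True)
class ConsensusRule:
    """Consensus = at least ``proportion_cutoff`` of respondents rating
    ``>= rating_cutoff``.  The proportion is stored as an exact fraction."""

    rating_cutoff: int = 7
    proportion_cutoff: Fraction = Fraction(4, 5)

    def __post_init__(self) -> None:
        cut = self.proportion_cutoff
        if not isinstance(cut, Fraction):
            # via str() so 0.8 means 8/10, not its binary float expansion
            cut = Fraction(str(cut))
            object.__setattr__(self, "proportion_cutoff", cut)
        if not (0 < cut <= 1):
            raise ConfigError(
                f"proportion_cutoff must lie in (0, 1], got {cut}"
            )


@dataclass(frozen=True)
class ItemSummary:
    """Per-item panel summary: median (P25-P75) and agreement count/percent."""

    item_id: str
    n_respondents: int
    median: float
    p25: float
    p75: float
    n_agree: int
    pct_agree: Decimal  # one decimal, half-up

    @property
    def agree_fraction(self) -> Fraction:
        return Fraction(self.n_agree, self.n_respondents)

    @property
    def iqr_width(self) -> float:
        return self.p75 - self.p25


@dataclass(frozen=True)
class RatingMatrix:
    """All ratings of one Delphi round: (item, rater) -> integer rating."""

    round_id: int
    scale: RatingScale
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"item_id", "rater_id", "rating"}
        if not required.issubset(self.frame.columns):
            raise ConfigError(
                "rating frame needs columns item_id, rater_id, rating"
            )
        if self.frame.duplicated(["item_id", "rater_id"]).any():
            dupes = self.frame[
                self.frame.duplicated(["item_id", "rater_id"], keep=False)
            ]
            pairs = sorted(
                set(zip(dupes["item_id"], dupes["rater_id"]))
            )[:5]
            raise ConfigError(f"duplicate (item, rater) rating(s): {pairs}")
        for item_id, group in self.frame.groupby("item_id"):
            self.scale.validate(
                group["rating"], context=f"item {item_id!r}"
            )

    @property
    def items(self) -> list[str]:
        return sorted(self.frame["item_id"].unique())

    @property
    def raters(self) -> list[str]:
        return sorted(self.frame["rater_id"].astype(str).unique())

    def ratings_for(self, item_id: str) -> np.ndarray:
        sel = self.frame.loc[self.frame["item_id"] == item_id, "rating"]
        return sel.to_numpy(dtype=int)


def summarize_item(
    ratings: Sequence[int] | np.ndarray,
    scale: RatingScale,
    rule: ConsensusRule | None = None,
    item_id: str = "",
) -> ItemSummary:
    """Median, quartiles and agreement percentage for one item's ratings.

    Raises :class:`~delphiscore.errors.RatingError` on an empty vector or a
    rating outside the scale.  The percentage is rounded half-up to one
    decimal (16 of 19 -> 84.2); the exact count is kept alongside so the
    consensus rule never operates on the rounded figure.
    """
    rule = rule or ConsensusRule()
    arr = np.asarray(list(ratings), dtype=float)
    if arr.size == 0:
        raise RatingError(f"no ratings for item {item_id!r}")
    scale.validate(arr.astype(int), context=f"item {item_id!r}")
    if not scale.contains(rule.rating_cutoff):
        raise ConfigError(
            f"rating_cutoff {rule.rating_cutoff} outside scale "
            f"[{scale.lowest}, {scale.highest}]"
        )
    p25, med, p75 = np.percentile(arr, [25, 50, 75])  # type-7 linear
    n = int(arr.size)
    n_agree = int((arr >= rule.rating_cutoff).sum())
    pct = round_half_up(Fraction(100 * n_agree, n), 1)
    return ItemSummary(
        item_id=item_id,
        n_respondents=n,
        median=float(med),
        p25=float(p25),
        p75=float(p75),
        n_agree=n_agree,
        pct_agree=pct,
    )


def is_consensus(summary: ItemSummary, rule: ConsensusRule | None = None) -> bool:
    """True iff the exact agreement fraction reaches the proportion cutoff."""
    rule = rule or ConsensusRule()
    return summary.agree_fraction >= rule.proportion_cutoff


def summarize_matrix(
    matrix: RatingMatrix, rule: ConsensusRule | None = None
) -> dict[str, ItemSummary]:
    """Summarize every item of a round, keyed by item id."""
    rule = rule or ConsensusRule()
    return {
        item: summarize_item(
            matrix.ratings_for(item), matrix.scale, rule, item_id=item
        )
        for item in matrix.items
    }


def read_ratings_csv(
    source: str | Path, scale: RatingScale = LIKERT_1_10
) -> dict[int, RatingMatrix]:
    """Read long-format ratings (round, item_id, rater_id, rating) into one
    :class:`RatingMatrix` per round, keyed by round number."""
    frame = pd.read_csv(source)
    required = {"round", "item_id", "rater_id", "rating"}
    if not required.issubset(frame.columns):
        raise ConfigError(
            "ratings CSV needs columns round, item_id, rater_id, rating; got "
            + ", ".join(frame.columns)
        )
    frame["rating"] = frame["rating"].astype(int)
    out: dict[int, RatingMatrix] = {}
    for round_id, group in frame.groupby("round", sort=True):
        out[int(round_id)] = RatingMatrix(
            round_id=int(round_id),
            scale=scale,
            frame=group[["item_id", "rater_id", "rating"]].reset_index(
                drop=True
            ),
        )
    return out


def summaries_frame(summaries: dict[str, ItemSummary]) -> pd.DataFrame:
    """Tabulate summaries as a DataFrame (one row per item)."""
    rows = [
        {
            "item_id": s.item_id,
            "n_respondents": s.n_respondents,
            "median": s.median,
            "p25": s.p25,
            "p75": s.p75,
            "n_agree": s.n_agree,
            "pct_agree": float(s.pct_agree),
        }
        for s in summaries.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "item_id",
            "n_respondents",
            "median",
            "p25",
            "p75",
            "n_agree",
            "pct_agree",
        ],
    )
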