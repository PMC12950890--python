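"""Multi-round Delphi orchestration: carryover, exclusion and feedback.

The engine runs anonymised expert panels through successive rating rounds.
Each round every open item is summarised (median, P25-P75, % agreement);
items meeting the consensus rule are settled and are not re-rated in later
rounds, the rest carry over.  After the configured maximum number of rounds
(default four), items that still lack consensus and whose summaries have
stagnated — agreement moved less than a configurable number of percentage
points and the median is unchanged since the previous round — are marked for
exclusion from the instrument.

Two carryover policies are provided.  ``failed_consensus`` (default)
carries over exactly the items that failed the rule.  ``low_agreement``
additionally re-presents items whose interquartile range is wide (dispersion
>= a configurable width) even when the percentage rule passed — for panels
that prefer to keep debating items with scattered ratings.

Reports aggregate only: medians, quartiles and counts.  Individual ratings
are never listed, preserving respondent anonymity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from ._util import fmt_decimal, round_half_up
from .consensus import (
    ConsensusRule,
    ItemSummary,
    RatingMatrix,
    is_consensus,
    summaries_frame,
    summarize_item,
)
from .errors import ConfigError

__all__ = [
    "DelphiConfig",
    "RoundResult",
    "PanelRoster",
    "run_round",
    "run_delphi",
    "feedback_report",
    "report_frame",
    "roster_summary",
    "read_roster_csv",
]

CarryoverPolicy = Literal["failed_consensus", "low_agreement"]


@dataclass(frozen=True)
class DelphiConfig:
    """Tunable parameters of the round engine.

    ``stagnation_delta`` is in percentage points; an item is "stagnant" when
    its agreement moved less than this between consecutive rounds and its
    median is unchanged.  ``low_agreement_iqr_width`` only matters under the
    ``low_agreement`` carryover policy.
    """

    max_rounds: int = 4
    rule: ConsensusRule = field(default_factory=ConsensusRule)
    carryover_policy: CarryoverPolicy = "failed_consensus"
    low_agreement_iqr_width: float = 3.0
    stagnation_delta: float = 5.0

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ConfigError("max_rounds must be >= 1")
        if self.carryover_policy not in ("failed_consensus", "low_agreement"):
            raise ConfigError(
                f"unknown carryover_policy {self.carryover_policy!r}"
            )
        if self.stagnation_delta <= 0 or self.low_agreement_iqr_width <= 0:
            raise ConfigError("thresholds must be positive")


@dataclass(frozen=True)
class RoundResult:
    """Outcome of one round: summaries plus the three disjoint item sets."""

    round_id: int
    summaries: Mapping[str, ItemSummary]
    consensus_items: frozenset[str]
    carryover_items: frozenset[str]
    excluded_items: frozenset[str]


@dataclass(frozen=True)
class PanelRoster:
    """Pseudonymous description of one panellist."""

    rater_id: str
    profession: str
    training: str = ""
    experience_band: str = ""


def _prior_consensus(history: Sequence[RoundResult]) -> frozenset[str]:
    out: set[str] = set()
    for r in history:
        out |= r.consensus_items
    return frozenset(out)


def run_round(
    matrix: RatingMatrix,
    config: DelphiConfig | None = None,
    history: Sequence[RoundResult] = (),
    roster: Iterable[PanelRoster] | None = None,
) -> RoundResult:
    """Analyse one round of ratings against the consensus rule.

    Items already settled in a prior round are skipped with a warning (they
    should not have been re-rated).  When ``roster`` is given, raters in the
    matrix but absent from the roster trigger a warning.  On the final round
    (``matrix.round_id == config.max_rounds``) stagnant non-consensus items
    are marked excluded rather than carried over.
    """
    config = config or DelphiConfig()
    settled = _prior_consensus(history)

    if roster is not None:
        known = {r.rater_id for r in roster}
        stray = sorted(set(matrix.raters) - known)
        if stray:
            warnings.warn(
                f"rater(s) not in roster: {', '.join(stray)}", stacklevel=2
            )

    items = []
    for item in matrix.items:
        if item in settled:
            warnings.warn(
                f"item {item!r} already reached consensus in an earlier "
                "round; its new ratings are ignored",
                stacklevel=2,
            )
        else:
            items.append(item)

    summaries: dict[str, ItemSummary] = {}
    consensus: set[str] = set()
    carryover: set[str] = set()
    excluded: set[str] = set()

    prev = history[-1] if history else None
    final_round = matrix.round_id >= config.max_rounds

    for item in items:
        summary = summarize_item(
            matrix.ratings_for(item), matrix.scale, config.rule, item_id=item
        )
        summaries[item] = summary
        passed = is_consensus(summary, config.rule)
        if passed and config.carryover_policy == "low_agreement":
            if summary.iqr_width >= config.low_agreement_iqr_width:
                passed = False  # wide dispersion: keep debating
        if passed:
            consensus.add(item)
            continue
        if final_round and prev is not None and item in prev.summaries:
            before = prev.summaries[item]
            delta = abs(float(summary.pct_agree) - float(before.pct_agree))
            if delta < config.stagnation_delta and summary.median == before.median:
                excluded.add(item)
                continue
        carryover.add(item)

    return RoundResult(
        round_id=matrix.round_id,
        summaries=summaries,
        consensus_items=frozenset(consensus),
        carryover_items=frozenset(carryover),
        excluded_items=frozenset(excluded),
    )


def run_delphi(
    matrices: Mapping[int, RatingMatrix],
    config: DelphiConfig | None = None,
    roster: Iterable[PanelRoster] | None = None,
) -> list[RoundResult]:
    """Run every round in order, threading results as history."""
    config = config or DelphiConfig()
    history: list[RoundResult] = []
    for round_id in sorted(matrices):
        history.append(
            run_round(matrices[round_id], config, tuple(history), roster)
        )
    return history


def _fmt(x: float) -> str:
    return fmt_decimal(x)


def report_frame(result: RoundResult) -> pd.DataFrame:
    """Tabular form of a round result (feeds both CSV and markdown output)."""
    frame = summaries_frame(dict(result.summaries))
    status = []
    for item in frame["item_id"]:
        if item in result.consensus_items:
            status.append("consensus")
        elif item in result.excluded_items:
            status.append("excluded")
        else:
            status.append("carryover")
    frame["status"] = status
    return frame


def feedback_report(
    result: RoundResult, labels: Mapping[str, str] | None = None
) -> str:
    """Markdown feedback shared with the panel after a round.

    One row per item: ``median (P25-P75)``, ``n_agree (pct%)`` and the
    consensus status — the aggregate-only summary convention of Delphi
    studies (no individual ratings).
    """
    labels = labels or {}
    lines = [
        f"## Delphi round {result.round_id}",
        "",
        "| Item | Median (P25–P75) | Agreement | Status |",
        "| --- | --- | --- | --- |",
    ]
    for item in sorted(result.summaries):
        s = result.summaries[item]
        if item in result.consensus_items:
            status = "consensus"
        elif item in result.excluded_items:
            status = "excluded"
        else:
            status = "carryover"
        med = f"{_fmt(s.median)} ({_fmt(s.p25)}–{_fmt(s.p75)})"
        agree = f"{s.n_agree} ({fmt_decimal(s.pct_agree)}%)"
        lines.append(
            f"| {labels.get(item, item)} | {med} | {agree} | {status} |"
        )
    lines.append("")
    return "\n".join(lines)


_ROSTER_FIELDS = ("profession", "training", "experience_band")


def roster_summary(roster: Iterable[PanelRoster]) -> pd.DataFrame:
    """Frequency table of panel characteristics.

    Counts and one-decimal percentages (half-up) per level of profession,
    training and experience band; empty levels are omitted, an empty roster
    yields an empty table.
    """
    members = list(roster)
    ids = [m.rater_id for m in members]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate rater ids in roster")
    rows = []
    n = len(members)
    for field_name in _ROSTER_FIELDS:
        values = [getattr(m, field_name) for m in members]
        values = [v for v in values if v]
        for level in sorted(set(values)):
            count = values.count(level)
            pct = round_half_up(Fraction(100 * count, n), 1)
            rows.append(
                {
                    "field": field_name,
                    "level": level,
                    "count": count,
                    "pct": float(pct),
                }
            )
    return pd.DataFrame(rows, columns=["field", "level", "count", "pct"])


def read_roster_csv(source: str | Path) -> list[PanelRoster]:
    """Read a roster CSV (rater_id, profession[, training, experience_band])."""
    frame = pd.read_csv(source, dtype=str).fillna("")
    if "rater_id" not in frame.columns:
        raise ConfigError("roster CSV needs a rater_id column")
    return [
        PanelRoster(
            rater_id=row["rater_id"],
            profession=row.get("profession", ""),
            training=row.get("training", ""),
            experience_band=row.get("experience_band", ""),
        )
        for _, row in frame.iterrows()
    ]
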