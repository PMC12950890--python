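"""Synthetic expert-panel rating generator.

Each rater-item rating is drawn independently from a two-component mixture:
with probability ``theta`` (the item's agreement level) from an *endorse*
distribution concentrated at or above the consensus rating cutoff, otherwise
from a *dissent* distribution over the whole scale.  Defaults emulate the
study design this package was built around: 19 raters, seven candidate
items, a 1-10 Likert scale, endorse uniform on {7..10}, dissent uniform on
{1..10}.

The mixture was chosen for analytic tractability: the probability that a
single rating clears the cutoff is available in closed form
(:func:`endorsement_probability`), which turns stochastic pipeline tests
into exact binomial calculations.  Rater-level random effects (consistently
generous or harsh judges) are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import LIKERT_1_10, RatingMatrix, RatingScale
from .errors import ConfigError

__all__ = [
    "PanelModel",
    "DEFAULT_ITEMS",
    "simulate_panel",
    "endorsement_probability",
]

#: The seven candidate categories of the bundled nursing score.
DEFAULT_ITEMS = (
    "parenteral_access",
    "tubes",
    "simple_wound_care",
    "complex_wound_care",
    "hygiene",
    "delirium",
    "social_family_issues",
)


def _uniform_dist(lo: int, hi: int) -> dict[int, float]:
    width = hi - lo + 1
    return {r: 1.0 / width for r in range(lo, hi + 1)}


def _check_dist(dist: Mapping[int, float], scale: RatingScale, name: str) -> None:
    if not dist:
        raise ConfigError(f"{name} distribution is empty")
    for r, p in dist.items():
        if not scale.contains(int(r)):
            raise ConfigError(f"{name} distribution has out-of-scale value {r}")
        if p < 0:
            raise ConfigError(f"{name} distribution has negative mass at {r}")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} distribution sums to {total}, not 1")


@dataclass(frozen=True)
class PanelModel:
    """Generative model of one panel round.

    ``agreement`` is either a single probability applied to every item or a
    mapping item -> probability.  ``endorse_dist``/``dissent_dist`` map
    rating -> probability; ``None`` selects the uniform defaults (endorse
    uniform on {rating_cutoff..highest}, dissent uniform on the full scale).
    """

    n_raters: int = 19
    items: Sequence[str] = DEFAULT_ITEMS
    scale: RatingScale = LIKERT_1_10
    agreement: float | Mapping[str, float] = 0.85
    rating_cutoff: int = 7
    endorse_dist: Mapping[int, float] | None = None
    dissent_dist: Mapping[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ConfigError("n_raters must be >= 1")
        if not self.scale.contains(self.rating_cutoff):
            raise ConfigError("rating_cutoff outside scale")
        for item, theta in self._theta_map().items():
            if not 0.0 <= theta <= 1.0:
                raise ConfigError(
                    f"agreement for {item!r} must lie in [0, 1], got {theta}"
                )
        _check_dist(self._endorse(), self.scale, "endorse")
        _check_dist(self._dissent(), self.scale, "dissent")

    def _theta_map(self) -> dict[str, float]:
        if isinstance(self.agreement, Mapping):
            missing = set(self.items) - set(self.agreement)
            if missing:
                raise ConfigError(
                    f"agreement mapping missing item(s): {sorted(missing)}"
                )
            return {i: float(self.agreement[i]) for i in self.items}
        return {i: float(self.agreement) for i in self.items}

    def _endorse(self) -> Mapping[int, float]:
        if self.endorse_dist is not None:
            return self.endorse_dist
        return _uniform_dist(self.rating_cutoff, self.scale.highest)

    def _dissent(self) -> Mapping[int, float]:
        if self.dissent_dist is not None:
            return self.dissent_dist
        return _uniform_dist(self.scale.lowest, self.scale.highest)


def endorsement_probability(model: PanelModel, item: str | None = None) -> float:
    """Closed-form P(one rating >= rating_cutoff) under the mixture.

    theta * P(endorse >= cutoff) + (1 - theta) * P(dissent >= cutoff); with
    the default distributions on a 1-10 scale and cutoff 7 this is
    ``theta + (1 - theta) * 0.4``.
    """
    thetas = model._theta_map()
    theta = thetas[item] if item is not None else next(iter(thetas.values()))
    if item is None and len(set(thetas.values())) > 1:
        raise ConfigError("heterogeneous agreement: pass an item id")
    p_end = sum(
        p for r, p in model._endorse().items() if r >= model.rating_cutoff
    )
    p_dis = sum(
        p for r, p in model._dissent().items() if r >= model.rating_cutoff
    )
    return theta * p_end + (1.0 - theta) * p_dis


def simulate_panel(
    model: PanelModel,
    round_id: int = 1,
    rng: np.random.Generator | None = None,
) -> RatingMatrix:
    """Draw one full rating matrix from the model.

    Reproducible: the same model (including its seed) always produces the
    same matrix.  Pass an explicit ``rng`` to draw replicate panels from a
    single stream instead.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    thetas = model._theta_map()
    endorse = model._endorse()
    dissent = model._dissent()
    e_vals = np.array(sorted(endorse), dtype=int)
    e_probs = np.array([endorse[v] for v in e_vals], dtype=float)
    d_vals = np.array(sorted(dissent), dtype=int)
    d_probs = np.array([dissent[v] for v in d_vals], dtype=float)

    records = []
    raters = [f"r{k + 1:02d}" for k in range(model.n_raters)]
    for item in model.items:
        theta = thetas[item]
        use_endorse = rng.random(model.n_raters) < theta
        from_e = rng.choice(e_vals, size=model.n_raters, p=e_probs)
        from_d = rng.choice(d_vals, size=model.n_raters, p=d_probs)
        ratings = np.where(use_endorse, from_e, from_d)
        for rater, rating in zip(raters, ratings):
            records.append(
                {"item_id": item, "rater_id": rater, "rating": int(rating)}
            )
    frame = pd.DataFrame(records, columns=["item_id", "rater_id", "rating"])
    return RatingMatrix(round_id=round_id, scale=model.scale, frame=frame)
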