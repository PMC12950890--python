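"""Aiken's V content-validity coefficient with exact significance.

For ``n`` judges rating an item on a ``c``-category scale whose lowest value
is ``l``, Aiken's V is

    V = sum_i (r_i - l) / (n * (c - 1)),

the mean rating rescaled to [0, 1]: V = 1 when every judge uses the scale
maximum, V = 0 at the minimum.  Significance is assessed against the null
hypothesis that each judge rates independently and uniformly across the c
categories: the p-value is the exact right tail P(S >= s) of the sum
S = sum_i (r_i - l) of n iid uniforms on {0, ..., c-1}.

The tail is computed by iterated convolution of the single-rater count
vector using exact integer arithmetic, so it agrees with full enumeration
over all c^n rating vectors at any size; a normal approximation (with
continuity correction) is available separately for very large panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .consensus import RatingMatrix, RatingScale
from .errors import ConfigError, RatingError

__all__ = [
    "AikenResult",
    "aiken_v",
    "aiken_pvalue",
    "aiken_pvalue_normal",
    "aiken_table",
    "format_pvalue",
]


@dataclass(frozen=True)
class AikenResult:
    """Aiken's V for one item plus the ingredients of its exact p-value."""

    item_id: str
    v: float
    v_rounded: Decimal  # two decimals, half-up
    s_sum: int
    n_raters: int
    scale: RatingScale
    p_value: float | None = None


def _uniform_sum_counts(n: int, c: int) -> list[int]:
    """Exact counts of outcomes of S = sum of n iid uniforms on {0..c-1}.

    Returns a list of length n*(c-1)+1 whose entries sum to c**n.  Python
    ints keep the convolution exact at any panel size.
    """
    counts = [1] * c
    for _ in range(n - 1):
        new = [0] * (len(counts) + c - 1)
        for s, k in enumerate(counts):
            if k:
                for d in range(c):
                    new[s + d] += k
        counts = new
    return counts


def aiken_v(
    ratings: Sequence[int] | np.ndarray,
    scale: RatingScale,
    item_id: str = "",
    p_value: bool = True,
) -> AikenResult:
    """Compute Aiken's V (and by default its exact p-value) for one item.

    ``ratings`` are integer scores on ``scale``; the scale must have at
    least two categories.  V is reported both exactly and rounded half-up
    to two decimals, the convention of published validity tables.
    """
    arr = np.asarray(list(ratings), dtype=int)
    if arr.size == 0:
        raise RatingError(f"no ratings for item {item_id!r}")
    if scale.width < 2:
        raise ConfigError("Aiken's V needs a scale of width >= 2")
    scale.validate(arr, context=f"item {item_id!r}")
    n = int(arr.size)
    s_sum = int((arr - scale.lowest).sum())
    v = Fraction(s_sum, n * (scale.width - 1))
    result = AikenResult(
        item_id=item_id,
        v=float(v),
        v_rounded=round_half_up(v, 2),
        s_sum=s_sum,
        n_raters=n,
        scale=scale,
        p_value=aiken_pvalue(s_sum, n, scale) if p_value else None,
    )
    return result


def aiken_pvalue(s_sum: int, n_raters: int, scale: RatingScale) -> float:
    """Exact right-tail P(S >= s_sum) under the uniform-rating null."""
    c = scale.width
    if c < 2 or n_raters < 1:
        raise ConfigError("need n_raters >= 1 and scale width >= 2")
    s_max = n_raters * (c - 1)
    if not 0 <= s_sum <= s_max:
        raise ConfigError(
            f"s_sum {s_sum} outside the support [0, {s_max}]"
        )
    counts = _uniform_sum_counts(n_raters, c)
    tail = sum(counts[s_sum:])
    return float(Fraction(tail, c**n_raters))


def aiken_pvalue_normal(
    s_sum: int, n_raters: int, scale: RatingScale
) -> float:
    """Normal approximation to the right tail, with continuity correction.

    Approximate — intended only for panels large enough that the exact
    convolution is unnecessary; the exact routine is the default everywhere.
    """
    from scipy.stats import norm

    c = scale.width
    mean = n_raters * (c - 1) / 2
    var = n_raters * (c**2 - 1) / 12
    return float(norm.sf((s_sum - 0.5 - mean) / math.sqrt(var)))


def format_pvalue(p: float, floor: float = 0.001) -> str:
    """Render a p-value as ``"<0.001"`` below the floor, numerically above."""
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.3f}"


def aiken_table(matrix: RatingMatrix) -> pd.DataFrame:
    """Per-item validity table (item, V, exact p) for one round's ratings."""
    rows = []
    for item in matrix.items:
        res = aiken_v(matrix.ratings_for(item), matrix.scale, item_id=item)
        rows.append(
            {
                "item_id": item,
                "n_raters": res.n_raters,
                "v_aiken": float(res.v_rounded),
                "p_value": format_pvalue(res.p_value),
                "p_exact": res.p_value,
            }
        )
    return pd.DataFrame(
        rows, columns=["item_id", "n_raters", "v_aiken", "p_value", "p_exact"]
    )
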