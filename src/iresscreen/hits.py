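"""Cut-off based Up/Down calling and gene-level concordance hits.

A reaction (one gene x siRNA) is an Up call when its percent-of-control
score is at or above the upper cut-off (default 250) and a Down call at or
below the lower cut-off (default 80); the cut-offs bracket the
control level of 100.  A gene is a hit when at least two of its siRNAs
agree in direction — the concordance requirement that guards against
single-siRNA off-target effects.  Up hits imply negative regulators of IRES
activity (silencing de-represses the reporter), Down hits positive
regulators.

Cut-offs may also be calibrated from the score distribution to a target
per-reaction hit rate: the widest rank-symmetric quantile pair within the
target rate, rounded outward to a round-number grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, ParameterError

UP = "up"
DOWN = "down"
NONE = "none"

HIT_COLUMNS = ["gene_symbol", "gene_class", "hit", "direction",
               "n_supporting_sirnas", "regulator_sign"]


@dataclass(frozen=True)
class CutoffPair:
    """Up/Down score cut-offs on the percent-of-control scale."""

    up_cutoff: float = 250.0
    down_cutoff: float = 80.0
    target_hit_rate: float = 0.10
    derivation: str = "fixed"

    def __post_init__(self):
        if not self.down_cutoff < 100 < self.up_cutoff:
            raise ParameterError(
                f"cut-offs must bracket the control level "
                f"(down < 100 < up), got ({self.up_cutoff}, {self.down_cutoff})"
            )
        if not 0 < self.target_hit_rate < 1:
            raise ParameterError("target_hit_rate must be in (0, 1)")


@dataclass(frozen=True)
class DirectionCall:
    gene_symbol: str
    sirna_index: int
    direction: str
    score: float


@dataclass(frozen=True)
class GeneHit:
    gene_symbol: str
    gene_class: str
    hit: bool
    direction: str | None
    n_supporting_sirnas: int
    regulator_sign: str | None


def frequency_distribution(
    scores, bin_width: float, origin: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of scores over origin-aligned bins of width ``bin_width``.

    Bins are half-open ``[lo, hi)`` with the last bin closed, so counts sum
    to the number of scores.  Returns ``(edges, counts)``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ParameterError("frequency_distribution needs at least one score")
    if not bin_width > 0:
        raise ParameterError("bin_width must be positive")
    k0 = math.floor((s.min() - origin) / bin_width)
    k1 = math.floor((s.max() - origin) / bin_width) + 1
    edges = origin + bin_width * np.arange(k0, k1 + 1)
    counts, edges = np.histogram(s, bins=edges)
    return edges, counts


def _fraction_beyond(sorted_scores: np.ndarray, down: float, up: float) -> float:
    n = sorted_scores.size
    n_down = int(np.searchsorted(sorted_scores, down, side="right"))
    n_up = n - int(np.searchsorted(sorted_scores, up, side="left"))
    return (n_down + n_up) / n


def calibrate_cutoffs(
    scores, target_hit_rate: float = 0.10, grid: float = 10.0
) -> CutoffPair:
    """Derive Up/Down cut-offs giving at most ``target_hit_rate`` calls.

    Places the Down cut-off at quantile q and the Up cut-off at quantile
    1 - q with q = target_hit_rate / 2 (the widest rank-symmetric pair),
    then rounds each outward to the nearest multiple of ``grid`` (down is
    floored, up is ceiled), widening by further grid steps if boundary ties
    still push the inclusive beyond-fraction over the target.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size == 0:
        raise ParameterError("calibrate_cutoffs needs at least one score")
    if not 0 < target_hit_rate < 1:
        raise ParameterError("target_hit_rate must be in (0, 1)")
    if not grid > 0:
        raise ParameterError("grid must be positive")
    if s[0] == s[-1]:
        raise CalibrationError("all scores are identical; cannot calibrate cut-offs")
    q = target_hit_rate / 2.0
    down = math.floor(float(np.quantile(s, q)) / grid) * grid
    up = math.ceil(float(np.quantile(s, 1.0 - q)) / grid) * grid
    for _ in range(10_000):
        if _fraction_beyond(s, down, up) <= target_hit_rate:
            break
        n_down = int(np.searchsorted(s, down, side="right"))
        n_up = s.size - int(np.searchsorted(s, up, side="left"))
        if n_down >= n_up:
            down -= grid
        else:
            up += grid
    # calibrated pairs must still bracket the control level of 100
    down = min(down, 100.0 - grid)
    up = max(up, 100.0 + grid)
    return CutoffPair(up_cutoff=up, down_cutoff=down,
                      target_hit_rate=target_hit_rate, derivation="calibrated")


def call_direction(score: float, cutoffs: CutoffPair) -> str:
    """Up/Down/none for a single score; cut-off values themselves are calls."""
    if score >= cutoffs.up_cutoff:
        return UP
    if score <= cutoffs.down_cutoff:
        return DOWN
    return NONE


def call_reaction(score, cutoffs: CutoffPair) -> DirectionCall:
    """Direction call for one reaction score (a row of the reactions table
    or any object with gene_symbol/sirna_index/score attributes)."""
    return DirectionCall(
        gene_symbol=score.gene_symbol,
        sirna_index=int(score.sirna_index),
        direction=call_direction(float(score.score), cutoffs),
        score=float(score.score),
    )


def call_reactions(reactions: pd.DataFrame, cutoffs: CutoffPair) -> pd.DataFrame:
    """Vectorized direction calls for the usable rows of a reactions table."""
    usable = reactions[reactions.get("usable", True)].copy() \
        if "usable" in reactions else reactions.copy()
    score = usable["score"].to_numpy(dtype=float)
    direction = np.where(score >= cutoffs.up_cutoff, UP,
                         np.where(score <= cutoffs.down_cutoff, DOWN, NONE))
    usable["direction"] = direction
    return usable[["gene_symbol", "sirna_index", "channel", "score", "direction"]] \
        if "channel" in usable else usable


def call_gene(directions, gene_symbol: str = "", gene_class: str = "other") -> GeneHit:
    """Gene-level concordance call from its per-siRNA directions.

    A hit requires at least two calls sharing the same direction; mixed
    up+down never qualifies.  Up hits map to negative regulators, Down hits
    to positive regulators.
    """
    dirs = [d.direction if isinstance(d, DirectionCall) else d for d in directions]
    if not 1 <= len(dirs) <= 3:
        raise ParameterError("call_gene expects 1-3 direction calls")
    n_up = dirs.count(UP)
    n_down = dirs.count(DOWN)
    if n_up >= 2:
        return GeneHit(gene_symbol, gene_class, True, UP, n_up, "negative")
    if n_down >= 2:
        return GeneHit(gene_symbol, gene_class, True, DOWN, n_down, "positive")
    return GeneHit(gene_symbol, gene_class, False, None, max(n_up, n_down), None)


def call_genes(calls: pd.DataFrame, gene_class: pd.Series | None = None) -> pd.DataFrame:
    """Gene-level hit table from a per-reaction calls table."""
    counts = (calls.groupby("gene_symbol")["direction"]
              .value_counts().unstack(fill_value=0))
    for d in (UP, DOWN):
        if d not in counts:
            counts[d] = 0
    n_up = counts[UP]
    n_down = counts[DOWN]
    hit = (n_up >= 2) | (n_down >= 2)
    direction = np.where(n_up >= 2, UP, np.where(n_down >= 2, DOWN, None))
    n_support = np.where(n_up >= 2, n_up, np.where(n_down >= 2, n_down,
                                                   np.maximum(n_up, n_down)))
    sign = np.where(n_up >= 2, "negative", np.where(n_down >= 2, "positive", None))
    out = pd.DataFrame({
        "gene_symbol": counts.index,
        "gene_class": (gene_class.reindex(counts.index).fillna("other").to_numpy()
                       if gene_class is not None else "other"),
        "hit": hit.to_numpy(),
        "direction": direction,
        "n_supporting_sirnas": n_support.astype(int),
        "regulator_sign": sign,
    }).reset_index(drop=True)
    return out[HIT_COLUMNS]


def summarize_screen(
    calls: pd.DataFrame, hits: pd.DataFrame, gene_class: pd.Series
) -> dict:
    """Screen-level counts: genes affected by >= 1 siRNA beyond a cut-off,
    hits by gene class, and hits by regulator sign."""
    affected_genes = calls.loc[calls["direction"] != NONE, "gene_symbol"].unique()
    cls = gene_class.reindex(affected_genes).fillna("other")
    hit_rows = hits[hits["hit"]]
    summary = {
        "n_genes": int(calls["gene_symbol"].nunique()),
        "n_reactions": int(len(calls)),
        "n_reactions_beyond_cutoffs": int((calls["direction"] != NONE).sum()),
        "per_reaction_hit_rate": float((calls["direction"] != NONE).mean())
        if len(calls) else 0.0,
        "n_genes_affected": int(len(affected_genes)),
        "affected_by_class": {k: int(v) for k, v in cls.value_counts().items()},
        "n_hits": int(len(hit_rows)),
        "hits_by_class": {k: int(v)
                          for k, v in hit_rows["gene_class"].value_counts().items()},
        "hits_by_sign": {k: int(v)
                         for k, v in hit_rows["regulator_sign"].value_counts().items()},
    }
    return summary
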