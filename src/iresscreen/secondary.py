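"""Secondary screen: confirmation, IRES specificity, and viability filtering.

Primary hits are re-assayed in three channels — the IRES-driven reporter,
a cap-driven reporter, and ATP viability.  A hit is *confirmed* when its
IRES-channel score is again beyond the primary cut-offs in the primary
direction; *IRES-specific* when additionally the cap-reporter score is
within a tolerance band around the control level (knockdown does not touch
cap-dependent translation); and *viable* when the ATP score stays above a
viability floor.  The surviving "specific hits" are
confirmed AND ires_specific AND viable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import screen_io as sio
from .errors import EvaluationError
from .hits import DOWN, UP, CutoffPair
from .normalize import aggregate_replicates, normalize_screen

SECONDARY_COLUMNS = ["gene_symbol", "ires_score", "cap_score", "viability_score",
                     "confirmed", "ires_specific", "viable", "specific_hit"]


@dataclass(frozen=True)
class SecondaryResult:
    gene_symbol: str
    ires_score: float
    cap_score: float
    viability_score: float
    confirmed: bool
    ires_specific: bool
    viable: bool

    @property
    def specific_hit(self) -> bool:
        return self.confirmed and self.ires_specific and self.viable


def evaluate_secondary(
    gene_symbol: str,
    primary_direction: str,
    channel_scores: dict[str, float],
    cutoffs: CutoffPair,
    cap_tolerance: float = 0.25,
    viability_floor: float = 0.70,
) -> SecondaryResult:
    """Classify one gene from its three normalized channel scores.

    ``channel_scores`` maps channel name to a percent-of-control score.
    ``cap_tolerance`` is the allowed fractional deviation of the cap score
    from 100 ("no effect" band); ``viability_floor`` the minimum ATP score
    as a fraction of control.
    """
    for ch in sio.CHANNELS:
        if ch not in channel_scores or pd.isna(channel_scores[ch]):
            raise EvaluationError(
                f"gene {gene_symbol}: missing secondary channel {ch!r}"
            )
    ires = float(channel_scores[sio.CHANNEL_IRES])
    cap = float(channel_scores[sio.CHANNEL_CAP])
    atp = float(channel_scores[sio.CHANNEL_ATP])
    if primary_direction == UP:
        confirmed = ires >= cutoffs.up_cutoff
    elif primary_direction == DOWN:
        confirmed = ires <= cutoffs.down_cutoff
    else:
        raise EvaluationError(
            f"gene {gene_symbol}: primary direction must be up or down, "
            f"got {primary_direction!r}"
        )
    ires_specific = confirmed and abs(cap - 100.0) <= cap_tolerance * 100.0
    viable = atp >= viability_floor * 100.0
    return SecondaryResult(gene_symbol, ires, cap, atp, confirmed,
                           ires_specific, viable)


def run_secondary(
    hits: pd.DataFrame,
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    cutoffs: CutoffPair,
    cap_tolerance: float = 0.25,
    viability_floor: float = 0.70,
) -> tuple[pd.DataFrame, dict]:
    """Normalize, aggregate and classify the secondary screen for all hits.

    Returns a per-gene result table and a summary dict with counts of
    tested / confirmed / ires_specific / specific+viable genes plus an
    ``untested`` list of hit genes without secondary measurements.
    """
    hit_rows = hits[hits["hit"]] if "hit" in hits else hits
    normalized = normalize_screen(measurements, layout)
    reactions = aggregate_replicates(normalized, layout, min_replicates=1)
    scores = reactions.pivot_table(index="gene_symbol", columns="channel",
                                   values="score", aggfunc="median")
    results, untested = [], []
    for row in hit_rows.itertuples(index=False):
        g = row.gene_symbol
        if g not in scores.index:
            untested.append(g)
            continue
        chan = scores.loc[g].to_dict()
        res = evaluate_secondary(g, row.direction, chan, cutoffs,
                                 cap_tolerance, viability_floor)
        results.append((g, res.ires_score, res.cap_score, res.viability_score,
                        res.confirmed, res.ires_specific, res.viable,
                        res.specific_hit))
    table = pd.DataFrame(results, columns=SECONDARY_COLUMNS)
    summary = {
        "n_hits": int(len(hit_rows)),
        "n_tested": int(len(table)),
        "n_confirmed": int(table["confirmed"].sum()) if len(table) else 0,
        "n_ires_specific": int(table["ires_specific"].sum()) if len(table) else 0,
        "n_specific_viable": int(table["specific_hit"].sum()) if len(table) else 0,
        "untested": untested,
    }
    return table, summary
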