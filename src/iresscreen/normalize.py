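"""Percent-of-control plate normalization and replicate aggregation.

Every raw well value is expressed relative to the median of the scrambled
negative-control wells on its own plate (set to 100), channel by channel;
controls themselves are normalized too so the anchor is directly checkable.
Per-siRNA reaction scores are the median of the normalized values across
replicate plates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import screen_io as sio
from .errors import NormalizationError

logger = logging.getLogger(__name__)

REACTION_COLUMNS = ["gene_symbol", "sirna_index", "channel", "score",
                    "n_replicates_used", "usable"]


def plate_control_median(measurements: pd.DataFrame, layout: pd.DataFrame) -> float:
    """Median raw value of the scrambled-control wells of one plate/channel.

    ``measurements`` must contain a single plate and channel.  Even control
    counts use the midpoint of the two central values.  Raises
    :class:`NormalizationError` if no scrambled well was measured, or the
    median is zero.
    """
    plates = measurements["plate_id"].unique()
    channels = measurements["channel"].unique()
    if len(plates) != 1 or len(channels) != 1:
        raise NormalizationError(
            "plate_control_median expects measurements from exactly one "
            f"plate and channel, got plates={list(plates)}, channels={list(channels)}"
        )
    scram_wells = layout.loc[
        (layout["plate_id"] == plates[0])
        & (layout["content_type"] == sio.CONTENT_SCRAMBLED), "well",
    ]
    vals = measurements.loc[measurements["well"].isin(scram_wells), "value"]
    if vals.empty:
        raise NormalizationError(
            f"plate {plates[0]} channel {channels[0]}: no measured "
            "scrambled-control well; plate is unusable"
        )
    med = float(np.median(vals.to_numpy()))
    if med <= 0:
        raise NormalizationError(
            f"plate {plates[0]} channel {channels[0]}: control median is {med}"
        )
    return med


def normalize_plate(measurements: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Normalize one plate/channel to the percent-of-control scale.

    ``normalized_value = raw / control_median * 100`` for every well,
    controls included.
    """
    med = plate_control_median(measurements, layout)
    out = measurements.copy()
    out["normalized_value"] = out["value"] / med * 100.0
    return out.drop(columns="value")


def normalize_screen(measurements: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Normalize every plate x channel of a measurement table.

    Vectorized equivalent of calling :func:`normalize_plate` per group.
    """
    meas = measurements
    scram = layout.loc[layout["content_type"] == sio.CONTENT_SCRAMBLED,
                       ["plate_id", "well"]]
    ctrl = meas.merge(scram, on=["plate_id", "well"])
    med = ctrl.groupby(["plate_id", "channel"])["value"].median()
    groups = meas[["plate_id", "channel"]].drop_duplicates()
    missing = [
        (p, c) for p, c in groups.itertuples(index=False) if (p, c) not in med.index
    ]
    if missing:
        p, c = missing[0]
        raise NormalizationError(
            f"plate {p} channel {c}: no measured scrambled-control well "
            f"({len(missing)} plate/channel group(s) affected)"
        )
    if (med <= 0).any():
        bad = med[med <= 0].index[0]
        raise NormalizationError(f"plate {bad[0]} channel {bad[1]}: control median <= 0")
    denom = med.loc[pd.MultiIndex.from_frame(meas[["plate_id", "channel"]])].to_numpy()
    out = meas.copy()
    out["normalized_value"] = out["value"] / denom * 100.0
    return out.drop(columns="value")


def aggregate_replicates(
    normalized: pd.DataFrame, layout: pd.DataFrame, min_replicates: int = 2
) -> pd.DataFrame:
    """Collapse replicate plates to per-siRNA reaction scores.

    The score is the median of the normalized values of one gene x siRNA x
    channel across replicate plates.  Reactions with fewer than
    ``min_replicates`` contributing values are kept but flagged unusable
    (excluded from hit calling) with a logged warning.
    """
    lay = layout.loc[layout["content_type"] == sio.CONTENT_GENE,
                     ["plate_id", "well", "gene_symbol", "sirna_index"]]
    merged = normalized.merge(lay, on=["plate_id", "well"])
    if merged.empty:
        return pd.DataFrame(columns=REACTION_COLUMNS)
    grouped = merged.groupby(["gene_symbol", "sirna_index", "channel"],
                             sort=True)["normalized_value"]
    scores = grouped.median().rename("score")
    counts = grouped.size().rename("n_replicates_used")
    out = pd.concat([scores, counts], axis=1).reset_index()
    out["sirna_index"] = out["sirna_index"].astype(int)
    out["usable"] = out["n_replicates_used"] >= min_replicates
    n_bad = int((~out["usable"]).sum())
    if n_bad:
        logger.warning(
            "%d reaction(s) have fewer than %d replicates and are excluded "
            "from hit calling", n_bad, min_replicates,
        )
    return out[REACTION_COLUMNS]
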