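"""Model-space consensus of repeated contour readings.

Several readers trace each hippocampus several times, and the tracings
disagree.  Averaging the raw Cartesian coordinates of discordant readings can
produce anatomically illegal curves (self-intersections), because at a given
point index two readers may have annotated different structures.  Instead,
each reading is projected onto the fitted point-distribution model, the mode
coefficients are averaged, and the average is back-projected — the consensus
therefore always lies in the model's span and inherits its anatomical
plausibility.

The mean is taken in two stages — repeats are first averaged within each
reader, then across readers — so a reader who traced three times does not
outweigh one who traced twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shape_model import PointDistributionModel, ShapeParameters

__all__ = ["ConsensusShape", "consensus_by_subject", "consensus_matrix"]


@dataclass
class ConsensusShape:
    """Per-(subject, side) consensus in model space.

    ``shape`` is exactly the back-projection of ``params`` (it lies in the
    model's span by construction).
    """

    subject_id: str
    side: str
    group: str
    params: ShapeParameters
    shape: np.ndarray
    n_readings: int


def consensus_by_subject(
    model: PointDistributionModel,
    aligned_shapes: np.ndarray,
    meta: pd.DataFrame,
    M: int,
) -> list:
    """Collapse aligned readings into one consensus per (subject, side).

    Parameters
    ----------
    model : fitted PointDistributionModel
    aligned_shapes : (n_readings, 2N) ndarray
        Readings aligned into the model's frame.
    meta : DataFrame
        Row-aligned provenance with columns ``subject_id``, ``side``,
        ``group``, ``reader_id``, ``repeat_index``.
    M : int
        Number of leading modes kept for averaging (the same truncation the
        classifier consumes).

    Returns
    -------
    list of ConsensusShape, sorted by (subject_id, side).  A subject with no
    readings for a side is simply absent (with a warning if the side exists
    for other subjects).
    """
    aligned_shapes = np.asarray(aligned_shapes, dtype=float)
    if len(aligned_shapes) != len(meta):
        raise ValueError("aligned_shapes and meta must have equal length")
    params_all = model.transform(aligned_shapes, n_modes=M)
    frame = meta.reset_index(drop=True).copy()
    frame["_row"] = np.arange(len(frame))

    out = []
    sides_present = sorted(frame["side"].unique())
    for (subject, side), block in frame.groupby(["subject_id", "side"], sort=True):
        groups = block["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {subject!r} has inconsistent group labels")
        per_reader = [
            params_all[rows["_row"].to_numpy()].mean(axis=0)
            for _, rows in block.groupby("reader_id", sort=True)
        ]
        b = np.mean(per_reader, axis=0)
        params = ShapeParameters(b=b, model_ref=model, M=M)
        out.append(
            ConsensusShape(
                subject_id=subject,
                side=side,
                group=str(groups[0]),
                params=params,
                shape=model.inverse_transform(b[None, :])[0],
                n_readings=len(block),
            )
        )
    for subject in frame["subject_id"].unique():
        have = set(frame.loc[frame["subject_id"] == subject, "side"])
        for side in sides_present:
            if side not in have:
                warnings.warn(
                    f"subject {subject!r} has no readings for side {side!r}; omitted",
                    stacklevel=2,
                )
    out.sort(key=lambda c: (c.subject_id, c.side))
    return out


def consensus_matrix(consensus: list, side: str | None = None):
    """Stack consensus parameters into (B, labels, subjects) arrays.

    ``B`` is (n_consensus, M); ``labels`` the group strings; convenience for
    feeding the classifier.
    """
    rows = [c for c in consensus if side is None or c.side == side]
    B = np.asarray([c.params.b for c in rows])
    labels = np.asarray([c.group for c in rows])
    subjects = [c.subject_id for c in rows]
    return B, labels, subjects
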