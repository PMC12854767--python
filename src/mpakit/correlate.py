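"""Structure–spectroscopy correlation across snapshots.

Joins per-frame structural descriptors (BLA, planarity) with per-snapshot
first excitation energies by nearest-time matching, then quantifies the
relationships with Pearson/Spearman coefficients and an OLS line.  Across a
well-sampled ensemble, lower bond-length alternation and higher planarity
(higher conjugation) go with a lower first excitation energy, so the
BLA–E1 correlation is expected positive and the planarity–E1 correlation
negative.

No p-values are reported: consecutive snapshots are autocorrelated, so the
nominal sample size overstates the information content; the coefficients
are descriptive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SnapshotRecord
from .structure import StructuralTimeline

__all__ = ["JoinedRecord", "join", "correlation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JoinedRecord:
    """One snapshot with its structural descriptors and first excitation energy."""

    snapshot_id: int
    time: float          # fs
    bla: float           # Å
    planarity: float
    e1: float            # eV


def join(
    timeline: StructuralTimeline,
    records: Sequence[SnapshotRecord],
    tolerance: float | None = None,
    state_index: int = 1,
) -> list[JoinedRecord]:
    """Nearest-time match of structural frames to excited-state snapshots.

    ``tolerance`` defaults to half the structural frame interval; record
    times farther than that from every frame are dropped (count logged).
    Raises if the time ranges do not overlap or nothing matches.
    """
    t_frames = np.asarray(timeline.times, dtype=float)
    if tolerance is None:
        dt = np.min(np.diff(t_frames)) if t_frames.size > 1 else 0.0
        tolerance = dt / 2.0 if dt > 0 else np.inf
    rec_times = np.array([r.time for r in records])
    if rec_times.min() > t_frames.max() or rec_times.max() < t_frames.min():
        raise ValueError("no overlap between record and frame time ranges")
    joined: list[JoinedRecord] = []
    dropped = 0
    for r in records:
        i = int(np.argmin(np.abs(t_frames - r.time)))
        if abs(t_frames[i] - r.time) > tolerance:
            dropped += 1
            continue
        joined.append(
            JoinedRecord(
                snapshot_id=r.snapshot_id,
                time=r.time,
                bla=float(timeline.bla[i]),
                planarity=float(timeline.planarity[i]),
                e1=float(r.state(state_index).energy),
            )
        )
    if dropped:
        logger.info("join: dropped %d/%d records beyond tolerance %.3g fs",
                    dropped, len(records), tolerance)
    if not joined:
        raise ValueError("empty join: no record matched any frame within tolerance")
    return joined


def to_frame(joined: Sequence[JoinedRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(j) for j in joined])


def correlation(
    joined: Sequence[JoinedRecord], x: str, y: str = "e1"
) -> dict[str, float]:
    """Pearson r, Spearman rho and the OLS line of y against descriptor x.

    ``x`` and ``y`` name JoinedRecord fields ("bla", "planarity", "e1").
    Requires n >= 3 and non-degenerate variance in both variables.
    """
    xv = np.array([getattr(j, x) for j in joined], dtype=float)
    yv = np.array([getattr(j, y) for j in joined], dtype=float)
    if xv.size < 3:
        raise ValueError("need at least 3 joined records")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    ols = stats.linregress(xv, yv)
    rho = stats.spearmanr(xv, yv).statistic
    return {
        "pearson_r": float(ols.rvalue),
        "spearman_rho": float(rho),
        "slope": float(ols.slope),
        "intercept": float(ols.intercept),
        "n": int(xv.size),
    }
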