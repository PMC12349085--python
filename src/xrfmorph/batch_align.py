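"""Session (setup) batch correction and pseudo-replicate averaging.

Spectra acquired on different beamline setups differ in morphology even for
the same physical zone.  Control specimens measured in every session provide
*homologous* spectrum pairs; the per-landmark mean difference Delta between a
session and the reference session is subtracted from all of that session's
spectra, aligning the sessions directly (no chaining).  Zones measured in
several sessions are then averaged into a single spectrum each, so repeatedly
measured specimens are not over-represented downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import LandmarkMatrix, N_LANDMARKS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BatchDelta:
    """Per-landmark mean difference between a session and the reference."""

    session: str
    reference_session: str
    delta: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "delta", d)
        if d.shape != (N_LANDMARKS,):
            raise ValueError(f"delta must have length {N_LANDMARKS}")
        if self.n_pairs < 1:
            raise ValueError("a BatchDelta needs at least one homologous pair")


def pair_homologous(
    matrix: LandmarkMatrix, session: str, reference_session: str
) -> list[tuple[int, int]]:
    """Indices of homologous row pairs (session row, reference row).

    The pairing key is ``zone_id`` (the specimen + zone-index identity, shared
    across sessions).  Zones lacking a partner in the other session are
    excluded and logged; control zones need no special manifest flag.
    """
    meta = matrix.meta
    for s in (session, reference_session):
        if not (meta["session"] == s).any():
            raise ValueError(f"session {s!r} absent from the matrix")
    ses_rows = {z: i for i, z in zip(meta.index, meta["zone_id"]) if meta.at[i, "session"] == session}
    ref_rows = {z: i for i, z in zip(meta.index, meta["zone_id"]) if meta.at[i, "session"] == reference_session}
    pairs = [(ses_rows[z], ref_rows[z]) for z in ses_rows if z in ref_rows]
    unmatched = sorted(set(ses_rows) ^ set(ref_rows))
    if unmatched:
        logger.info(
            "pair_homologous(%s vs %s): %d zone(s) without a partner excluded: %s",
            session, reference_session, len(unmatched), unmatched,
        )
    if not pairs:
        raise ValueError(f"no homologous spectra between {session!r} and {reference_session!r}")
    return sorted(pairs)


def compute_mean_delta(
    matrix: LandmarkMatrix,
    pairs: list[tuple[int, int]],
    session: str,
    reference_session: str,
) -> BatchDelta:
    """Mean over pairs of (session landmarks - reference landmarks)."""
    if not pairs:
        raise ValueError("need at least one homologous pair")
    diffs = np.stack([matrix.values[i] - matrix.values[j] for i, j in pairs])
    return BatchDelta(
        session=session,
        reference_session=reference_session,
        delta=diffs.mean(axis=0),
        n_pairs=len(pairs),
    )


def apply_realignment(matrix: LandmarkMatrix, delta: BatchDelta) -> LandmarkMatrix:
    """Subtract ``delta`` from every row of its session; other rows untouched."""
    if delta.delta.shape != (matrix.grid.size,):
        raise ValueError("delta grid does not match matrix grid")
    mask = (matrix.meta["session"] == delta.session).to_numpy()
    values = matrix.values.copy()
    if not mask.any():
        logger.warning("session %r absent from matrix; returning it unchanged", delta.session)
    else:
        values[mask] -= delta.delta
    return LandmarkMatrix(values, matrix.meta.copy(), matrix.grid, aligned=True)


def realign_sessions(matrix: LandmarkMatrix, reference_session: str) -> tuple[LandmarkMatrix, list[BatchDelta]]:
    """Align every non-reference session directly to the reference session."""
    sessions = [s for s in pd.unique(matrix.meta["session"]) if s != reference_session]
    if not (matrix.meta["session"] == reference_session).any():
        raise ValueError(f"reference session {reference_session!r} absent from the matrix")
    deltas = []
    out = matrix
    for ses in sessions:
        pairs = pair_homologous(out, ses, reference_session)
        delta = compute_mean_delta(out, pairs, ses, reference_session)
        out = apply_realignment(out, delta)
        deltas.append(delta)
        logger.info("realigned %s -> %s using %d homologous pairs", ses, reference_session, delta.n_pairs)
    out.aligned = True
    return out, deltas


def average_pseudoreplicates(matrix: LandmarkMatrix) -> LandmarkMatrix:
    """Collapse rows sharing a zone_id to their landmark-wise mean.

    Merged rows get session "merged"; zones measured in a single session pass
    through unchanged.  Requires a realigned matrix (or a single-session one,
    where realignment is vacuous).
    """
    n_sessions = matrix.meta["session"].nunique()
    if not matrix.aligned and n_sessions > 1:
        raise ValueError("average_pseudoreplicates requires a realigned multi-session matrix")
    rows = []
    meta_rows = []
    for zone_id, idx in matrix.meta.groupby("zone_id", sort=False).groups.items():
        idx = list(idx)
        rows.append(matrix.values[idx].mean(axis=0))
        m = matrix.meta.loc[idx[0]].copy()
        if len(idx) > 1:
            m["session"] = "merged"
        meta_rows.append(m)
    merged = LandmarkMatrix(
        np.vstack(rows), pd.DataFrame(meta_rows).reset_index(drop=True), matrix.grid, aligned=matrix.aligned
    )
    logger.info("averaged pseudo-replicates: %d rows -> %d rows", matrix.n_rows, merged.n_rows)
    return merged
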