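"""Chaos-game representation of nucleotide sequences (auxiliary view).

Each base maps to a corner of the unit square — A:(0,0), C:(0,1), G:(1,1),
T/U:(1,0) — and the trace walks halfway from the previous point towards the
current base's corner, starting from the centroid (0.5, 0.5):

    p_i = p_{i-1} + alpha * (v_{x_i} - p_{i-1}),   alpha = 0.5.

The 2-D trace is collapsed to one scalar per position, the difference of the
vertical and horizontal components (state_i = y_i - x_i in [-1, 1]), giving
the L0 x 1 feature matrix fed to the auxiliary BiLSTM branch.  Because each
step halves the influence of everything before it, the coordinate carries the
current base's identity plus an exponentially decaying memory of the prefix.

Gap-padded positions ('-') carry no sequence identity, so the walk is frozen
there: the coordinate (and hence the state) repeats the previous position's
value, with state 0 for a leading gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import SequenceRecord

ALPHA = 0.5
VERTICES = {
    "A": np.array([0.0, 0.0]),
    "C": np.array([0.0, 1.0]),
    "G": np.array([1.0, 1.0]),
    "T": np.array([1.0, 0.0]),
    "U": np.array([1.0, 0.0]),
}


@dataclass(frozen=True)
class CgrTrace:
    """Per-position 2-D coordinates and scalar states of one sequence."""

    coords: np.ndarray  # (L, 2), each row in [0,1]^2
    states: np.ndarray  # (L,), each in [-1, 1]
    alpha: float = ALPHA


def cgr_trace(seq: str, alpha: float = ALPHA) -> CgrTrace:
    """Walk the iterated function system over `seq` and record every point."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    coords = np.empty((len(seq), 2))
    p = np.array([0.5, 0.5])
    for i, base in enumerate(seq.upper()):
        if base == "-":
            coords[i] = p  # frozen walk on padding
            continue
        try:
            v = VERTICES[base]
        except KeyError:
            raise ValueError(f"illegal character {base!r} at position {i}") from None
        p = p + alpha * (v - p)
        coords[i] = p
    states = coords[:, 1] - coords[:, 0]
    # leading gaps sit at the centroid, whose state is already 0
    return CgrTrace(coords=coords, states=states, alpha=alpha)


def cgr_states(trace: CgrTrace) -> np.ndarray:
    """Scalar state vector: vertical minus horizontal component per position."""
    return trace.coords[:, 1] - trace.coords[:, 0]


def encode_batch(records: list[SequenceRecord]) -> np.ndarray:
    """Stack state vectors of equal-length records into an (N, L0, 1) array."""
    if not records:
        return np.empty((0, 0, 1))
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"records have ragged lengths {sorted(lengths)}; pad first")
    states = np.stack([cgr_trace(r.seq).states for r in records])
    return states[:, :, None]


def write_trace_csv(trace: CgrTrace, path: str | Path) -> None:
    """Debug dump: one row per position with x, y and state."""
    with open(path, "w") as fh:
        fh.write("position,x,y,state\n")
        for i, ((x, y), s) in enumerate(zip(trace.coords, trace.states)):
            fh.write(f"{i},{x:.10g},{y:.10g},{s:.10g}\n")
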