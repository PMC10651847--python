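"""Shared containers: per-molecule intensity traces and tabular trace I/O.

An :class:`IntensityTrace` holds the background-subtracted donor and acceptor
intensity time series of one surface-immobilized molecule, sampled at a fixed
frame interval (0.1 s per frame in the canonical imaging conditions).
Trace sets round-trip through a TSV table with columns
``molecule_id, frame, I_donor, I_acceptor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["IntensityTrace", "traces_to_frame", "frame_to_traces", "write_traces", "read_traces"]


@dataclass
class IntensityTrace:
    """Donor/acceptor intensity time series of one molecule.

    Parameters
    ----------
    donor, acceptor : ndarray
        Per-frame background-subtracted intensities (counts). Equal length.
    frame_dt : float
        Frame interval in seconds.
    molecule_id : int
        Identifier within a dataset.
    meta : dict
        Free-form provenance (ground-truth bleach frames, generating rates,
        extraction flags...). Never consumed by analysis code.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    frame_dt: float = 0.1
    molecule_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.donor.shape != self.acceptor.shape:
            raise InvalidParameterError("donor and acceptor must be equal-length 1-D arrays")
        if self.frame_dt <= 0:
            raise InvalidParameterError("frame_dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    """Stack traces into a long-format table (molecule_id, frame, I_donor, I_acceptor)."""
    if not traces:
        return pd.DataFrame(columns=["molecule_id", "frame", "I_donor", "I_acceptor"])
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(tr.n_frames),
                    "I_donor": tr.donor,
                    "I_acceptor": tr.acceptor,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame, frame_dt: float = 0.1) -> list[IntensityTrace]:
    """Inverse of :func:`traces_to_frame`; traces ordered by molecule_id."""
    out = []
    for mid, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            IntensityTrace(
                donor=grp["I_donor"].to_numpy(),
                acceptor=grp["I_acceptor"].to_numpy(),
                frame_dt=frame_dt,
                molecule_id=int(mid),
            )
        )
    return out


def write_traces(path, traces: list[IntensityTrace]) -> None:
    traces_to_frame(traces).to_csv(path, sep="\t", index=False)


def read_traces(path, frame_dt: float = 0.1) -> list[IntensityTrace]:
    return frame_to_traces(pd.read_csv(path, sep="\t"), frame_dt=frame_dt)
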