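"""Per-base posterior accessibility tracks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .intervals import GenomicInterval


@dataclass
class PosteriorTrack:
    """Per-base posterior probability of the open macro-state."""

    chrom: str
    start: int
    p_open: np.ndarray

    def __post_init__(self):
        self.p_open = np.asarray(self.p_open, dtype=float)
        if self.p_open.ndim != 1 or len(self.p_open) < 1:
            raise ValidationError("p_open must be a non-empty 1-D array")
        if ((self.p_open < 0) | (self.p_open > 1)).any():
            raise ValidationError("posterior probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p_open)

    @property
    def end(self) -> int:
        return self.start + len(self.p_open)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def write_bedgraph(track: PosteriorTrack, path, precision: int = 6) -> None:
    """Write p_open as bedGraph, collapsing runs of equal value."""
    vals = np.round(track.p_open, precision)
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vals)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(
                f"{track.chrom}\t{track.start + s}\t{track.start + e}\t{vals[s]:.{precision}g}\n"
            )
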