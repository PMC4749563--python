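"""Per-base genomic signal container.

A :class:`SignalTrack` holds one non-negative float array per chromosome
(per-base resolution; bedGraph input is expanded on read).  ``total_mapped``
is the library size used for RPM normalization and is carried through
arithmetic-free transformations so normalization is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["SignalTrack"]


@dataclass
class SignalTrack:
    values: dict[str, np.ndarray]
    total_mapped: float | None = None
    units: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, v in self.values.items():
            arr = np.asarray(v, dtype=float)
            if (arr < 0).any():
                raise InvalidParameterError(f"negative signal values on {c}")
            self.values[c] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy_with(self, values: dict[str, np.ndarray], units: str | None = None) -> "SignalTrack":
        return SignalTrack(
            values=values,
            total_mapped=self.total_mapped,
            units=units if units is not None else self.units,
            meta=dict(self.meta),
        )

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of values in [start, end), clipped to the chromosome."""
        arr = self.values[chrom]
        start = max(int(start), 0)
        end = min(int(end), len(arr))
        if end <= start:
            return 0.0
        return float(arr[start:end].sum())
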