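"""Toy genome and the two-zone centromere suppression model.

The toy genome stands in for a budding-yeast-like genome at desk scale:
a handful of chromosomes, each with a single point centromere, a set of
DSB hotspots with heavy-tailed intensities, and a regular grid of
heterozygous markers (hybrid-like SNP density).

The suppression model encodes two mechanistically distinct zones around
each centromere:

* a mid-range zone in which DSB formation itself is damped, with
  residual intensity ``s0`` at the centromere recovering exponentially
  with length scale ``dsb_tau`` (so ~95% recovery by ~3*tau); and
* a broader zone (half-width ``co_halfwidth``, default 20 kb) in which a
  DSB that does form is repaired from the sister chromatid with
  probability ``sister_bias`` and therefore never appears as a CO or NCO
  between homologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["ToyGenome", "SuppressionModel", "dsb_suppression_factor"]


@dataclass
class ToyGenome:
    """Synthetic genome annotation.

    Attributes
    ----------
    chrom_names:
        Ordered chromosome identifiers.
    chrom_lengths:
        Mapping chromosome -> length in bp.
    cen_mid:
        Mapping chromosome -> centromere midpoint (bp, 0-based).
    hotspots:
        DataFrame with columns ``chrom``, ``pos`` (bp), ``intensity``
        (relative heat, >= 0).
    markers:
        DataFrame with columns ``chrom``, ``pos`` (bp); positions strictly
        increasing within each chromosome.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cen_mid: dict[str, int]
    hotspots: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "intensity"]))
    markers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "pos"]))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for c in self.chrom_names:
            length = self.chrom_lengths[c]
            if length <= 0:
                raise InvalidParameterError(f"chromosome {c} has non-positive length {length}")
            cen = self.cen_mid[c]
            if not (0 < cen < length):
                raise InvalidParameterError(f"centromere of {c} at {cen} outside (0, {length})")
        for df, what in ((self.hotspots, "hotspot"), (self.markers, "marker")):
            for c, sub in df.groupby("chrom", sort=False):
                length = self.chrom_lengths[str(c)]
                pos = sub["pos"].to_numpy()
                if ((pos < 0) | (pos >= length)).any():
                    raise InvalidParameterError(f"{what} position outside [0, {length}) on {c}")
        for c, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise InvalidParameterError(f"marker positions not strictly increasing on {c}")
        if len(self.hotspots) and (self.hotspots["intensity"].to_numpy() < 0).any():
            raise InvalidParameterError("hotspot intensities must be >= 0")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths[c] for c in self.chrom_names))

    def marker_positions(self, chrom: str) -> np.ndarray:
        sub = self.markers[self.markers["chrom"] == chrom]
        return sub["pos"].to_numpy(dtype=np.int64)

    def centromere_table(self) -> pd.DataFrame:
        """Centromere midpoints as a one-row-per-chromosome table."""
        return pd.DataFrame(
            {"chrom": self.chrom_names, "cen_mid": [self.cen_mid[c] for c in self.chrom_names]}
        )


@dataclass(frozen=True)
class SuppressionModel:
    """Two-zone pericentromeric suppression parameters.

    ``dsb_floor`` (s0) is the residual relative DSB intensity at the
    centromere itself; ``dsb_tau`` the exponential recovery length (bp);
    ``co_halfwidth`` the half-width of the sister-bias zone (bp);
    ``sister_bias`` the probability that a DSB inside that zone is
    repaired from the sister and is therefore invisible in the spores.
    """

    dsb_floor: float = 0.1
    dsb_tau: float = 1500.0
    co_halfwidth: float = 20_000.0
    sister_bias: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsb_floor <= 1.0:
            raise InvalidParameterError(f"dsb_floor must be in [0,1], got {self.dsb_floor}")
        if self.dsb_tau <= 0:
            raise InvalidParameterError(f"dsb_tau must be > 0, got {self.dsb_tau}")
        if self.co_halfwidth < 0:
            raise InvalidParameterError(f"co_halfwidth must be >= 0, got {self.co_halfwidth}")
        if not 0.0 <= self.sister_bias <= 1.0:
            raise InvalidParameterError(f"sister_bias must be in [0,1], got {self.sister_bias}")


def dsb_suppression_factor(distance: np.ndarray | float, model: SuppressionModel) -> np.ndarray | float:
    """Relative DSB intensity f(x) at distance ``x`` from the centromere midpoint.

    f(x) = s0 + (1 - s0) * (1 - exp(-x / tau)); f(0) = s0, f(inf) = 1.
    """
    x = np.abs(distance)
    s0 = model.dsb_floor
    return s0 + (1.0 - s0) * (1.0 - np.exp(-x / model.dsb_tau))
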