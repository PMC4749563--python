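"""Three-color fluorescent tetrad scoring and tetrad-based map distance.

A heterozygous GFP and RFP reporter pair flanking an interval segregates
into the four spores of a tetrad; the joint GFP/RFP pattern classifies the
tetrad as parental ditype (PD), non-parental ditype (NPD) or tetratype
(TT).  A homozygous CFP reporter marks spores that inherited a full
chromosome complement: tetrads in which any spore lacks CFP are excluded,
which guards against chromosome mis-segregation confounding the CO count.

Map distance is the Perkins estimator

    cM = 100 * (TT/2 + 3*NPD) / n,   n = PD + NPD + TT

with a multinomial delta-method standard error.  Strain comparisons use a
two-sided Fisher's exact test on recombinant (TT+NPD) vs parental (PD)
tetrad counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError, MalformedInputError

__all__ = [
    "SporeColors",
    "TetradTypeCounts",
    "MapDistanceEstimate",
    "classify_tetrad",
    "tally",
    "perkins_map_distance",
    "compare_map_distance",
    "bootstrap_se",
    "required_tetrads",
]

PD, NPD, TT, EXCLUDED = "PD", "NPD", "TT", "EXCLUDED"


@dataclass(frozen=True)
class SporeColors:
    """Fluorescence state of one spore."""

    gfp: bool
    rfp: bool
    cfp: bool


@dataclass(frozen=True)
class TetradTypeCounts:
    pd: int
    npd: int
    tt: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.pd, self.npd, self.tt, self.excluded) < 0:
            raise InvalidParameterError("tetrad type counts must be >= 0")

    @property
    def n(self) -> int:
        """Informative tetrads (excluded tetrads never enter n)."""
        return self.pd + self.npd + self.tt


@dataclass(frozen=True)
class MapDistanceEstimate:
    cm: float
    se: float
    n: int


def classify_tetrad(colors: Sequence[SporeColors | tuple], phase: str = "cis") -> str:
    """Classify one tetrad from its four spores' GFP/RFP/CFP states.

    ``phase`` declares whether RFP and GFP entered the cross on the same
    parental homolog (``cis``) or on opposite homologs (``trans``); the
    trans configuration swaps the PD and NPD patterns.

    Returns ``"PD"``, ``"NPD"``, ``"TT"`` or ``"EXCLUDED"``.  A tetrad is
    excluded if any spore lacks CFP, or if GFP or RFP does not segregate
    2:2 (reporter gene conversion or mis-segregation).
    """
    if phase not in ("cis", "trans"):
        raise InvalidParameterError(f"phase must be 'cis' or 'trans', got {phase!r}")
    spores = [s if isinstance(s, SporeColors) else SporeColors(*s) for s in colors]
    if len(spores) != 4:
        raise MalformedInputError(f"a tetrad has exactly four spores, got {len(spores)}")
    if not all(s.cfp for s in spores):
        return EXCLUDED
    n_gfp = sum(s.gfp for s in spores)
    n_rfp = sum(s.rfp for s in spores)
    if n_gfp != 2 or n_rfp != 2:
        return EXCLUDED
    n_both = sum(s.gfp and s.rfp for s in spores)
    # With both markers 2:2, n_both is 2 (ditype) or 1 (tetratype).
    if n_both == 1:
        return TT
    parental_is_both = phase == "cis"
    if (n_both == 2) == parental_is_both:
        return PD
    return NPD


def tally(classes: Iterable[str]) -> TetradTypeCounts:
    """Count tetrad classes; order-independent."""
    counts = {PD: 0, NPD: 0, TT: 0, EXCLUDED: 0}
    for c in classes:
        if c not in counts:
            raise MalformedInputError(f"unknown tetrad class {c!r}")
        counts[c] += 1
    return TetradTypeCounts(pd=counts[PD], npd=counts[NPD], tt=counts[TT], excluded=counts[EXCLUDED])


def perkins_map_distance(counts: TetradTypeCounts) -> MapDistanceEstimate:
    """Perkins map distance (cM) with delta-method standard error.

    With t = TT/n and v = NPD/n the estimator is 100*(t/2 + 3v) and its
    multinomial sampling variance is (t(1-t)/4 + 9v(1-v) - 3tv)/n, from
    Var(t), Var(v) and Cov(t, v) = -tv/n.
    """
    n = counts.n
    if n < 1:
        raise InsufficientDataError("no informative tetrads (PD+NPD+TT = 0)")
    t = counts.tt / n
    v = counts.npd / n
    cm = 100.0 * (t / 2.0 + 3.0 * v)
    var = (t * (1.0 - t) / 4.0 + 9.0 * v * (1.0 - v) - 3.0 * t * v) / n
    se = 100.0 * math.sqrt(max(var, 0.0))
    return MapDistanceEstimate(cm=cm, se=se, n=n)


def perkins_se_at_truth(t: float, v: float, n: int) -> float:
    """Standard error of the Perkins estimator at known class probabilities.

    Used for parameter-recovery checks against a simulation truth, where
    the sampling SE at the true (t, v) is the proper yardstick (the
    plug-in SE degenerates to 0 in zero-recombinant samples).
    """
    var = (t * (1.0 - t) / 4.0 + 9.0 * v * (1.0 - v) - 3.0 * t * v) / n
    return 100.0 * math.sqrt(max(var, 0.0))


def compare_map_distance(a: TetradTypeCounts, b: TetradTypeCounts) -> float:
    """Two-sided Fisher's exact p-value comparing two strains.

    The 2x2 table is recombinant-type tetrads (TT+NPD) vs parental (PD)
    for each strain.  Note NPD-weighted alternatives exist (an NPD carries
    two COs); this construction treats tetrad classes, not COs, as the
    sampling unit.
    """
    if a.n < 1 or b.n < 1:
        raise InsufficientDataError("both strains need at least one informative tetrad")
    table = [[a.tt + a.npd, a.pd], [b.tt + b.npd, b.pd]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bootstrap_se(counts: TetradTypeCounts, n_boot: int = 10_000, seed: int | None = 0) -> float:
    """Bootstrap SE of the Perkins estimate (multinomial resampling)."""
    n = counts.n
    if n < 1:
        raise InsufficientDataError("no informative tetrads")
    rng = np.random.default_rng(seed)
    p = np.array([counts.pd, counts.npd, counts.tt], dtype=float) / n
    draws = rng.multinomial(n, p, size=n_boot).astype(float)
    est = 100.0 * (draws[:, 2] / 2.0 + 3.0 * draws[:, 1]) / n
    return float(est.std(ddof=1))


def required_tetrads(d1_cm: float, d2_cm: float, alpha: float = 0.05, power: float = 0.87) -> int:
    """Tetrads per strain to distinguish two map distances.

    A documented planning helper: treats the Perkins estimates as normal
    with the delta-method SE at each truth (small-distance approximation
    t ~ 2d/100 Morgans doubled, v ~ 0) and solves the usual two-sample
    z-test sample-size equation.  Approximate by construction.
    """
    if d1_cm < 0 or d2_cm < 0:
        raise InvalidParameterError("map distances must be >= 0")
    if d1_cm == d2_cm:
        raise InvalidParameterError("cannot power a test of identical distances")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)

    def var1(d_cm: float) -> float:  # per-tetrad variance of the cM estimate
        t = min(2.0 * d_cm / 100.0, 1.0)  # P(TT) ~ 2*Morgans at small d
        return 100.0**2 * (t * (1 - t) / 4.0)

    delta = abs(d1_cm - d2_cm)
    n = z**2 * (var1(d1_cm) + var1(d2_cm)) / delta**2
    return int(math.ceil(n))
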