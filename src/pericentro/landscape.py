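"""Spo11-oligo and ChIP-Seq signal analyses around centromeres.

Operations: RPM normalization, pericentromeric fold-change segments with
boxplot statistics, Hann-window smoothing, distance-to-centromere
profiles with a local-quadratic (loess) fit and bootstrap 95% CI,
per-centromere window folds, whole-chromosome log2 fold profiles,
interval fold changes, the DSB-vs-CO accounting percentage, and median
metaplots over pericentromeric regions.

Conventions: bins are half-open ``[k*bin, (k+1)*bin)`` anchored at the
centromere midpoint; the centromere anchor is the midpoint of the BED
centromere interval; smoothing at chromosome ends truncates and
renormalizes the kernel (constant tracks stay constant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedFoldError
from .events import _cen_mapping
from .track import SignalTrack

__all__ = [
    "rpm_normalize",
    "pericen_fold_change",
    "hann_smooth",
    "loess_fit",
    "distance_to_cen_profile",
    "recovery_distance",
    "cen_window_fold",
    "chrom_log2_profile",
    "interval_fold_change",
    "accounting_percent",
    "metaplot_median",
    "DistanceProfile",
    "FoldChangeTable",
    "AccountingResult",
]


# ---------------------------------------------------------------------------
# normalization and smoothing


def rpm_normalize(t: SignalTrack) -> SignalTrack:
    """Scale a raw-count track to reads per million total mapped reads.

    Uses ``t.total_mapped`` if set, else the track's own sum.  Applying
    it to an already-RPM track is a no-op (idempotent up to the units
    bookkeeping).
    """
    if t.units == "RPM":
        return t.copy_with({c: v.copy() for c, v in t.values.items()})
    total = t.total_mapped if t.total_mapped is not None else t.total()
    if not total or total <= 0:
        raise InvalidParameterError("cannot RPM-normalize: total mapped reads is zero")
    factor = 1e6 / total
    return t.copy_with({c: v * factor for c, v in t.values.items()}, units="RPM")


def hann_smooth(t: SignalTrack, window: int = 201) -> SignalTrack:
    """Smooth each chromosome with a unit-sum Hann window.

    w[j] = 0.5*(1 - cos(2*pi*j/(M-1))), j = 0..M-1, normalized to unit
    sum; at chromosome ends the kernel is truncated and renormalized so a
    constant track is reproduced exactly everywhere.
    """
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError(f"window must be odd and >= 3, got {window}")
    j = np.arange(window, dtype=float)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * j / (window - 1)))
    out: dict[str, np.ndarray] = {}
    for c, v in t.values.items():
        num = np.convolve(v, w, mode="same")
        den = np.convolve(np.ones_like(v), w, mode="same")
        out[c] = num / den
    return t.copy_with(out)


# ---------------------------------------------------------------------------
# local regression (loess)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    x_eval: np.ndarray | None = None,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For every evaluation point the nearest ``ceil(span*n)`` observations
    (by |x - x0|) get tricube weights (1 - (d/dmax)^3)^3 and a degree-
    ``degree`` weighted polynomial is fit; the prediction at x0 is
    returned.  NaN observations are dropped.
    """
    if not 0 < span <= 1:
        raise InvalidParameterError(f"span must be in (0,1], got {span}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x_eval is None:
        x_eval = x
    x_eval = np.asarray(x_eval, dtype=float)
    n = len(x)
    if n == 0:
        return np.full(len(x_eval), np.nan)
    q = max(int(math.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        wt = (1.0 - (d[idx] / dmax) ** 3) ** 3
        wt = np.clip(wt, 0.0, None)
        deg = min(degree, len(idx) - 1)
        # weighted least squares on a shifted basis for conditioning
        xs = x[idx] - x0
        design = np.vander(xs, deg + 1, increasing=True)
        sw = np.sqrt(wt)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out


# ---------------------------------------------------------------------------
# fold changes around centromeres


@dataclass
class FoldChangeTable:
    """Per-segment fold changes pooled across centromeres, plus boxplot stats."""

    folds: pd.DataFrame  # chrom, segment, rel_start, wt_density, mut_density, fold
    stats: pd.DataFrame  # segment, rel_start, median, q1, q3, whisker_low, whisker_high, n
    excluded: pd.DataFrame  # segments dropped because the wild-type density was zero


def _boxplot_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_bound) & (values <= hi_bound)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n": int(len(values)),
    }


def pericen_fold_change(
    wt: SignalTrack,
    mut: SignalTrack,
    cens,
    bin: int = 3000,
    span: int = 36_000,
) -> FoldChangeTable:
    """Mutant/wild-type density fold change in fixed segments around centromeres.

    The ``span`` bp region centered on each centromere midpoint is cut
    into ``span/bin`` segments (default 12 x 3 kb over +/-18 kb); per
    segment the density (signal per kb) is computed for both tracks and
    the fold mut/wt taken.  Segments with zero wild-type density are
    excluded and reported separately.  Folds are pooled across
    centromeres by relative position, with median/IQR/1.5*IQR-whisker
    summary statistics per relative segment.
    """
    if span % bin != 0:
        raise InvalidParameterError(f"span {span} is not a multiple of bin {bin}")
    cen_mid = _cen_mapping(cens)
    half = span // 2
    n_seg = span // bin
    rows, dropped = [], []
    for chrom, cm in cen_mid.items():
        if chrom not in wt.values or chrom not in mut.values:
            continue
        for k in range(n_seg):
            rel_start = -half + k * bin
            start, end = cm + rel_start, cm + rel_start + bin
            w = wt.interval_sum(chrom, start, end) / (bin / 1000.0)
            mu = mut.interval_sum(chrom, start, end) / (bin / 1000.0)
            rec = {
                "chrom": chrom,
                "segment": k,
                "rel_start": rel_start,
                "wt_density": w,
                "mut_density": mu,
            }
            if w <= 0:
                dropped.append(rec)
                continue
            rec["fold"] = mu / w
            rows.append(rec)
    folds = pd.DataFrame(rows, columns=["chrom", "segment", "rel_start", "wt_density", "mut_density", "fold"])
    stat_rows = []
    for (k, rel_start), sub in folds.groupby(["segment", "rel_start"], sort=True):
        stat_rows.append({"segment": k, "rel_start": rel_start, **_boxplot_stats(sub["fold"].to_numpy())})
    stats = pd.DataFrame(
        stat_rows,
        columns=["segment", "rel_start", "median", "q1", "q3", "whisker_low", "whisker_high", "n"],
    )
    excluded = pd.DataFrame(dropped, columns=["chrom", "segment", "rel_start", "wt_density", "mut_density"])
    return FoldChangeTable(folds=folds, stats=stats, excluded=excluded)


def cen_window_fold(wt: SignalTrack, mut: SignalTrack, cens, window: int = 10_000) -> pd.Series:
    """Per-chromosome mut/wt fold of summed signal in cen_mid +/- window/2.

    Chromosomes with a zero wild-type sum are reported as NaN.
    """
    cen_mid = _cen_mapping(cens)
    out = {}
    half = window // 2
    for chrom, cm in cen_mid.items():
        if chrom not in wt.values or chrom not in mut.values:
            continue
        w = wt.interval_sum(chrom, cm - half, cm + half)
        m = mut.interval_sum(chrom, cm - half, cm + half)
        out[chrom] = m / w if w > 0 else float("nan")
    return pd.Series(out, name="fold").sort_index()


def chrom_log2_profile(
    wt: SignalTrack,
    mut: SignalTrack,
    bin: int = 5000,
    pseudocount: float = 0.01,
    loess_span: float = 0.3,
) -> pd.DataFrame:
    """log2 mutant/wild-type fold in fixed bins along each chromosome.

    A pseudocount (default 0.01 RPM) guards zero bins, so a bin empty in
    both tracks reports 0 rather than an undefined value.  A loess curve
    (degree 2) is fit along each chromosome.
    """
    rows = []
    for chrom in wt.chroms:
        if chrom not in mut.values:
            continue
        w, m = wt.values[chrom], mut.values[chrom]
        n_bins = int(math.ceil(len(w) / bin))
        starts = np.arange(n_bins) * bin
        wsum = np.add.reduceat(w, starts)
        msum = np.add.reduceat(m, starts)
        log2fc = np.log2((msum + pseudocount) / (wsum + pseudocount))
        centers = starts + np.minimum(bin, len(w) - starts) / 2.0
        smooth = loess_fit(centers, log2fc, span=loess_span, degree=2) if n_bins >= 4 else log2fc
        for s, c, v, sm in zip(starts, centers, log2fc, smooth):
            rows.append(
                {"chrom": chrom, "bin_start": int(s), "bin_center": float(c), "log2_fold": float(v), "loess": float(sm)}
            )
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_center", "log2_fold", "loess"])


def interval_fold_change(wt: SignalTrack, mut: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Mut/wt fold of summed signal within [start, end)."""
    if end <= start:
        raise InvalidParameterError(f"empty interval [{start}, {end})")
    w = wt.interval_sum(chrom, start, end)
    m = mut.interval_sum(chrom, start, end)
    if w <= 0:
        raise UndefinedFoldError(f"wild-type signal is zero in {chrom}:{start}-{end}")
    return m / w


class AccountingResult(NamedTuple):
    percent: float
    percent_rounded: int


def accounting_percent(dsb_fold: float, co_fold: float) -> AccountingResult:
    """Fraction of a CO increase attributable to the DSB increase.

    100 * dsb_fold / co_fold, e.g. a ~5-fold DSB rise against a ~21-fold
    CO rise accounts for ~24% of the CO increase.  Returns the unrounded
    percentage and its nearest-integer rounding.
    """
    if co_fold <= 0:
        raise UndefinedFoldError("co_fold must be > 0")
    pct = 100.0 * dsb_fold / co_fold
    return AccountingResult(percent=pct, percent_rounded=int(round(pct)))


# ---------------------------------------------------------------------------
# distance profiles and metaplots


@dataclass
class DistanceProfile:
    """Signal density vs distance from the centromere, averaged across arms."""

    bin_start: np.ndarray  # bp from centromere midpoint (half-open bins)
    bin_center: np.ndarray
    mean: np.ndarray  # per-bin mean of per-base density across arms
    loess: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    genome_average: float
    n_arms: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "bin_center": self.bin_center,
                "mean": self.mean,
                "loess": self.loess,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _arm_bin_means(arr: np.ndarray, cen: int, bin: int, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean density for the two arms of one chromosome.

    Bin j covers distances [j*bin, (j+1)*bin) from the centromere
    midpoint; arms shorter than the profile contribute only their
    existing bases (partial terminal bins use the bases present).
    """
    left = arr[:cen][::-1]  # distance 1..cen (per-base, moving away)
    right = arr[cen:]
    out = []
    for armvals in (left, right):
        means = np.full(n_bins, np.nan)
        for j in range(n_bins):
            seg = armvals[j * bin : (j + 1) * bin]
            if len(seg):
                means[j] = seg.mean()
        out.append(means)
    return out[0], out[1]


def distance_to_cen_profile(
    t: SignalTrack,
    cens,
    bin: int = 500,
    max_dist: int = 75_000,
    loess_span: float = 0.3,
    ci_boot: int = 200,
    seed: int = 0,
) -> DistanceProfile:
    """Mean signal density in distance bins from the centromere.

    For each of the two arms per chromosome, per-base signal is averaged
    in ``bin``-bp distance bins out to ``max_dist``; the profile is the
    per-bin mean across arms.  A degree-2 loess (span ``loess_span``) is
    fit over distance, with a 95% percentile CI from ``ci_boot``
    bootstrap resamples of the arms.  The genome-average per-base density
    is included as a reference level.
    """
    cen_mid = _cen_mapping(cens)
    n_bins = max_dist // bin
    arms = []
    for chrom, cm in cen_mid.items():
        if chrom not in t.values:
            continue
        l_arm, r_arm = _arm_bin_means(t.values[chrom], int(cm), bin, n_bins)
        arms.append(l_arm)
        arms.append(r_arm)
    if not arms:
        raise InvalidParameterError("no chromosomes shared between track and centromere table")
    mat = np.vstack(arms)  # (n_arms, n_bins)
    with warnings.catch_warnings():
        # bins beyond every arm's end are legitimately all-NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
    centers = (np.arange(n_bins) + 0.5) * bin
    fit = loess_fit(centers, mean, span=loess_span, degree=2, x_eval=centers)

    rng = np.random.default_rng(seed)
    n_arms = mat.shape[0]
    boots = np.empty((ci_boot, n_bins))
    with warnings.catch_warnings():
        # a resample may hold no finite arm for a terminal bin
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(ci_boot):
            pick = rng.integers(0, n_arms, size=n_arms)
            boots[b] = loess_fit(
                centers, np.nanmean(mat[pick], axis=0), span=loess_span, degree=2, x_eval=centers
            )
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5], axis=0)

    genome_avg = t.total() / sum(len(v) for v in t.values.values())
    return DistanceProfile(
        bin_start=np.arange(n_bins) * bin,
        bin_center=centers,
        mean=mean,
        loess=fit,
        ci_low=ci_low,
        ci_high=ci_high,
        genome_average=float(genome_avg),
        n_arms=n_arms,
    )


def recovery_distance(profile: DistanceProfile) -> float:
    """Distance at which the loess fit first reaches the genome average.

    Linear interpolation between the last bin below and the first bin at
    or above the genome-average line; NaN if the fit never crosses.
    """
    fit = profile.loess
    target = profile.genome_average
    above = fit >= target
    if above[0]:
        return float(profile.bin_center[0])
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return float("nan")
    i = idx[0]
    x0, x1 = profile.bin_center[i - 1], profile.bin_center[i]
    y0, y1 = fit[i - 1], fit[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))


def metaplot_median(
    t: SignalTrack,
    cens,
    halfwidth: int = 25_000,
    bin: int = 500,
) -> pd.DataFrame:
    """Median signal profile across centromere-anchored regions.

    Relative-position bins cover [-halfwidth, +halfwidth) around each
    centromere midpoint; the value per bin is the median across
    centromeres of the per-base mean in that bin.  Regions truncated by
    chromosome ends contribute only their existing bases.
    """
    cen_mid = _cen_mapping(cens)
    if not cen_mid:
        raise InvalidParameterError("need at least one centromere")
    offsets = np.arange(-halfwidth, halfwidth, bin)
    profiles = []
    for chrom, cm in cen_mid.items():
        if chrom not in t.values:
            continue
        arr = t.values[chrom]
        vals = np.full(len(offsets), np.nan)
        for k, off in enumerate(offsets):
            lo = max(cm + off, 0)
            hi = min(cm + off + bin, len(arr))
            if hi > lo:
                vals[k] = arr[lo:hi].mean()
        profiles.append(vals)
    if not profiles:
        raise InvalidParameterError("no chromosomes shared between track and centromere table")
    mat = np.vstack(profiles)
    return pd.DataFrame(
        {
            "offset_start": offsets,
            "offset_center": offsets + bin / 2.0,
            "median": np.nanmedian(mat, axis=0),
            "n_regions": np.isfinite(mat).sum(axis=0),
        }
    )
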