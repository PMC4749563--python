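"""Synthetic meiosis, tetrad, and sequencing-signal generators.

Everything downstream of raw data in this package can be exercised on
synthetic inputs produced here, with the statistical structure the
analyses assume:

* tetrad-class frequencies for a two-marker interval under a
  no-chromatid-interference crossover model at a given true map distance;
* SNP-dense four-spore genotypes carrying planted CO and NCO events whose
  rates are shaped by the two-zone centromere suppression model
  (DSB damping near the centromere; sister-biased repair within the
  broader pericentromere);
* hotspot-structured Spo11-oligo read counts (multinomial sampling of a
  planted intensity landscape); and
* pericentromere-enriched ChIP coverage.

All generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .events import EventCall, GenotypeMatrix, events_to_frame
from .fluor import TetradTypeCounts
from .genome import SuppressionModel, ToyGenome, dsb_suppression_factor
from .track import SignalTrack

__all__ = [
    "make_toy_genome",
    "simulate_interval_tetrads",
    "simulate_meiosis",
    "simulate_spo11_reads",
    "simulate_chip_coverage",
    "tetrad_class_probs_given_k",
    "tetrad_class_probs",
    "MeiosisProducts",
]

DEFAULT_N_CHROM = 16
DEFAULT_CHROM_LENGTH = 200_000
DEFAULT_HOTSPOT_RATE = 0.3  # hotspots per kb
DEFAULT_MARKER_SPACING = 500  # bp (hybrid-like SNP density)


# ---------------------------------------------------------------------------
# toy genome


def make_toy_genome(
    n_chrom: int = DEFAULT_N_CHROM,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    hotspot_rate: float = DEFAULT_HOTSPOT_RATE,
    marker_spacing: int = DEFAULT_MARKER_SPACING,
    seed: int = 0,
    hotspot_shape: float = 1.0,
) -> ToyGenome:
    """Build a reproducible toy genome.

    Centromere midpoints are placed uniformly at least 25 kb from either
    chromosome end (where the length allows).  Hotspots are a homogeneous
    Poisson point process at ``hotspot_rate`` per kb with gamma-distributed
    relative intensities (shape ``hotspot_shape``, mean 1; shape 1 gives
    exponential, heavy-tailed heats).  Markers sit on a regular grid of
    ``marker_spacing`` bp offset by half a spacing from the chromosome
    start.
    """
    if n_chrom < 1:
        raise InvalidParameterError(f"n_chrom must be >= 1, got {n_chrom}")
    if chrom_length < 50_000:
        raise InvalidParameterError(f"chrom_length must be >= 50000, got {chrom_length}")
    if marker_spacing < 1:
        raise InvalidParameterError(f"marker_spacing must be >= 1, got {marker_spacing}")
    if hotspot_rate < 0:
        raise InvalidParameterError(f"hotspot_rate must be >= 0, got {hotspot_rate}")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    lengths = {c: int(chrom_length) for c in names}

    margin = 25_000 if chrom_length >= 2 * 25_000 + 1 else chrom_length // 4
    cen_mid = {c: int(rng.integers(margin, chrom_length - margin)) for c in names}

    hs_rows = []
    for c in names:
        k = rng.poisson(hotspot_rate * chrom_length / 1000.0)
        pos = np.sort(rng.integers(0, chrom_length, size=k))
        intensity = rng.gamma(shape=hotspot_shape, scale=1.0 / hotspot_shape, size=k)
        for p, h in zip(pos, intensity):
            hs_rows.append((c, int(p), float(h)))
    hotspots = pd.DataFrame(hs_rows, columns=["chrom", "pos", "intensity"])

    mk_rows = []
    offset = marker_spacing // 2
    for c in names:
        grid = np.arange(offset, chrom_length, marker_spacing, dtype=np.int64)
        grid = grid[(grid > 0) & (grid < chrom_length)]
        for p in grid:
            mk_rows.append((c, int(p)))
    markers = pd.DataFrame(mk_rows, columns=["chrom", "pos"])

    return ToyGenome(
        chrom_names=names,
        chrom_lengths=lengths,
        cen_mid=cen_mid,
        hotspots=hotspots,
        markers=markers,
    )


# ---------------------------------------------------------------------------
# two-marker tetrad simulator

# Markov chain on the number of recombinant chromatids r in {0, 2, 4}
# for the distal marker.  Each crossover picks one of the four non-sister
# chromatid pairs uniformly and swaps their distal segments:
# from r=0 any pair makes both chromatids recombinant (-> r=2); from r=2
# the four pairs lead to r=0, 2, 2, 4 with equal probability; from r=4
# any swap reverts two chromatids (-> r=2).
_R_CHAIN = np.array(
    [
        [0.0, 1.0, 0.0],
        [0.25, 0.5, 0.25],
        [0.0, 1.0, 0.0],
    ]
)


def tetrad_class_probs_given_k(k: int) -> tuple[float, float, float]:
    """(P(PD), P(TT), P(NPD)) after exactly ``k`` crossovers.

    Exact aggregation of the uniform chromatid-pair process: r=0
    recombinant chromatids is PD, r=2 is TT, r=4 is NPD.
    """
    if k < 0:
        raise InvalidParameterError("crossover count must be >= 0")
    state = np.array([1.0, 0.0, 0.0])
    state = state @ np.linalg.matrix_power(_R_CHAIN, k)
    return float(state[0]), float(state[1]), float(state[2])


def tetrad_class_probs(d_cm: float) -> tuple[float, float, float]:
    """(P(PD), P(TT), P(NPD)) at true map distance ``d_cm``.

    Crossover count per bivalent is Poisson with mean 2*(d_cm/100)
    (map distance in Morgans is half the mean crossovers per bivalent);
    the k-conditional class probabilities are mixed over that law.
    """
    if d_cm < 0:
        raise InvalidParameterError(f"map distance must be >= 0, got {d_cm}")
    lam = 2.0 * d_cm / 100.0
    # Truncate the Poisson mixture where the tail is negligible.
    kmax = max(8, int(lam + 12.0 * np.sqrt(lam) + 12))
    probs = np.zeros(3)
    pk = np.exp(-lam)
    state = np.array([1.0, 0.0, 0.0])
    for k in range(kmax + 1):
        probs += pk * state
        state = state @ _R_CHAIN
        pk *= lam / (k + 1)
    return float(probs[0]), float(probs[1]), float(probs[2])


def simulate_interval_tetrads(d_cm: float, n_tetrads: int, seed: int = 0) -> TetradTypeCounts:
    """Simulate PD/NPD/TT counts for one interval at true distance ``d_cm``.

    Per tetrad the crossover count k is Poisson(2 * d_cm/100); each
    crossover involves one of the four non-sister chromatid pairs
    uniformly and independently (no chromatid interference).  The class
    is sampled from the exact k-conditional distribution, which is
    distributionally identical to replaying the chromatid choices.
    """
    if d_cm < 0:
        raise InvalidParameterError(f"map distance must be >= 0, got {d_cm}")
    if n_tetrads < 1:
        raise InvalidParameterError(f"n_tetrads must be >= 1, got {n_tetrads}")
    rng = np.random.default_rng(seed)
    lam = 2.0 * d_cm / 100.0
    ks = rng.poisson(lam, size=n_tetrads)
    pd_n = npd_n = tt_n = 0
    for k, count in zip(*np.unique(ks, return_counts=True)):
        p_pd, p_tt, p_npd = tetrad_class_probs_given_k(int(k))
        draw = rng.multinomial(int(count), [p_pd, p_tt, p_npd])
        pd_n += int(draw[0])
        tt_n += int(draw[1])
        npd_n += int(draw[2])
    return TetradTypeCounts(pd=pd_n, npd=npd_n, tt=tt_n, excluded=0)


def simulate_interval_tetrads_chromatid(d_cm: float, n_tetrads: int, seed: int = 0) -> TetradTypeCounts:
    """Explicit chromatid-level reference simulator (slow; used as oracle).

    Tracks the distal-marker allele of all four chromatids and swaps the
    chosen non-sister pair for every crossover.
    """
    if d_cm < 0:
        raise InvalidParameterError(f"map distance must be >= 0, got {d_cm}")
    rng = np.random.default_rng(seed)
    lam = 2.0 * d_cm / 100.0
    counts = {"PD": 0, "NPD": 0, "TT": 0}
    pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
    for _ in range(n_tetrads):
        distal = [0, 0, 1, 1]  # parental alleles; chromatids 0,1 = P1 homolog
        for _ in range(rng.poisson(lam)):
            i, j = pairs[rng.integers(4)]
            distal[i], distal[j] = distal[j], distal[i]
        r = (distal[0] != 0) + (distal[1] != 0) + (distal[2] != 1) + (distal[3] != 1)
        counts["PD" if r == 0 else ("TT" if r == 2 else "NPD")] += 1
    return TetradTypeCounts(pd=counts["PD"], npd=counts["NPD"], tt=counts["TT"])


# ---------------------------------------------------------------------------
# whole-genome meiosis simulator


@dataclass
class MeiosisProducts:
    """Genotype matrices plus the planted ground truth for caller validation."""

    genotypes: list[GenotypeMatrix]
    truth: pd.DataFrame  # columns: tetrad, type, chrom, start, end, midpoint, spores

    def truth_events(self, tetrad: int) -> list[EventCall]:
        sub = self.truth[self.truth["tetrad"] == tetrad]
        return [
            EventCall(
                type=row.type,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                midpoint=float(row.midpoint),
                spores=tuple(int(s) - 1 for s in str(row.spores).split(",")),
            )
            for row in sub.itertuples()
        ]


def simulate_meiosis(
    genome: ToyGenome,
    model: SuppressionModel,
    interhomolog_event_rate: float = 30.0,
    co_fraction: float = 0.65,
    nco_tract_mean: float = 2000.0,
    n_tetrads: int = 1,
    seed: int = 0,
    min_event_separation: int = 6000,
    na_rate: float = 0.0,
    flip_rate: float = 0.0,
) -> MeiosisProducts:
    """Simulate hybrid meioses with planted, centromere-modulated events.

    Candidate DSB positions are drawn from the hotspot intensities scaled
    by the DSB suppression factor f(x).  A DSB within ``co_halfwidth`` of
    the centromere is discarded (invisible sister repair) with probability
    ``sister_bias``.  Survivors become COs with probability
    ``co_fraction`` (reciprocal exchange between one chromatid of each
    homolog) or NCOs (one-sided conversion tract, geometric length with
    mean ``nco_tract_mean``, converting one chromatid to the opposite
    parental allele).

    Events are only planted where their affected region is strictly
    inside the marker-covered span and at least ``min_event_separation``
    bp from every other event on the same chromosome of the same tetrad;
    candidates violating this are discarded.  This keeps every planted
    event individually resolvable in the genotypes (the truth log is then
    an exact reference for the simplified event caller, which does not
    attempt to disentangle overlapping events).

    ``na_rate``/``flip_rate`` optionally inject uniform genotyping noise
    (per marker-call NA masking / allele flips); the truth log is not
    perturbed.
    """
    for name, val in (
        ("interhomolog_event_rate", interhomolog_event_rate),
        ("nco_tract_mean", nco_tract_mean),
    ):
        if val < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {val}")
    if not 0.0 <= co_fraction <= 1.0:
        raise InvalidParameterError(f"co_fraction must be in [0,1], got {co_fraction}")
    if len(genome.markers) == 0:
        raise InvalidParameterError("genome has no markers; genotypes would be empty")
    if n_tetrads < 1:
        raise InvalidParameterError(f"n_tetrads must be >= 1, got {n_tetrads}")

    rng = np.random.default_rng(seed)

    hs = genome.hotspots
    hs_chrom = hs["chrom"].to_numpy()
    hs_pos = hs["pos"].to_numpy(dtype=np.int64)
    cen = np.array([genome.cen_mid[str(c)] for c in hs_chrom], dtype=np.int64) if len(hs) else np.array([], dtype=np.int64)
    weights = hs["intensity"].to_numpy(dtype=float) * np.asarray(
        dsb_suppression_factor(hs_pos - cen, model), dtype=float
    ) if len(hs) else np.array([])
    total_w = weights.sum() if len(hs) else 0.0
    site_p = weights / total_w if total_w > 0 else None

    marker_pos = {c: genome.marker_positions(c) for c in genome.chrom_names}
    marker_chroms = [c for c in genome.chrom_names if len(marker_pos[c]) > 0]
    all_chrom = np.concatenate([np.full(len(marker_pos[c]), c, dtype=object) for c in marker_chroms])
    all_pos = np.concatenate([marker_pos[c] for c in marker_chroms])

    genotypes: list[GenotypeMatrix] = []
    truth_rows: list[dict] = []

    for tetrad in range(n_tetrads):
        # --- pass 1: draw candidate DSBs, thin by sister bias, enforce
        # resolvability (inside the marker span, min separation)
        accepted: dict[str, list[tuple[int, bool, int, int]]] = {c: [] for c in marker_chroms}
        regions: dict[str, list[tuple[int, int]]] = {c: [] for c in marker_chroms}
        n_dsb = rng.poisson(interhomolog_event_rate)
        if site_p is None and n_dsb > 0:
            n_dsb = 0  # no hotspots -> no DSBs
        for site in rng.choice(len(weights), size=n_dsb, p=site_p) if n_dsb else []:
            chrom = str(hs_chrom[site])
            if chrom not in accepted:
                continue
            p = int(hs_pos[site])
            pos = marker_pos[chrom]
            is_co = rng.random() < co_fraction
            if is_co:
                lo = hi = p
            else:
                tract = int(rng.geometric(1.0 / max(nco_tract_mean, 1.0)))
                if rng.random() < 0.5:
                    lo, hi = p, p + tract
                else:
                    lo, hi = p - tract, p
            if lo <= pos[0] or hi >= pos[-1]:
                continue
            # recorded midpoint (marker resolution): CO anchors at the
            # inter-marker interval containing the DSB, NCO at its tract span
            if is_co:
                at = int(np.searchsorted(pos, p, side="right"))
                mid = (pos[at - 1] + pos[at]) / 2.0
            else:
                in_tract = (pos >= lo) & (pos <= hi)
                if not in_tract.any():
                    continue  # conversion between markers: genetically silent
                t_idx = np.flatnonzero(in_tract)
                mid = (pos[t_idx[0]] + pos[t_idx[-1]]) / 2.0
            # sister-bias thinning, applied at marker resolution so the
            # visible-event zone boundary is exact
            if abs(mid - genome.cen_mid[chrom]) <= model.co_halfwidth and rng.random() < model.sister_bias:
                continue  # repaired from the sister: invisible in the spores
            if any(
                max(a - hi, lo - b, 0) < min_event_separation for a, b in regions[chrom]
            ):
                continue
            regions[chrom].append((lo, hi))
            accepted[chrom].append((p, is_co, lo, hi))

        # --- pass 2: replay events in positional order on the chromatids
        # (4, n_markers) alleles per chromosome; chromatids 0,1 = P1 homolog
        alleles = {
            c: np.repeat(np.array([[1], [1], [2], [2]], dtype=np.int8), len(marker_pos[c]), axis=1)
            for c in marker_chroms
        }
        for chrom, evts in accepted.items():
            pos = marker_pos[chrom]
            arr = alleles[chrom]
            for p, is_co, lo, hi in sorted(evts):
                if is_co:
                    # reciprocal exchange between one chromatid of each
                    # homolog: pick uniformly among chromatids carrying
                    # opposite local haplotypes (tracks homolog identity
                    # through preceding exchanges)
                    at = int(np.searchsorted(pos, p, side="right"))
                    local = arr[:, at]  # first marker distal to the exchange
                    p1_side = np.flatnonzero(local == 1)
                    p2_side = np.flatnonzero(local == 2)
                    i = int(rng.choice(p1_side))
                    j = int(rng.choice(p2_side))
                    distal = pos > p
                    tmp = arr[i, distal].copy()
                    arr[i, distal] = arr[j, distal]
                    arr[j, distal] = tmp
                    left = int(pos[at - 1])
                    right = int(pos[at])
                    truth_rows.append(
                        {
                            "tetrad": tetrad,
                            "type": "CO",
                            "chrom": chrom,
                            "start": left,
                            "end": right,
                            "midpoint": (left + right) / 2.0,
                            "spores": f"{min(i, j) + 1},{max(i, j) + 1}",
                            "source_pos": p,
                        }
                    )
                else:
                    in_tract = (pos >= lo) & (pos <= hi)
                    if not in_tract.any():
                        continue  # conversion between markers: genetically silent
                    s = int(rng.integers(4))
                    # flip to the opposite parental allele over the tract
                    # (local 2:2 is guaranteed by the separation constraint)
                    arr[s, in_tract] = np.where(arr[s, in_tract] == 1, 2, 1)
                    t_idx = np.flatnonzero(in_tract)
                    t_start = int(pos[t_idx[0]])
                    t_end = int(pos[t_idx[-1]])
                    truth_rows.append(
                        {
                            "tetrad": tetrad,
                            "type": "NCO",
                            "chrom": chrom,
                            "start": t_start,
                            "end": t_end,
                            "midpoint": (t_start + t_end) / 2.0,
                            "spores": str(s + 1),
                            "source_pos": p,
                        }
                    )

        calls = np.concatenate([alleles[c].T for c in marker_chroms], axis=0)
        if flip_rate > 0:
            flip = rng.random(calls.shape) < flip_rate
            calls = np.where(flip, np.where(calls == 1, 2, 1), calls).astype(np.int8)
        if na_rate > 0:
            calls = np.where(rng.random(calls.shape) < na_rate, 0, calls).astype(np.int8)
        genotypes.append(GenotypeMatrix(chrom=all_chrom.copy(), pos=all_pos.copy(), calls=calls))

    truth = pd.DataFrame(
        truth_rows,
        columns=["tetrad", "type", "chrom", "start", "end", "midpoint", "spores", "source_pos"],
    )
    return MeiosisProducts(genotypes=genotypes, truth=truth)


# ---------------------------------------------------------------------------
# sequencing-signal simulators


def _multinomial_track(
    genome: ToyGenome, intensity: dict[str, np.ndarray], total_reads: int, rng: np.random.Generator
) -> SignalTrack:
    """Sample exactly ``total_reads`` reads from a per-base intensity landscape."""
    chroms = genome.chrom_names
    flat = np.concatenate([intensity[c] for c in chroms])
    p = flat / flat.sum()
    draw = rng.multinomial(total_reads, p)
    values: dict[str, np.ndarray] = {}
    offset = 0
    for c in chroms:
        n = genome.chrom_lengths[c]
        values[c] = draw[offset : offset + n].astype(float)
        offset += n
    return SignalTrack(values=values, total_mapped=float(total_reads), units="counts")


def simulate_spo11_reads(
    genome: ToyGenome,
    model: SuppressionModel,
    suppression_on: bool = True,
    total_reads: int = 1_000_000,
    read_spread: float = 200.0,
    background: float = 0.2,
    seed: int = 0,
) -> SignalTrack:
    """Simulate a Spo11-oligo count track.

    The expected per-base intensity is a mixture of Gaussian hotspot
    kernels (sd ``read_spread`` bp, mass proportional to hotspot
    intensity) plus a uniform background carrying fraction ``background``
    of the pre-suppression expected reads.  With ``suppression_on`` the
    landscape is multiplied by the DSB suppression factor f(distance to
    centromere).  Reads are multinomially sampled so the track sums to
    exactly ``total_reads``.
    """
    if total_reads < 1:
        raise InvalidParameterError(f"total_reads must be >= 1, got {total_reads}")
    if not 0.0 <= background < 1.0:
        raise InvalidParameterError(f"background must be in [0,1), got {background}")
    if read_spread <= 0:
        raise InvalidParameterError(f"read_spread must be > 0, got {read_spread}")
    rng = np.random.default_rng(seed)
    hs = genome.hotspots
    total_heat = float(hs["intensity"].sum()) if len(hs) else 0.0
    if total_heat > 0:
        bg_per_base = background / (1.0 - background) * total_heat / genome.total_length
    else:
        bg_per_base = 1.0 / genome.total_length  # hotspot-free genome: flat landscape
    half = int(np.ceil(4 * read_spread))
    kernel_x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (kernel_x / read_spread) ** 2)
    kernel /= kernel.sum()

    intensity: dict[str, np.ndarray] = {}
    for c in genome.chrom_names:
        n = genome.chrom_lengths[c]
        arr = np.full(n, bg_per_base, dtype=float)
        sub = hs[hs["chrom"] == c]
        for p, h in zip(sub["pos"].to_numpy(dtype=np.int64), sub["intensity"].to_numpy(dtype=float)):
            lo = max(p - half, 0)
            hi = min(p + half + 1, n)
            arr[lo:hi] += h * kernel[lo - (p - half) : hi - (p - half)]
        if suppression_on:
            x = np.abs(np.arange(n, dtype=float) - genome.cen_mid[c])
            arr *= np.asarray(dsb_suppression_factor(x, model))
        intensity[c] = arr
    return _multinomial_track(genome, intensity, int(total_reads), rng)


def simulate_chip_coverage(
    genome: ToyGenome,
    enrichment: float = 4.0,
    halfwidth: float = 20_000.0,
    total_reads: int = 1_000_000,
    seed: int = 0,
) -> SignalTrack:
    """Simulate ChIP coverage with a flat pericentromeric enrichment block.

    The expected landscape is a uniform baseline multiplied by
    ``enrichment`` within +/- ``halfwidth`` of each centromere midpoint,
    multinomially sampled to exactly ``total_reads``.
    """
    if enrichment < 1.0:
        raise InvalidParameterError(f"enrichment must be >= 1, got {enrichment}")
    if halfwidth < 0:
        raise InvalidParameterError(f"halfwidth must be >= 0, got {halfwidth}")
    if total_reads < 1:
        raise InvalidParameterError(f"total_reads must be >= 1, got {total_reads}")
    rng = np.random.default_rng(seed)
    intensity: dict[str, np.ndarray] = {}
    for c in genome.chrom_names:
        n = genome.chrom_lengths[c]
        arr = np.ones(n, dtype=float)
        x = np.abs(np.arange(n, dtype=float) - genome.cen_mid[c])
        arr[x <= halfwidth] = enrichment
        intensity[c] = arr
    return _multinomial_track(genome, intensity, int(total_reads), rng)


def truth_to_frame(products: MeiosisProducts) -> pd.DataFrame:
    """Alias for the truth log table (kept for symmetry with events_to_frame)."""
    return products.truth.copy()
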