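"""CO/NCO event calling from four-spore genotype matrices.

Each hybrid meiosis yields four spores genotyped at a dense set of
heterozygous markers (alleles P1/P2, or NA for a failed call).  A
crossover appears as reciprocal allele switches on two spores in the same
inter-marker interval; a non-crossover (gene conversion) as an isolated
run of 3:1 (or 1:3) segregation bounded by 2:2 markers.  This is a
simplified caller: complex events (double COs with shared tracts,
chromatid-strand classes) are out of scope, and a conversion tract within
``merge_gap`` of a CO is absorbed into that CO, which then counts once.

Coordinates are 0-based half-open internally; human-facing TSV output is
1-based (see :mod:`pericentro.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    MalformedInputError,
    MissingAnnotationError,
)

__all__ = [
    "GenotypeMatrix",
    "EventCall",
    "MeiosisEventCounts",
    "EventSummary",
    "segregation_profile",
    "call_events",
    "classify_proximity",
    "summarize",
    "welch_ttest",
    "chisq_yates",
]

# Allele encoding: 0 = NA, 1 = P1, 2 = P2
NA, P1, P2 = 0, 1, 2
_ALLELE_STR = {NA: "NA", P1: "P1", P2: "P2"}
_ALLELE_CODE = {v: k for k, v in _ALLELE_STR.items()}


@dataclass
class GenotypeMatrix:
    """Markers x 4 spores for one meiosis.

    ``chrom``/``pos`` are parallel arrays (positions strictly increasing
    within a chromosome); ``calls`` is an (n_markers, 4) int8 array with
    the encoding 0=NA, 1=P1, 2=P2.
    """

    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[1] != 4:
            raise MalformedInputError("genotype matrix needs exactly 4 spore columns")
        if not (len(self.chrom) == len(self.pos) == len(self.calls)):
            raise MalformedInputError("chrom/pos/calls lengths differ")
        if not np.isin(self.calls, [NA, P1, P2]).all():
            raise MalformedInputError("allele codes must be in {0:NA, 1:P1, 2:P2}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise MalformedInputError(f"marker positions not strictly increasing on {c}")

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for s in range(4):
            df[f"spore{s + 1}"] = [_ALLELE_STR[int(a)] for a in self.calls[:, s]]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        cols = [f"spore{s + 1}" for s in range(4)]
        missing = [c for c in ["chrom", "pos", *cols] if c not in df.columns]
        if missing:
            raise MalformedInputError(f"genotype table missing columns {missing}")
        try:
            calls = np.array([[_ALLELE_CODE[str(v)] for v in df[c]] for c in cols], dtype=np.int8).T
        except KeyError as e:  # pragma: no cover - message detail
            raise MalformedInputError(f"unknown allele {e.args[0]!r} (expected P1/P2/NA)") from e
        return cls(chrom=df["chrom"].to_numpy(), pos=df["pos"].to_numpy(), calls=calls)


@dataclass(frozen=True)
class EventCall:
    """One CO or NCO; ``start``/``end`` bound the event's inter-marker span."""

    type: str  # "CO" | "NCO"
    chrom: str
    start: int
    end: int
    midpoint: float
    spores: tuple[int, ...]  # 0-based spore indices involved

    def __post_init__(self) -> None:
        if self.type not in ("CO", "NCO"):
            raise MalformedInputError(f"event type must be CO or NCO, got {self.type!r}")
        if not self.start <= self.midpoint <= self.end:
            raise MalformedInputError("event midpoint outside its span")


def events_to_frame(events: Sequence[EventCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "type": [e.type for e in events],
            "chrom": [e.chrom for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "midpoint": [e.midpoint for e in events],
            "spores": [",".join(str(s + 1) for s in e.spores) for e in events],
        }
    )


def segregation_profile(m: GenotypeMatrix) -> pd.Series:
    """Per-marker P1:P2 ratio class.

    Classes: ``2:2``, ``3:1``, ``1:3``, ``4:0``, ``0:4`` or ``NA`` (any
    spore uncalled; such markers are skipped downstream).
    """
    has_na = (m.calls == NA).any(axis=1)
    n_p1 = (m.calls == P1).sum(axis=1)
    labels = np.array([f"{k}:{4 - k}" for k in range(5)], dtype=object)
    out = labels[n_p1]
    out[has_na] = "NA"
    return pd.Series(out, name="seg_class")


@dataclass
class _ChromCalls:
    pos: np.ndarray  # informative marker positions
    calls: np.ndarray
    seg: np.ndarray  # seg class per informative marker


def _informative(m: GenotypeMatrix, chrom: str) -> _ChromCalls | None:
    mask = m.chrom == chrom
    seg = segregation_profile(m).to_numpy()[mask]
    pos = m.pos[mask]
    calls = m.calls[mask]
    keep = np.isin(seg, ["2:2", "3:1", "1:3"])  # NA and 4:0/0:4 are non-informative
    if keep.sum() < 2:
        return None
    return _ChromCalls(pos=pos[keep], calls=calls[keep], seg=seg[keep])


def call_events(
    m: GenotypeMatrix,
    min_tract_markers: int = 1,
    merge_gap: int = 5000,
) -> list[EventCall]:
    """Call CO and NCO events for one meiosis.

    Per chromosome: (1) find per-spore allele switches between adjacent
    informative markers; (2) an interval where exactly two spores switch
    in opposite directions, flanked by 2:2 markers, is a CO anchored at
    that interval; (3) a maximal run of >= ``min_tract_markers``
    consecutive 3:1/1:3 markers with the same converted spore, bounded on
    both sides by 2:2 markers, is an NCO spanning the run - unless it
    lies within ``merge_gap`` of a CO interval, in which case it is
    absorbed into that CO (CO-with-conversion counts once, as CO);
    (4) 4:0/0:4 markers are excluded from calling (QC-flagged upstream).

    For NCOs the reported spore is the minority-allele carrier: the
    actual conversion recipient cannot be identified from segregation
    alone (the converted chromatid joins the majority class).
    """
    events: list[EventCall] = []
    for chrom in m.chromosomes():
        cc = _informative(m, chrom)
        if cc is None:
            continue
        pos, calls, seg = cc.pos, cc.calls, cc.seg
        n = len(pos)

        # --- crossovers: reciprocal switches in one inter-marker interval
        diffs = calls[1:] != calls[:-1]  # (n-1, 4) switch indicators
        co_spans: list[list[int]] = []  # mutable [start, end]
        co_spores: list[tuple[int, int]] = []
        for i in range(n - 1):
            if seg[i] != "2:2" or seg[i + 1] != "2:2":
                continue
            switching = np.flatnonzero(diffs[i])
            if len(switching) != 2:
                continue
            s1, s2 = int(switching[0]), int(switching[1])
            d1 = int(calls[i + 1, s1]) - int(calls[i, s1])
            d2 = int(calls[i + 1, s2]) - int(calls[i, s2])
            if d1 == -d2 != 0:
                co_spans.append([int(pos[i]), int(pos[i + 1])])
                co_spores.append((s1, s2))

        # --- non-crossovers: isolated 3:1 / 1:3 tracts
        nco_runs: list[tuple[int, int, int]] = []  # (first_idx, last_idx, spore)
        i = 0
        while i < n:
            if seg[i] in ("3:1", "1:3"):
                minority = P2 if seg[i] == "3:1" else P1
                spore = int(np.flatnonzero(calls[i] == minority)[0])
                j = i
                while (
                    j + 1 < n
                    and seg[j + 1] == seg[i]
                    and calls[j + 1, spore] == minority
                ):
                    j += 1
                bounded = i > 0 and j < n - 1  # needs 2:2 markers on both flanks
                if bounded and (j - i + 1) >= min_tract_markers:
                    nco_runs.append((i, j, spore))
                i = j + 1
            else:
                i += 1

        # --- absorb CO-adjacent conversion tracts into the CO
        for first, last, spore in nco_runs:
            t_start, t_end = int(pos[first]), int(pos[last])
            absorbed = False
            for span in co_spans:
                gap = max(span[0] - t_end, t_start - span[1], 0)
                if gap <= merge_gap:
                    span[0] = min(span[0], t_start)
                    span[1] = max(span[1], t_end)
                    absorbed = True
                    break
            if not absorbed:
                events.append(
                    EventCall(
                        type="NCO",
                        chrom=chrom,
                        start=t_start,
                        end=t_end,
                        midpoint=(t_start + t_end) / 2.0,
                        spores=(spore,),
                    )
                )
        for span, spores in zip(co_spans, co_spores):
            events.append(
                EventCall(
                    type="CO",
                    chrom=chrom,
                    start=span[0],
                    end=span[1],
                    midpoint=(span[0] + span[1]) / 2.0,
                    spores=spores,
                )
            )
    events.sort(key=lambda e: (str(e.chrom), e.start, e.type))
    return events


@dataclass
class MeiosisEventCounts:
    co_count: int
    nco_count: int


@dataclass
class EventSummary:
    """Proximity classification of a set of events against centromeres."""

    per_chromosome: pd.DataFrame  # chrom, co_within, nco_within, co_total, nco_total, pct_within
    window: int
    co_within: int = 0
    nco_within: int = 0
    co_total: int = 0
    nco_total: int = 0

    @property
    def pct_within(self) -> float:
        """Pooled % of all events (CO+NCO) within the window; NaN if no events."""
        total = self.co_total + self.nco_total
        if total == 0:
            return float("nan")
        return 100.0 * (self.co_within + self.nco_within) / total


def _cen_mapping(cens) -> Mapping[str, int]:
    if isinstance(cens, Mapping):
        return cens
    if isinstance(cens, pd.DataFrame):
        if "cen_mid" in cens.columns:
            return dict(zip(cens["chrom"].astype(str), cens["cen_mid"].astype(int)))
        return dict(
            zip(cens["chrom"].astype(str), ((cens["start"] + cens["end"]) // 2).astype(int))
        )
    raise MalformedInputError("centromere table must be a mapping or DataFrame")


def classify_proximity(
    events: Sequence[EventCall], cens, window: int = 20_000
) -> EventSummary:
    """Count events within ``window`` bp of the centromere midpoint.

    An event is "within" iff |midpoint - cen_mid| <= window (boundary
    inclusive).  Per-chromosome percentages are computed as a fraction of
    the combined CO+NCO total on that chromosome (NaN when empty).
    """
    cen_mid = _cen_mapping(cens)
    rows: dict[str, dict[str, int]] = {}
    for e in events:
        c = str(e.chrom)
        if c not in cen_mid:
            raise MissingAnnotationError(f"no centromere annotation for chromosome {c}")
        row = rows.setdefault(c, {"co_within": 0, "nco_within": 0, "co_total": 0, "nco_total": 0})
        key = e.type.lower()
        row[f"{key}_total"] += 1
        if abs(e.midpoint - cen_mid[c]) <= window:
            row[f"{key}_within"] += 1
    records = []
    for c, row in sorted(rows.items()):
        total = row["co_total"] + row["nco_total"]
        pct = 100.0 * (row["co_within"] + row["nco_within"]) / total if total else float("nan")
        records.append({"chrom": c, **row, "pct_within": pct})
    per_chrom = pd.DataFrame(
        records,
        columns=["chrom", "co_within", "nco_within", "co_total", "nco_total", "pct_within"],
    )
    return EventSummary(
        per_chromosome=per_chrom,
        window=window,
        co_within=int(per_chrom["co_within"].sum()) if len(per_chrom) else 0,
        nco_within=int(per_chrom["nco_within"].sum()) if len(per_chrom) else 0,
        co_total=int(per_chrom["co_total"].sum()) if len(per_chrom) else 0,
        nco_total=int(per_chrom["nco_total"].sum()) if len(per_chrom) else 0,
    )


def summarize(meioses: Sequence[MeiosisEventCounts]) -> dict:
    """Mean and SD of CO and NCO counts per tetrad across meioses.

    SD is reported as 0.0 for a single meiosis (undefined with n=1).
    """
    if len(meioses) < 1:
        raise InsufficientDataError("need at least one meiosis")
    co = np.array([m.co_count for m in meioses], dtype=float)
    nco = np.array([m.nco_count for m in meioses], dtype=float)
    sd = lambda x: float(x.std(ddof=1)) if len(x) > 1 else 0.0  # noqa: E731
    return {
        "n_meioses": len(meioses),
        "co_mean": float(co.mean()),
        "co_sd": sd(co),
        "nco_mean": float(nco.mean()),
        "nco_sd": sd(nco),
    }


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed Welch t-test p-value between two strains' per-tetrad counts."""
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("Welch t-test needs >= 2 meioses per strain")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def chisq_yates(table) -> tuple[float, float]:
    """Chi-square test with Yates continuity correction on a 2x2 table.

    statistic = sum((max(|O - E| - 0.5, 0))^2 / E) with E from the
    margins; p-value from the chi-square law with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise MalformedInputError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise MalformedInputError("table counts must be >= 0")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("2x2 table has a zero margin")
    expected = np.outer(row, col) / obs.sum()
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float((corrected**2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p
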