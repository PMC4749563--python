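"""Readers and writers for the plain-text formats the pipeline consumes.

bedGraph and BED use 0-based half-open coordinates.  Genotype matrices,
tetrad-count tables and truth logs are TSV.  Readers validate rather than
silently coerce; writers round-trip (sums and values are preserved
exactly).  The human-facing events TSV is 1-based inclusive and says so
in its header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .events import EventCall, GenotypeMatrix, events_to_frame
from .fluor import TetradTypeCounts
from .track import SignalTrack

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "centromere_table",
    "read_genotypes",
    "write_genotypes",
    "read_tetrad_counts",
    "write_tetrad_counts",
    "read_events",
    "write_events",
    "read_fluor_table",
]


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None, total_mapped: float | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a per-base SignalTrack.

    Intervals are 0-based half-open and must not overlap.  Array lengths
    come from ``chrom_sizes`` when given, else from the largest end seen
    per chromosome.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise MalformedInputError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as e:
                raise MalformedInputError(f"{path}:{lineno}: {e}") from e
            if start < 0 or end <= start:
                raise MalformedInputError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if value < 0:
                raise MalformedInputError(f"{path}:{lineno}: negative value {value}")
            intervals.setdefault(chrom, []).append((start, end, value))
    values: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise MalformedInputError(f"{path}: overlapping intervals on {chrom} at {s2} < {e1}")
        length = chrom_sizes[chrom] if chrom_sizes else ivs[-1][1]
        arr = np.zeros(length, dtype=float)
        for s, e, v in ivs:
            arr[s:e] = v
        values[chrom] = arr
    if chrom_sizes:
        for chrom, length in chrom_sizes.items():
            values.setdefault(chrom, np.zeros(length, dtype=float))
    return SignalTrack(values=values, total_mapped=total_mapped)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write non-zero runs of a track as 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.values[chrom]
            if not len(arr):
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> pd.DataFrame:
    """Read a >=3-column BED (0-based half-open); returns sorted intervals."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise MalformedInputError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise MalformedInputError(f"{path}:{lineno}: {e}") from e
            if start < 0:
                raise MalformedInputError(f"{path}:{lineno}: negative coordinate {start}")
            if start >= end:
                raise MalformedInputError(f"{path}:{lineno}: start {start} >= end {end}")
            rows.append({"chrom": parts[0], "start": start, "end": end, "name": parts[3] if len(parts) > 3 else ""})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns and df["name"].astype(str).str.len().any() else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def centromere_table(bed: pd.DataFrame) -> pd.DataFrame:
    """Derive centromere midpoints (floor of the interval midpoint) from BED rows."""
    out = bed.copy()
    out["cen_mid"] = (out["start"] + out["end"]) // 2
    return out[["chrom", "cen_mid"]]


# ---------------------------------------------------------------------------
# genotype matrices / tetrad counts / events


def write_genotypes(m: GenotypeMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    # keep_default_na: the literal string "NA" is a genotype code here
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    return GenotypeMatrix.from_frame(df)


def write_tetrad_counts(counts: TetradTypeCounts, path, **extra) -> None:
    pd.DataFrame(
        [{"pd": counts.pd, "npd": counts.npd, "tt": counts.tt, "excluded": counts.excluded, **extra}]
    ).to_csv(path, sep="\t", index=False)


def read_tetrad_counts(path) -> TetradTypeCounts:
    df = pd.read_csv(path, sep="\t")
    for col in ("pd", "npd", "tt"):
        if col not in df.columns:
            raise MalformedInputError(f"{path}: missing column {col!r}")
    row = df.iloc[0]
    return TetradTypeCounts(
        pd=int(row["pd"]),
        npd=int(row["npd"]),
        tt=int(row["tt"]),
        excluded=int(row["excluded"]) if "excluded" in df.columns else 0,
    )


def write_events(events: Sequence[EventCall], path, tetrad: int | None = None) -> None:
    """Write events as TSV with 1-based inclusive coordinates (human-facing)."""
    df = events_to_frame(events)
    df["start"] = df["start"] + 1  # 1-based inclusive for human readability
    if tetrad is not None:
        df.insert(0, "tetrad", tetrad)
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive\n")
        df.to_csv(fh, sep="\t", index=False)


def read_events(path) -> list[EventCall]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for row in df.itertuples():
        out.append(
            EventCall(
                type=row.type,
                chrom=row.chrom,
                start=int(row.start) - 1,
                end=int(row.end),
                midpoint=float(row.midpoint),
                spores=tuple(int(s) - 1 for s in str(row.spores).split(",")),
            )
        )
    return out


def read_fluor_table(path) -> dict[str, list[tuple[bool, bool, bool]]]:
    """Read a fluorescent-tetrad score TSV: tetrad_id, spore, gfp, rfp, cfp (0/1).

    Returns tetrad_id -> list of four (gfp, rfp, cfp) tuples in spore order.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"tetrad_id", "spore", "gfp", "rfp", "cfp"}
    if not required.issubset(df.columns):
        raise MalformedInputError(f"{path}: needs columns {sorted(required)}")
    for col in ("gfp", "rfp", "cfp"):
        if not df[col].isin([0, 1]).all():
            raise MalformedInputError(f"{path}: column {col!r} must be 0/1")
    out: dict[str, list[tuple[bool, bool, bool]]] = {}
    for tid, sub in df.groupby("tetrad_id", sort=False):
        sub = sub.sort_values("spore")
        if len(sub) != 4:
            raise MalformedInputError(f"{path}: tetrad {tid} has {len(sub)} spores (need 4)")
        out[str(tid)] = [
            (bool(r.gfp), bool(r.rfp), bool(r.cfp)) for r in sub.itertuples()
        ]
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
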