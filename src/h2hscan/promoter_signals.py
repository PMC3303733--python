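"""Bidirectional-promoter features: TATA boxes, bendability, accessibility.

The bidirectional promoter of an h2h pair is the intergenic region between the
two genes — by default between the coding regions, optionally between the two
TSSs.  Three features are computed over it:

* TATA class: a promoter is TATA-containing when at least one TATA-box
  interval intersects the region (partial overlap counts).
* DNA bendability: a per-base track derived from a 64-entry tri-nucleotide
  propensity table, averaging the propensities of the (up to three) windows
  covering each base.  Windows containing N are invalid; a base covered by no
  valid window is undefined (NaN).
* Accessibility: a promoter is "more accessible" when it contains at least one
  run of ``min_len`` (default 8, near the typical transcription-factor
  binding-site size) consecutive bases whose bendability AND nucleosome
  occupancy are both strictly below their genome-wide averages — a stretch of
  rigid, nucleosome-depleted DNA long enough for a TF to bind.

Tracks are double-strand properties: strand is ignored, and the propensity
table is applied to the plus-strand sequence.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .genome_pairs import AdjacentPair, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_RUN = 8

ALL_TRIPLETS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter interval (1-based, closed); empty when start > end."""

    left_gene: str
    right_gene: str
    chrom: str
    start: int
    end: int
    source: str

    @property
    def is_empty(self) -> bool:
        return self.start > self.end

    @property
    def length(self) -> int:
        return 0 if self.is_empty else self.end - self.start + 1


@dataclass(frozen=True)
class TataBox:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"TATA box {self.chrom}:{self.start}-{self.end} has start > end")


@dataclass
class GenomeTrack:
    """Per-base signal per chromosome; NaN marks undefined bases."""

    kind: str
    data: dict[str, np.ndarray]


def bidirectional_promoter_region(
    pair: AdjacentPair,
    genes: Mapping[str, GeneModel],
    source: str = "between_cds",
) -> PromoterRegion:
    """The intergenic gap of an h2h pair, between CDSs or between TSSs."""
    if pair.pair_class != "h2h":
        raise ValueError(
            f"pair ({pair.left_gene}, {pair.right_gene}) is {pair.pair_class}, not h2h"
        )
    left, right = genes[pair.left_gene], genes[pair.right_gene]
    if source == "between_cds":
        start, end = left.cds_end + 1, right.cds_start - 1
    elif source == "between_tss":
        if left.tss is None or right.tss is None:
            raise ValueError(
                f"pair ({pair.left_gene}, {pair.right_gene}): TSS missing, "
                "cannot form a between_tss promoter region"
            )
        lo, hi = sorted((left.tss, right.tss))
        start, end = lo + 1, hi - 1
    else:
        raise ValueError(f"unknown promoter source {source!r}")
    return PromoterRegion(pair.left_gene, pair.right_gene, pair.chrom, start, end, source)


def classify_tata(region: PromoterRegion, boxes: Iterable[TataBox]) -> str:
    """``tata_containing`` iff any box interval intersects the (closed) region."""
    if region.is_empty:
        return "tata_less"
    for box in boxes:
        if box.chrom == region.chrom and box.start <= region.end and box.end >= region.start:
            return "tata_containing"
    return "tata_less"


# ---------------------------------------------------------------------------
# Bendability


def read_propensity_table(path: str | Path) -> dict[str, float]:
    """Read a (triplet, value) TSV; all 64 tri-nucleotides must be present."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if str(df.iloc[0, 0]).lower() in ("triplet", "trinucleotide"):
        df = df.iloc[1:]
    table = {str(t).upper(): float(v) for t, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return validate_propensity_table(table)


def validate_propensity_table(table: Mapping[str, float]) -> dict[str, float]:
    missing = [t for t in ALL_TRIPLETS if t not in table]
    if missing:
        raise InputFormatError(
            f"propensity table is missing {len(missing)} tri-nucleotides "
            f"(first: {missing[:3]})"
        )
    return {t: float(table[t]) for t in ALL_TRIPLETS}


_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def bendability_track(sequence: str, table: Mapping[str, float]) -> np.ndarray:
    """Per-base bendability of a DNA string; NaN where no valid window covers.

    Each tri-nucleotide window contributes its table value to its three bases;
    a base's value is the mean over its valid covering windows (up to 3).
    """
    table = validate_propensity_table(table)
    L = len(sequence)
    if L == 0:
        return np.empty(0, dtype=float)
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if L < 3:
        return np.full(L, np.nan)
    c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0)
    values = np.array([table[t] for t in ALL_TRIPLETS], dtype=float)
    idx = np.where(valid, c0 * 16 + c1 * 4 + c2, 0)
    win = np.where(valid, values[idx], np.nan)
    # stack the three window layers shifted so layer s covers bases j..j+2
    layers = np.full((3, L), np.nan)
    for s in range(3):
        layers[s, s : s + win.size] = win
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN columns
        return np.nanmean(layers, axis=0)


def genome_mean(track: GenomeTrack | Mapping[str, np.ndarray]) -> float:
    """Pooled mean over all defined bases of all chromosomes."""
    data = track.data if isinstance(track, GenomeTrack) else track
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in data.values()])
    if pooled.size == 0 or np.isnan(pooled).all():
        raise ValueError("track has no defined values")
    return float(np.nanmean(pooled))


# ---------------------------------------------------------------------------
# Accessibility


def accessible_segments(
    region: PromoterRegion,
    bend: GenomeTrack | Mapping[str, np.ndarray],
    occ: GenomeTrack | Mapping[str, np.ndarray],
    bend_avg: float,
    occ_avg: float,
    min_len: int = DEFAULT_MIN_RUN,
) -> list[tuple[int, int]]:
    """Maximal runs ≥ min_len where both signals are strictly below average.

    Returns 1-based closed genomic intervals.  NaN track values fail the
    predicate.  A region extending past the track bounds is a hard error.
    """
    if region.is_empty:
        return []
    bdata = bend.data if isinstance(bend, GenomeTrack) else bend
    odata = occ.data if isinstance(occ, GenomeTrack) else occ
    if region.chrom not in bdata or region.chrom not in odata:
        raise ValueError(f"region chromosome {region.chrom!r} missing from tracks")
    b = np.asarray(bdata[region.chrom], dtype=float)
    o = np.asarray(odata[region.chrom], dtype=float)
    if region.start < 1 or region.end > min(b.size, o.size):
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} outside track bounds"
        )
    bs = b[region.start - 1 : region.end]
    os_ = o[region.start - 1 : region.end]
    with np.errstate(invalid="ignore"):
        mask = (bs < bend_avg) & (os_ < occ_avg)
    segments: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, ok in enumerate(np.append(mask, False)):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start >= min_len:
                segments.append((region.start + run_start, region.start + i - 1))
            run_start = None
    return segments


def longest_joint_run(
    region: PromoterRegion,
    bend: GenomeTrack | Mapping[str, np.ndarray],
    occ: GenomeTrack | Mapping[str, np.ndarray],
    bend_avg: float,
    occ_avg: float,
) -> int:
    """Length of the longest jointly-below-average run in the region."""
    segs = accessible_segments(region, bend, occ, bend_avg, occ_avg, min_len=1)
    return max((e - s + 1 for s, e in segs), default=0)


def classify_accessibility(
    region: PromoterRegion,
    bend: GenomeTrack | Mapping[str, np.ndarray],
    occ: GenomeTrack | Mapping[str, np.ndarray],
    bend_avg: float,
    occ_avg: float,
    min_len: int = DEFAULT_MIN_RUN,
) -> str:
    """``more_accessible`` iff the promoter holds ≥1 qualifying run."""
    if region.is_empty:
        logger.info(
            "empty promoter region for pair (%s, %s): less_accessible",
            region.left_gene, region.right_gene,
        )
        return "less_accessible"
    segs = accessible_segments(region, bend, occ, bend_avg, occ_avg, min_len)
    return "more_accessible" if segs else "less_accessible"


# ---------------------------------------------------------------------------
# Track / interval IO


def read_tata_bed(path: str | Path) -> list[TataBox]:
    """Read TATA boxes from BED (0-based half-open → 1-based closed)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    boxes = []
    for chrom, start, end in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        boxes.append(TataBox(str(chrom), int(start) + 1, int(end)))
    return boxes


def write_tata_bed(boxes: Sequence[TataBox], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\n")


def read_track_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int], kind: str
) -> GenomeTrack:
    """Read a bedGraph (chrom, start0, end, value) into dense per-base arrays.

    Bases not covered by any interval stay NaN (undefined).
    """
    data = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": int, "end": int, "value": float})
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in data:
            raise InputFormatError(f"{path}: unknown chromosome {chrom!r}")
        arr = data[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            if s < 0 or e > arr.size:
                raise InputFormatError(f"{path}: interval {chrom}:{s}-{e} outside chromosome")
            arr[s:e] = v
    return GenomeTrack(kind, data)


def write_track_bedgraph(track: GenomeTrack, path: str | Path) -> None:
    """Write dense tracks as bedGraph, merging runs of identical values."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = np.asarray(track.data[chrom], dtype=float)
            if arr.size == 0:
                continue
            run_start = 0
            for i in range(1, arr.size + 1):
                boundary = i == arr.size or not (
                    arr[i] == arr[run_start]
                    or (np.isnan(arr[i]) and np.isnan(arr[run_start]))
                )
                if boundary:
                    if not np.isnan(arr[run_start]):
                        fh.write(f"{chrom}\t{run_start}\t{i}\t{float(arr[run_start])!r}\n")
                    run_start = i
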