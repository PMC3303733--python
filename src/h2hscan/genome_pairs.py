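"""Adjacent gene-pair formation and orientation classification.

Two genes that are neighbors on a chromosome fall into one of three
organizations depending on their strands: head-to-head (h2h) pairs transcribe
divergently away from a shared intergenic region (the bidirectional promoter),
head-to-tail (h2t) pairs sit on the same strand, and tail-to-tail (t2t) pairs
transcribe convergently.  This module reads gene annotations, forms the
consecutive pairs per chromosome, drops pairs whose coding regions overlap,
classifies the survivors, and measures the intergenic distances between coding
regions (CR distance) and between transcription start sites (TSS distance).

All coordinates are 1-based closed intervals, the GFF3 convention.  Both
distances count the bases *strictly between* the two features, so touching
features are at distance 0.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError

logger = logging.getLogger(__name__)

PAIR_CLASSES = ("h2h", "h2t", "t2t")

_TSV_COLUMNS = ("gene_id", "chrom", "strand", "cds_start", "cds_end")


@dataclass(frozen=True)
class GeneModel:
    """One gene: coding-region coordinates plus optional transcript boundaries.

    ``tss`` lies upstream of the coding region: at or before ``cds_start`` on
    the plus strand, at or after ``cds_end`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    tss: int | None = None
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.cds_start > self.cds_end:
            raise ValueError(
                f"gene {self.gene_id!r}: cds_start {self.cds_start} > cds_end {self.cds_end}"
            )
        if self.tss is not None:
            if self.strand == "+" and self.tss > self.cds_start:
                raise ValueError(
                    f"gene {self.gene_id!r}: plus-strand TSS {self.tss} downstream of CDS start"
                )
            if self.strand == "-" and self.tss < self.cds_end:
                raise ValueError(
                    f"gene {self.gene_id!r}: minus-strand TSS {self.tss} upstream of CDS end"
                )


@dataclass(frozen=True)
class AdjacentPair:
    """A classified, non-overlapping neighbor pair (left precedes right)."""

    left_gene: str
    right_gene: str
    chrom: str
    pair_class: str
    cr_distance: int
    tss_distance: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.left_gene, self.right_gene)


# ---------------------------------------------------------------------------
# Readers


def read_gene_annotations(path: str | Path, fmt: str = "tsv") -> list[GeneModel]:
    """Read gene records from a TSV or GFF3 file.

    TSV columns: gene_id, chrom, strand, cds_start, cds_end, optionally tss
    (whitespace- or tab-separated; a header line starting with ``gene_id`` is
    allowed).  GFF3 files are read through :mod:`gffutils`, taking features of
    type ``gene``.

    Records with ``cds_start > cds_end`` are skipped with a warning; a strand
    other than '+'/'-' is a hard error naming the offending record.
    """
    path = Path(path)
    if fmt == "tsv":
        return _read_tsv_genes(path)
    if fmt == "gff3":
        return _read_gff3_genes(path)
    raise InputFormatError(f"unknown annotation format {fmt!r} (expected 'tsv' or 'gff3')")


def _read_tsv_genes(path: Path) -> list[GeneModel]:
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        return []
    if str(df.iloc[0, 0]).lower() == "gene_id":
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 5:
        raise InputFormatError(f"{path}: expected at least 5 columns, got {df.shape[1]}")
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        gene_id, chrom, strand = str(row[0]), str(row[1]), str(row[2])
        if strand not in ("+", "-"):
            raise InputFormatError(f"{path}: gene {gene_id!r} has unknown strand {strand!r}")
        try:
            start, end = int(row[3]), int(row[4])
        except (TypeError, ValueError) as exc:
            raise InputFormatError(f"{path}: gene {gene_id!r} has non-integer coordinates") from exc
        if start > end:
            logger.warning("skipping gene %s: cds_start %d > cds_end %d", gene_id, start, end)
            continue
        tss = None
        if len(row) > 5 and pd.notna(row[5]) and str(row[5]) not in (".", ""):
            tss = int(row[5])
        genes.append(GeneModel(gene_id, chrom, strand, start, end, tss=tss))
    return genes


def _read_gff3_genes(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.strand not in ("+", "-"):
            raise InputFormatError(
                f"{path}: gene {gene_id!r} ({feat.seqid}:{feat.start}-{feat.end}) "
                f"has unknown strand {feat.strand!r}"
            )
        if feat.start > feat.end:
            logger.warning("skipping gene %s: start %d > end %d", gene_id, feat.start, feat.end)
            continue
        tss = None
        if "tss" in feat.attributes:
            tss = int(feat.attributes["tss"][0])
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, feat.start, feat.end, tss=tss))
    return genes


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a transcript-boundary table (gene_id, tss[, utr...]) as strings."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "tss" not in df.columns:
        raise InputFormatError(f"{path}: TSS table needs 'gene_id' and 'tss' columns")
    return df


def apply_tss_table(genes: Sequence[GeneModel], table: pd.DataFrame) -> list[GeneModel]:
    """Attach TSSs (and UTRs when present) from a transcript-boundary table.

    Genes absent from the table keep ``tss=None``.  A TSS that violates the
    upstream-of-CDS invariant is dropped with a warning rather than aborting
    the run, since transcript and CDS annotations come from different sources.
    """
    by_gene = {str(r["gene_id"]): r for _, r in table.iterrows()}
    out: list[GeneModel] = []
    for g in genes:
        row = by_gene.get(g.gene_id)
        if row is None or pd.isna(row["tss"]) or str(row["tss"]) in (".", ""):
            out.append(g)
            continue
        try:
            out.append(replace(g, tss=int(row["tss"])))
        except ValueError as exc:
            logger.warning("ignoring TSS for gene %s: %s", g.gene_id, exc)
            out.append(g)
    return out


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) table into a dict."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if str(df.iloc[0, 0]).lower() in ("chrom", "chr"):
        df = df.iloc[1:]
    return {str(c): int(l) for c, l in zip(df.iloc[:, 0], df.iloc[:, 1])}


# ---------------------------------------------------------------------------
# Pair formation and classification


def form_adjacent_pairs(genes: Iterable[GeneModel]) -> list[tuple[GeneModel, GeneModel]]:
    """Form candidate neighbor pairs: consecutive genes per chromosome.

    Genes are sorted by (cds_start, cds_end, gene_id) within each chromosome,
    so the result is independent of input order; a chromosome with n genes
    yields n−1 candidates.  Exact coordinate ties are broken by gene_id and
    logged.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    pairs: list[tuple[GeneModel, GeneModel]] = []
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.cds_start, g.cds_end, g.gene_id))
        for a, b in zip(chrom_genes, chrom_genes[1:]):
            if (a.cds_start, a.cds_end) == (b.cds_start, b.cds_end):
                logger.info(
                    "coordinate tie on %s at %d-%d broken by gene_id (%s, %s)",
                    chrom, a.cds_start, a.cds_end, a.gene_id, b.gene_id,
                )
            pairs.append((a, b))
    return pairs


def filter_overlapping(
    candidates: Sequence[tuple[GeneModel, GeneModel]],
) -> list[tuple[GeneModel, GeneModel]]:
    """Drop candidate pairs whose closed coding intervals intersect.

    Touching-but-not-overlapping neighbors (left end + 1 == right start) are
    retained; they have CR distance 0.
    """
    kept = [(a, b) for a, b in candidates if a.cds_end < b.cds_start]
    n_dropped = len(candidates) - len(kept)
    if n_dropped:
        logger.info("excluded %d candidate pairs with overlapping coding regions", n_dropped)
    return kept


def classify_pair(left: GeneModel, right: GeneModel) -> str:
    """Orientation class of a non-overlapping neighbor pair.

    (−,+) diverges → h2h; same strand → h2t; (+,−) converges → t2t.
    """
    if left.strand == right.strand:
        return "h2t"
    return "h2h" if left.strand == "-" else "t2t"


def cr_distance(left: GeneModel, right: GeneModel) -> int:
    """Bases strictly between the two coding regions (0 when touching)."""
    d = right.cds_start - left.cds_end - 1
    if d < 0:
        raise ValueError(
            f"pair ({left.gene_id}, {right.gene_id}): coding regions overlap "
            f"(distance {d}); overlapping pairs must be filtered first"
        )
    return d


def tss_distance(left: GeneModel, right: GeneModel) -> int | None:
    """Bases strictly between the two TSSs of an h2h pair, floored at 0.

    ``None`` when either TSS is unknown.  Interleaved transcript starts
    (coincident or crossing TSSs) legitimately give 0.  Calling this on a
    non-h2h pair is a hard error: TSS distance of same-strand or convergent
    pairs depends on coding-region length and is not comparable.
    """
    if classify_pair(left, right) != "h2h":
        raise ValueError(
            f"TSS distance is defined for h2h pairs only "
            f"({left.gene_id}, {right.gene_id} is {classify_pair(left, right)})"
        )
    if left.tss is None or right.tss is None:
        return None
    return max(abs(right.tss - left.tss) - 1, 0)


def adjacent_pairs(genes: Iterable[GeneModel]) -> list[AdjacentPair]:
    """Full pipeline: form candidates, filter overlaps, classify, measure.

    Returns the retained pairs with CR distance always set and TSS distance
    set for h2h pairs whose both TSSs are known.
    """
    genes = list(genes)
    candidates = form_adjacent_pairs(genes)
    kept = filter_overlapping(candidates)
    logger.info(
        "%d genes -> %d candidate pairs -> %d non-overlapping pairs",
        len(genes), len(candidates), len(kept),
    )
    out: list[AdjacentPair] = []
    for a, b in kept:
        cls = classify_pair(a, b)
        tssd = tss_distance(a, b) if cls == "h2h" else None
        out.append(AdjacentPair(a.gene_id, b.gene_id, a.chrom, cls, cr_distance(a, b), tssd))
    return out


# ---------------------------------------------------------------------------
# Summaries


def chromosome_summary(
    genes: Iterable[GeneModel],
    pairs: Iterable[AdjacentPair],
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-chromosome gene/pair tallies plus an ``overall`` row.

    Density is genes per 10 kbp.  Class percentages are of that chromosome's
    retained pairs and are NaN for chromosomes without pairs.  A chromosome
    present in the gene set but absent from ``chrom_lengths`` is a hard error.
    """
    genes = list(genes)
    pairs = list(pairs)
    chroms = sorted({g.chrom for g in genes})
    missing = [c for c in chroms if c not in chrom_lengths]
    if missing:
        raise ValueError(f"chromosomes missing from length table: {missing}")

    rows = []
    for chrom in chroms:
        n_genes = sum(g.chrom == chrom for g in genes)
        cpairs = [p for p in pairs if p.chrom == chrom]
        rows.append(_summary_row(chrom, chrom_lengths[chrom], n_genes, cpairs))
    total_len = sum(chrom_lengths[c] for c in chroms)
    rows.append(_summary_row("overall", total_len, len(genes), pairs))
    return pd.DataFrame(rows)


def _summary_row(chrom: str, length_bp: int, n_genes: int, pairs: list[AdjacentPair]) -> dict:
    counts = {cls: sum(p.pair_class == cls for p in pairs) for cls in PAIR_CLASSES}
    n_pairs = len(pairs)
    row = {
        "chrom": chrom,
        "length_bp": length_bp,
        "n_genes": n_genes,
        "density": n_genes / (length_bp / 10_000) if length_bp else np.nan,
        "n_pairs": n_pairs,
        "n_h2h": counts["h2h"],
        "n_h2t": counts["h2t"],
        "n_t2t": counts["t2t"],
    }
    for cls in PAIR_CLASSES:
        row[f"pct_{cls}"] = 100.0 * counts[cls] / n_pairs if n_pairs else np.nan
    return row


@dataclass
class DistanceHistogram:
    """Fixed-width distance histogram with an overflow tally.

    Fractions are over the *full* value count (overflow included), so the
    shown bins sum to ≤ 1.
    """

    bin_width: int
    max_value: int
    counts: np.ndarray
    n_total: int
    n_overflow: int

    @property
    def fractions(self) -> np.ndarray:
        if self.n_total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_total

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(0, self.max_value, self.bin_width)
        return pd.DataFrame(
            {
                "bin_start": starts,
                "bin_end": starts + self.bin_width,
                "count": self.counts,
                "fraction": self.fractions,
            }
        )


def bin_distances(
    values: Iterable[int], bin_width: int = 200, max_value: int = 3000
) -> DistanceHistogram:
    """Bin distances into half-open bins [0,w), [w,2w), …, [max−w, max).

    Values ≥ ``max_value`` are counted only in the overflow tally; negative
    values are a hard error.
    """
    vals = np.asarray(list(values), dtype=float)
    n_bins = max_value // bin_width
    if vals.size == 0:
        return DistanceHistogram(bin_width, max_value, np.zeros(n_bins, dtype=int), 0, 0)
    if (vals < 0).any():
        raise ValueError("negative distance passed to bin_distances")
    counts, _ = np.histogram(vals, bins=np.arange(0, max_value + bin_width, bin_width))
    # np.histogram closes the last bin on the right; re-apply the half-open rule.
    counts[-1] = ((vals >= max_value - bin_width) & (vals < max_value)).sum()
    n_overflow = int((vals >= max_value).sum())
    return DistanceHistogram(bin_width, max_value, counts.astype(int), int(vals.size), n_overflow)
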