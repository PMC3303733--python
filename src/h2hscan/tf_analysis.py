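"""Stratification of pair association by shared transcription factors.

Evidence records come from curated resources and are of two kinds: *binding*
(band-shift, footprinting, ChIP — the TF binds the gene's promoter) and
*regulation* (knockout assays — losing the TF changes the gene's expression).
A TF is "common" to a pair when it has evidence of the requested kind for both
genes; mode ``either`` unions the two evidence kinds per gene before
intersecting.

Two analyses are built on this:

* bucketing pairs by their number of common TFs and testing whether bucket
  mean association rises with the count (a trend Pearson correlation over
  bucket ordinals);
* per-TF group statistics over h2h pairs whose common set contains the TF:
  the e-score (mean co-expression) and f-score (mean functional similarity),
  the fraction of group pairs with a protein-protein interaction, and the
  fraction of the TF's targets that are h2h genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association_metrics import AssociationScores, pearson
from .errors import InputFormatError
from .genome_pairs import AdjacentPair

logger = logging.getLogger(__name__)

EVIDENCE_KINDS = ("binding", "regulation")
EVIDENCE_MODES = EVIDENCE_KINDS + ("either",)


class EvidenceIndex:
    """Deduplicated TF→gene evidence, indexed both ways."""

    def __init__(self, records: pd.DataFrame) -> None:
        required = {"tf_id", "gene_id", "evidence"}
        if not required.issubset(records.columns):
            raise InputFormatError(f"evidence table needs columns {sorted(required)}")
        bad = set(records["evidence"]) - set(EVIDENCE_KINDS)
        if bad:
            raise InputFormatError(f"unknown evidence kinds {sorted(bad)}")
        records = records.drop_duplicates(["tf_id", "gene_id", "evidence"])
        self.records = records.reset_index(drop=True)
        self._by_gene: dict[str, dict[str, frozenset[str]]] = {}
        self._by_tf: dict[str, dict[str, frozenset[str]]] = {}
        for kind in EVIDENCE_KINDS:
            sub = records[records["evidence"] == kind]
            gmap: dict[str, set[str]] = {}
            tmap: dict[str, set[str]] = {}
            for tf, gene in zip(sub["tf_id"], sub["gene_id"]):
                gmap.setdefault(gene, set()).add(tf)
                tmap.setdefault(tf, set()).add(gene)
            self._by_gene[kind] = {g: frozenset(s) for g, s in gmap.items()}
            self._by_tf[kind] = {t: frozenset(s) for t, s in tmap.items()}

    def tfs_of(self, gene: str, mode: str = "either") -> frozenset[str]:
        _check_mode(mode)
        if mode == "either":
            return self._by_gene["binding"].get(gene, frozenset()) | self._by_gene[
                "regulation"
            ].get(gene, frozenset())
        return self._by_gene[mode].get(gene, frozenset())

    def targets_of(self, tf: str, mode: str = "either") -> frozenset[str]:
        _check_mode(mode)
        if mode == "either":
            return self._by_tf["binding"].get(tf, frozenset()) | self._by_tf[
                "regulation"
            ].get(tf, frozenset())
        return self._by_tf[mode].get(tf, frozenset())

    @property
    def tfs(self) -> set[str]:
        return set(self._by_tf["binding"]) | set(self._by_tf["regulation"])


def _check_mode(mode: str) -> None:
    if mode not in EVIDENCE_MODES:
        raise ValueError(f"evidence mode must be one of {EVIDENCE_MODES}, got {mode!r}")


def load_evidence(path: str | Path) -> EvidenceIndex:
    """Read a TSV with columns tf_id, gene_id, evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "tf_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["tf_id", "gene_id", "evidence"])
    return EvidenceIndex(df)


def load_ppi(path: str | Path) -> set[frozenset]:
    """Read an unordered two-column gene-pair TSV into a set of frozensets."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if str(df.iloc[0, 0]).lower() in ("gene_a", "gene1", "gene_id"):
        df = df.iloc[1:]
    return {frozenset((str(a), str(b))) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def common_tfs(
    gene_a: str, gene_b: str, evidence: EvidenceIndex, mode: str = "either"
) -> frozenset[str]:
    """TFs with evidence of the requested kind for *both* genes."""
    return evidence.tfs_of(gene_a, mode) & evidence.tfs_of(gene_b, mode)


# ---------------------------------------------------------------------------
# Bucketing by common-TF count


@dataclass
class TfBinTable:
    """Bucketed association means plus the bucket-ordinal trend correlations."""

    table: pd.DataFrame
    pcc_coexpression: float
    pcc_similarity: float


def association_by_common_tf_count(
    pairs: Sequence[AdjacentPair],
    scores: Mapping[tuple[str, str], AssociationScores],
    evidence: EvidenceIndex,
    mode: str = "regulation",
    min_bin_size: int = 90,
) -> TfBinTable:
    """Bucket pairs by |common TFs| and correlate bucket means with the count.

    Buckets run 0, 1, 2, …; from the first bucket smaller than
    ``min_bin_size`` upward, everything is merged into a final "≥k" bucket.
    Bucket sizes count every pair; bucket means are over pairs where the
    respective index is defined.  The trend PCC pairs the bucket ordinal with
    the bucket mean and is NaN with fewer than two buckets.
    """
    ks = [len(common_tfs(p.left_gene, p.right_gene, evidence, mode)) for p in pairs]
    if not ks:
        raise ValueError("no pairs to bucket")
    kmax = max(ks)
    sizes = [sum(k == i for k in ks) for i in range(kmax + 1)]
    merge_at = next((i for i, s in enumerate(sizes) if s < min_bin_size), None)
    if merge_at is not None and merge_at < kmax:
        cut = max(merge_at, 1)  # never merge everything into a single "≥0" row
    else:
        cut = kmax + 1

    rows = []
    for ordinal, lo in enumerate(list(range(cut)) + ([cut] if cut <= kmax else [])):
        merged = lo == cut
        members = [p for p, k in zip(pairs, ks) if (k >= lo if merged else k == lo)]
        coexpr = [
            scores[p.key].coexpression
            for p in members
            if scores[p.key].coexpression is not None
        ]
        sims = [
            scores[p.key].functional_similarity
            for p in members
            if scores[p.key].functional_similarity is not None
        ]
        label = f"≥{lo} TFs" if merged else (f"{lo} TF" if lo <= 1 else f"{lo} TFs")
        rows.append(
            {
                "bin_index": ordinal,
                "label": label,
                "n_pairs": len(members),
                "mean_coexpression": float(np.mean(coexpr)) if coexpr else np.nan,
                "mean_functional_similarity": float(np.mean(sims)) if sims else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    return TfBinTable(
        table,
        _trend_pcc(table["bin_index"], table["mean_coexpression"]),
        _trend_pcc(table["bin_index"], table["mean_functional_similarity"]),
    )


def _trend_pcc(ordinals: pd.Series, means: pd.Series) -> float:
    ok = means.notna()
    if ok.sum() < 2:
        return float("nan")
    x = ordinals[ok].to_numpy(dtype=float)
    y = means[ok].to_numpy(dtype=float)
    if ok.sum() == 2:
        # two points define the sign exactly
        return float(np.sign((x[1] - x[0]) * (y[1] - y[0]))) or float("nan")
    try:
        return pearson(x, y)
    except ValueError:
        return float("nan")


# ---------------------------------------------------------------------------
# Per-TF group statistics


def tf_group_scores(
    tf: str,
    pairs: Sequence[AdjacentPair],
    scores: Mapping[tuple[str, str], AssociationScores],
    evidence: EvidenceIndex,
    mode: str = "either",
) -> tuple[float, float] | None:
    """(e_score, f_score) of the TF's group: means over its h2h pairs.

    The group holds every pair whose common-TF set (under ``mode``) contains
    the TF; a pair with several common TFs appears in several groups.  Means
    are over defined indices only; ``None`` for an empty group.
    """
    group = [
        p for p in pairs if tf in common_tfs(p.left_gene, p.right_gene, evidence, mode)
    ]
    if not group:
        return None
    coexpr = [scores[p.key].coexpression for p in group
              if scores[p.key].coexpression is not None]
    sims = [scores[p.key].functional_similarity for p in group
            if scores[p.key].functional_similarity is not None]
    e = float(np.mean(coexpr)) if coexpr else float("nan")
    f = float(np.mean(sims)) if sims else float("nan")
    return e, f


def ppi_fraction(
    group_pairs: Sequence[AdjacentPair], ppi_pairs: set[frozenset]
) -> tuple[int, float]:
    """How many group pairs have a protein-protein interaction (unordered)."""
    n = sum(frozenset((p.left_gene, p.right_gene)) in ppi_pairs for p in group_pairs)
    pct = 100.0 * n / len(group_pairs) if group_pairs else 0.0
    return n, pct


def h2h_target_fraction(
    tf: str, evidence: EvidenceIndex, h2h_genes: set[str], mode: str = "either"
) -> tuple[int, float] | None:
    """Of the TF's distinct target genes, the percentage that are h2h genes.

    ``h2h_genes`` is the set of genes belonging to any h2h pair.  ``None``
    when the TF has no targets under the requested mode.
    """
    targets = evidence.targets_of(tf, mode)
    if not targets:
        return None
    return len(targets), 100.0 * len(targets & h2h_genes) / len(targets)


def tf_score_table(
    h2h_pairs: Sequence[AdjacentPair],
    scores: Mapping[tuple[str, str], AssociationScores],
    evidence: EvidenceIndex,
    ppi_pairs: set[frozenset] | None = None,
    mode: str = "either",
) -> pd.DataFrame:
    """Full ranked per-TF table (sorted by f_score descending).

    Columns: tf_id, n_h2h_pairs, e_score, f_score, n_ppi, pct_ppi,
    n_target_genes, pct_h2h.  TFs whose group of h2h pairs is empty are
    omitted.
    """
    ppi_pairs = ppi_pairs or set()
    h2h_genes = {g for p in h2h_pairs for g in (p.left_gene, p.right_gene)}
    groups: dict[str, list[AdjacentPair]] = {}
    for p in h2h_pairs:
        for tf in common_tfs(p.left_gene, p.right_gene, evidence, mode):
            groups.setdefault(tf, []).append(p)

    rows = []
    for tf, group in groups.items():
        ef = tf_group_scores(tf, h2h_pairs, scores, evidence, mode)
        assert ef is not None  # group is non-empty by construction
        n_ppi, pct_ppi = ppi_fraction(group, ppi_pairs)
        tgt = h2h_target_fraction(tf, evidence, h2h_genes, mode)
        n_targets, pct_h2h = tgt if tgt is not None else (0, float("nan"))
        rows.append(
            {
                "tf_id": tf,
                "n_h2h_pairs": len(group),
                "e_score": ef[0],
                "f_score": ef[1],
                "n_ppi": n_ppi,
                "pct_ppi": pct_ppi,
                "n_target_genes": n_targets,
                "pct_h2h": pct_h2h,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["tf_id", "n_h2h_pairs", "e_score", "f_score", "n_ppi", "pct_ppi",
                 "n_target_genes", "pct_h2h"],
    )
    return out.sort_values("f_score", ascending=False, kind="stable").reset_index(drop=True)
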