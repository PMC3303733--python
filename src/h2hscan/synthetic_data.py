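"""Synthetic inputs with planted structure for exercising the whole pipeline.

Real runs of this analysis need curated resources: genome annotations,
expression compendia, a GO hierarchy with gene annotations, TF binding and
regulation evidence, TATA-box coordinates and per-base bendability/nucleosome
tracks.  This module generates statistically controlled stand-ins for all of
them, together with the ground-truth labels needed for recovery tests:

* a gene layout per chromosome with i.i.d. strands (so the 25/50/25
  h2h/h2t/t2t expectation holds under uniform strands);
* a subset of h2h pairs is "planted" as associated, each with a strength
  c ∈ {1..planted_common_tfs}: the pair receives c common regulation TFs, an
  expression correlation of assoc_expr_corr·c/planted_common_tfs in one
  dataset, and a shared GO term whose specificity grows with c.  Association
  therefore rises with the planted common-TF count, which is the structure the
  bucket-trend analysis is meant to detect;
* bendability/occupancy tracks are Gaussian noise around a global mean; a
  chosen subset of bidirectional promoters gets an inserted jointly
  below-average run, while every other h2h promoter gets an above-average base
  every min_len−1 positions so no qualifying run can arise there by chance —
  accessibility labels are exact by construction;
* a fraction of promoters gets an inserted TATA-box interval.

Everything is deterministic under a fixed seed (independent child generators
per component, so adding a component never perturbs the others).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association_metrics import ExpressionDataset, GoDag, propagate_annotations
from .genome_pairs import AdjacentPair, GeneModel, adjacent_pairs
from .promoter_signals import (
    GenomeTrack,
    PromoterRegion,
    TataBox,
    bidirectional_promoter_region,
    write_tata_bed,
    write_track_bedgraph,
)

BEND_MEAN, BEND_SD = 5.0, 1.0
OCC_MEAN, OCC_SD = 0.5, 0.15
BEND_LOW, OCC_LOW = 3.0, 0.1      # planted accessible-run values (well below mean)
BEND_HIGH = 7.5                   # run-breaking value (well above mean)


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults mirror the study's conditions.

    16 chromosomes with uniform strands reproduce the random-arrangement
    setting; ten expression datasets at ≥15 samples mirror the retained
    microarray compendium; min_len 8 matches the accessible-run rule.
    """

    seed: int = 0
    n_chroms: int = 16
    genes_per_chrom: int = 100
    gene_len_range: tuple[int, int] = (300, 3000)
    gap_len_range: tuple[int, int] = (0, 1000)
    strand_prob_plus: float = 0.5
    tss_frac: float = 0.8
    tss_offset_range: tuple[int, int] = (10, 150)
    frac_associated_h2h: float = 0.5
    assoc_expr_corr: float = 0.8
    n_datasets: int = 10
    samples_per_dataset: int = 50
    dag_depth: int = 5
    dag_branching: int = 3
    annotation_frac: float = 0.9
    n_tfs: int = 30
    planted_common_tfs: int = 2
    background_evidence: int = 200
    accessible_frac: float = 0.5
    accessible_run_len: int = 12
    accessible_min_len: int = 8
    tata_frac: float = 0.4
    tata_len: int = 8
    with_sequence: bool = True

    def __post_init__(self) -> None:
        for name in ("strand_prob_plus", "tss_frac", "frac_associated_h2h",
                     "annotation_frac", "accessible_frac", "tata_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.assoc_expr_corr <= 1.0:
            raise ValueError("assoc_expr_corr must be in [0, 1]")
        for name in ("gene_len_range", "gap_len_range", "tss_offset_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} is infeasible: ({lo}, {hi})")
        if self.gene_len_range[0] < 1:
            raise ValueError("genes must be at least 1 bp long")
        if self.samples_per_dataset < 15:
            raise ValueError("samples_per_dataset must be >= 15 (the dataset filter)")
        if self.planted_common_tfs < 1 or self.planted_common_tfs > self.n_tfs:
            raise ValueError("planted_common_tfs must be in [1, n_tfs]")


@dataclass
class SynthTruth:
    """Planted labels: what the pipeline should recover."""

    associated: dict[tuple[str, str], int]   # pair key -> strength (1..max)
    accessible: set[tuple[str, str]]
    tata: set[tuple[str, str]]


@dataclass
class SynthData:
    """One generated study: every pipeline input plus the ground truth."""

    cfg: SynthConfig
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    pairs: list[AdjacentPair]
    datasets: list[ExpressionDataset]
    dag: GoDag
    evidence: pd.DataFrame
    ppi: set[frozenset]
    bend: GenomeTrack
    occ: GenomeTrack
    tata_boxes: list[TataBox]
    truth: SynthTruth

    @property
    def h2h_pairs(self) -> list[AdjacentPair]:
        return [p for p in self.pairs if p.pair_class == "h2h"]

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


# ---------------------------------------------------------------------------
# Genome layout


def generate_genome(
    cfg: SynthConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], dict[str, int], dict[str, str]]:
    """Lay out genes left-to-right per chromosome with uniform random gaps.

    Gaps between consecutive coding regions are drawn uniformly from
    ``gap_len_range`` (the gap *is* the CR distance, so the distance histogram
    of the layout is analytically flat over that range); strands are i.i.d.
    Bernoulli(strand_prob_plus).  TSSs sit upstream of the CDS at a uniform
    random offset for a ``tss_frac`` subset of genes.
    """
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    margin = cfg.tss_offset_range[1] + 200
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1:02d}"
        pos = 0
        for gi in range(cfg.genes_per_chrom):
            gap = int(rng.integers(cfg.gap_len_range[0], cfg.gap_len_range[1] + 1))
            length = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
            start = pos + gap + 1
            end = start + length - 1
            strand = "+" if rng.random() < cfg.strand_prob_plus else "-"
            tss = None
            if rng.random() < cfg.tss_frac:
                off = int(rng.integers(cfg.tss_offset_range[0], cfg.tss_offset_range[1] + 1))
                tss = max(1, start - off) if strand == "+" else end + off
            genes.append(GeneModel(f"{chrom}g{gi + 1:04d}", chrom, strand, start, end, tss=tss))
            pos = end
        chrom_lengths[chrom] = pos + margin
        if cfg.with_sequence:
            codes = rng.integers(0, 4, size=chrom_lengths[chrom], dtype=np.uint8)
            sequences[chrom] = codes.astype(np.uint8).tobytes().translate(
                bytes.maketrans(bytes(range(4)), b"ACGT")
            ).decode("ascii")
    return genes, chrom_lengths, sequences


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    gene_ids: Sequence[str],
    planted: Mapping[tuple[str, str], int],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> list[ExpressionDataset]:
    """Noise matrices with planted pair correlations in the first dataset.

    A planted pair of strength c gets profiles sharing a latent factor so the
    population correlation is assoc_expr_corr·c/planted_common_tfs; all other
    profiles are independent standard normals.  Later datasets drop a random
    5% of non-planted genes, exercising the both-genes-present rule.
    """
    gene_ids = list(gene_ids)
    m = cfg.samples_per_dataset
    planted_genes = {g for key in planted for g in key}
    datasets: list[ExpressionDataset] = []
    for j in range(cfg.n_datasets):
        mat = rng.standard_normal((len(gene_ids), m))
        df = pd.DataFrame(mat, index=gene_ids,
                          columns=[f"s{k + 1:03d}" for k in range(m)])
        if j == 0:
            for (a, b), strength in planted.items():
                rho = cfg.assoc_expr_corr * strength / cfg.planted_common_tfs
                z = rng.standard_normal(m)
                for g in (a, b):
                    df.loc[g] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * rng.standard_normal(m)
        else:
            droppable = [g for g in gene_ids if g not in planted_genes]
            n_drop = len(droppable) // 20
            if n_drop:
                drop = rng.choice(droppable, size=n_drop, replace=False)
                df = df.drop(index=drop)
        datasets.append(ExpressionDataset(f"ds{j:02d}", df))
    return datasets


# ---------------------------------------------------------------------------
# GO DAG


def generate_go(
    gene_ids: Sequence[str],
    planted: Mapping[tuple[str, str], int],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> GoDag:
    """A toy biological-process hierarchy: a tree with planted shared terms.

    Planted pairs of full strength share a private leaf term (two genes →
    maximal specificity); weaker strengths share mid-depth terms drawn from a
    small pool, so several weak pairs share the same term and its gene count
    is larger (less specific).  Background genes are annotated to depth-1
    terms, whose large counts make random overlaps unspecific.
    """
    root = "GO:ROOT"
    parents: dict[str, set[str]] = {root: set()}
    levels: list[list[str]] = [[root]]
    for d in range(1, cfg.dag_depth + 1):
        level: list[str] = []
        for i in range(cfg.dag_branching ** d):
            term = f"GO:D{d}N{i:04d}"
            parents[term] = {levels[d - 1][i // cfg.dag_branching]}
            level.append(term)
        levels.append(level)

    annotations: dict[str, set[str]] = {}
    leaf_cycle = itertools.cycle(levels[cfg.dag_depth])
    mid_depth = max(1, cfg.dag_depth // 2)
    mid_pool = levels[mid_depth][: cfg.dag_branching]
    mid_cycle = itertools.cycle(mid_pool)
    for (a, b), strength in planted.items():
        term = next(leaf_cycle) if strength == cfg.planted_common_tfs else next(mid_cycle)
        for g in (a, b):
            annotations.setdefault(g, set()).add(term)
    planted_genes = set(annotations)
    for g in gene_ids:
        if g in planted_genes or rng.random() >= cfg.annotation_frac:
            continue
        annotations.setdefault(g, set()).add(
            levels[1][int(rng.integers(0, len(levels[1])))]
        )
    return propagate_annotations(GoDag(parents, annotations, root=root))


# ---------------------------------------------------------------------------
# TF evidence and PPIs


def generate_tf_evidence(
    gene_ids: Sequence[str],
    planted: Mapping[tuple[str, str], int],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, set[frozenset]]:
    """Regulation evidence for planted common TFs plus random background.

    A planted pair of strength c receives c TFs with regulation evidence for
    both genes.  Background records (random TF, gene and evidence kind) are
    sprinkled on top.  Half of the full-strength pairs also get a PPI edge,
    along with a few random gene pairs.
    """
    tf_ids = [f"TF{i:02d}" for i in range(cfg.n_tfs)]
    rows: list[tuple[str, str, str]] = []
    ppi: set[frozenset] = set()
    for (a, b), strength in planted.items():
        chosen = rng.choice(cfg.n_tfs, size=strength, replace=False)
        for t in chosen:
            rows.append((tf_ids[int(t)], a, "regulation"))
            rows.append((tf_ids[int(t)], b, "regulation"))
        if strength == cfg.planted_common_tfs and rng.random() < 0.5:
            ppi.add(frozenset((a, b)))
    gene_ids = list(gene_ids)
    for _ in range(cfg.background_evidence):
        tf = tf_ids[int(rng.integers(0, cfg.n_tfs))]
        gene = gene_ids[int(rng.integers(0, len(gene_ids)))]
        kind = "binding" if rng.random() < 0.5 else "regulation"
        rows.append((tf, gene, kind))
    for _ in range(10):
        a, b = rng.choice(len(gene_ids), size=2, replace=False)
        ppi.add(frozenset((gene_ids[int(a)], gene_ids[int(b)])))
    df = pd.DataFrame(rows, columns=["tf_id", "gene_id", "evidence"])
    return df.drop_duplicates().reset_index(drop=True), ppi


# ---------------------------------------------------------------------------
# Tracks and TATA boxes


def generate_tracks_and_tata(
    genes: Sequence[GeneModel],
    pairs: Sequence[AdjacentPair],
    chrom_lengths: Mapping[str, int],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[GenomeTrack, GenomeTrack, list[TataBox], set, set]:
    """Noise tracks with planted accessible runs, plus TATA intervals.

    Accessible promoters get a run of ``accessible_run_len`` bases set well
    below both genome means.  Every *other* h2h promoter gets an above-average
    bendability base every ``accessible_min_len − 1`` positions, capping any
    chance joint-below run at min_len − 2 — the planted accessibility labels
    are therefore exact, not merely probable.
    """
    bend_data = {c: rng.normal(BEND_MEAN, BEND_SD, n) for c, n in chrom_lengths.items()}
    occ_data = {c: rng.normal(OCC_MEAN, OCC_SD, n) for c, n in chrom_lengths.items()}

    by_id = {g.gene_id: g for g in genes}
    regions: list[PromoterRegion] = [
        bidirectional_promoter_region(p, by_id)
        for p in pairs
        if p.pair_class == "h2h"
    ]
    candidates = [r for r in regions if r.length >= cfg.accessible_run_len]
    n_acc = round(cfg.accessible_frac * len(candidates))
    acc_idx = set(rng.choice(len(candidates), size=n_acc, replace=False).tolist()) if n_acc else set()
    accessible: set[tuple[str, str]] = set()
    for i, r in enumerate(candidates):
        if i in acc_idx:
            off = int(rng.integers(0, r.length - cfg.accessible_run_len + 1))
            s = r.start - 1 + off
            bend_data[r.chrom][s : s + cfg.accessible_run_len] = BEND_LOW
            occ_data[r.chrom][s : s + cfg.accessible_run_len] = OCC_LOW
            accessible.add((r.left_gene, r.right_gene))
    stride = max(cfg.accessible_min_len - 1, 1)
    for r in regions:
        if (r.left_gene, r.right_gene) in accessible or r.is_empty:
            continue
        spots = np.arange(r.start - 1, r.end, stride)
        bend_data[r.chrom][spots] = BEND_HIGH

    tata_candidates = [r for r in regions if r.length >= cfg.tata_len]
    n_tata = round(cfg.tata_frac * len(tata_candidates))
    tata_idx = set(rng.choice(len(tata_candidates), size=n_tata, replace=False).tolist()) if n_tata else set()
    boxes: list[TataBox] = []
    tata: set[tuple[str, str]] = set()
    for i, r in enumerate(tata_candidates):
        if i in tata_idx:
            off = int(rng.integers(0, r.length - cfg.tata_len + 1))
            boxes.append(TataBox(r.chrom, r.start + off, r.start + off + cfg.tata_len - 1))
            tata.add((r.left_gene, r.right_gene))

    return (
        GenomeTrack("bendability", bend_data),
        GenomeTrack("occupancy", occ_data),
        boxes,
        accessible,
        tata,
    )


# ---------------------------------------------------------------------------
# Orchestration


def generate_dataset(cfg: SynthConfig) -> SynthData:
    """Generate every pipeline input, deterministically under ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    r_genome, r_assoc, r_expr, r_go, r_tf, r_tracks = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    genes, chrom_lengths, sequences = generate_genome(cfg, r_genome)
    pairs = adjacent_pairs(genes)
    h2h = [p for p in pairs if p.pair_class == "h2h"]

    n_assoc = round(cfg.frac_associated_h2h * len(h2h))
    idx = sorted(r_assoc.choice(len(h2h), size=n_assoc, replace=False).tolist()) if n_assoc else []
    planted = {
        h2h[i].key: 1 + (rank % cfg.planted_common_tfs) for rank, i in enumerate(idx)
    }

    gene_ids = [g.gene_id for g in genes]
    datasets = generate_expression(gene_ids, planted, cfg, r_expr)
    dag = generate_go(gene_ids, planted, cfg, r_go)
    evidence, ppi = generate_tf_evidence(gene_ids, planted, cfg, r_tf)
    bend, occ, boxes, accessible, tata = generate_tracks_and_tata(
        genes, pairs, chrom_lengths, cfg, r_tracks
    )
    return SynthData(
        cfg=cfg, genes=genes, chrom_lengths=chrom_lengths, sequences=sequences,
        pairs=pairs, datasets=datasets, dag=dag, evidence=evidence, ppi=ppi,
        bend=bend, occ=occ, tata_boxes=boxes,
        truth=SynthTruth(planted, accessible, tata),
    )


def write_dataset(data: SynthData, out_dir: str | Path) -> dict[str, Path]:
    """Write every generated input in the formats the pipeline readers expect.

    Also writes ``truth.tsv`` (planted labels) and ``run.yaml`` (a ready
    pipeline configuration pointing at the written files).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = out / "genes.gff3"
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in data.genes:
            fh.write(
                f"{g.chrom}\th2hscan\tgene\t{g.cds_start}\t{g.cds_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )

    paths["tss"] = out / "tss.tsv"
    with open(paths["tss"], "w") as fh:
        fh.write("gene_id\ttss\n")
        for g in data.genes:
            if g.tss is not None:
                fh.write(f"{g.gene_id}\t{g.tss}\n")

    paths["chrom_lengths"] = out / "chrom_lengths.tsv"
    with open(paths["chrom_lengths"], "w") as fh:
        for c in sorted(data.chrom_lengths):
            fh.write(f"{c}\t{data.chrom_lengths[c]}\n")

    if data.sequences:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        paths["fasta"] = out / "genome.fasta"
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in sorted(data.sequences.items())
        ]
        SeqIO.write(records, str(paths["fasta"]), "fasta")

    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    expr_paths = []
    for ds in data.datasets:
        p = expr_dir / f"{ds.dataset_id}.tsv"
        ds.values.to_csv(p, sep="\t", index_label="gene_id")
        expr_paths.append(p)
    paths["expression_dir"] = expr_dir

    paths["go_edges"] = out / "go_edges.tsv"
    with open(paths["go_edges"], "w") as fh:
        for child in sorted(data.dag.terms):
            for parent in sorted(data.dag.graph.successors(child)):
                fh.write(f"{child}\t{parent}\n")
    paths["go_annotations"] = out / "go_annotations.tsv"
    with open(paths["go_annotations"], "w") as fh:
        for gene in sorted(data.dag.annotations):
            for term in sorted(data.dag.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")

    paths["tf_evidence"] = out / "tf_evidence.tsv"
    data.evidence.to_csv(paths["tf_evidence"], sep="\t", index=False)

    paths["ppi"] = out / "ppi.tsv"
    with open(paths["ppi"], "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in data.ppi):
            fh.write(f"{pair[0]}\t{pair[1]}\n")

    paths["tata"] = out / "tata.bed"
    write_tata_bed(data.tata_boxes, paths["tata"])

    paths["bend"] = out / "bendability.bedgraph"
    write_track_bedgraph(data.bend, paths["bend"])
    paths["occ"] = out / "occupancy.bedgraph"
    write_track_bedgraph(data.occ, paths["occ"])

    paths["truth"] = out / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("left_gene\tright_gene\tassociated_strength\taccessible\ttata\n")
        for p in data.h2h_pairs:
            key = p.key
            fh.write(
                f"{p.left_gene}\t{p.right_gene}\t{data.truth.associated.get(key, 0)}\t"
                f"{int(key in data.truth.accessible)}\t{int(key in data.truth.tata)}\n"
            )

    import yaml

    paths["run_config"] = out / "run.yaml"
    cfg_doc = {
        "genes": str(paths["genes"]),
        "genes_format": "gff3",
        "tss": str(paths["tss"]),
        "chrom_lengths": str(paths["chrom_lengths"]),
        "expression": [str(p) for p in expr_paths],
        "go_edges": str(paths["go_edges"]),
        "go_annotations": str(paths["go_annotations"]),
        "tf_evidence": str(paths["tf_evidence"]),
        "ppi": str(paths["ppi"]),
        "tata_bed": str(paths["tata"]),
        "bend_track": str(paths["bend"]),
        "occ_track": str(paths["occ"]),
        "out_dir": str(out / "results"),
        "min_bin_size": 1,
    }
    with open(paths["run_config"], "w") as fh:
        yaml.safe_dump(cfg_doc, fh, sort_keys=False)
    return paths
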