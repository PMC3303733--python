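"""End-to-end orchestration: from input files to report tables.

``run_pipeline`` sequences the analyses — pair classification and chromosome
summary, distance histograms, association scoring, common-TF stratification,
per-TF scores, TATA and accessibility stratification — and writes each result
as a TSV plus a machine-readable ``headline.json`` of the summary statistics.
Optional inputs degrade gracefully: a missing TF-evidence table skips the TF
stages with a warning, missing tracks skip accessibility, and so on.

Every analysis constant (bin width, maximum binned distance, minimum dataset
samples, minimum accessible-run length, bucket-merge threshold) is a named,
defaulted configuration field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association_metrics as am
from . import genome_pairs as gp
from . import promoter_signals as ps
from . import tf_analysis as tfa
from .errors import ConfigError

logger = logging.getLogger(__name__)

STAGES = ("pairs", "assoc", "tf", "promoter")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    genes: str
    chrom_lengths: str
    out_dir: str
    genes_format: str = "gff3"
    tss: str | None = None
    expression: list[str] = field(default_factory=list)
    go_edges: str | None = None
    go_annotations: str | None = None
    tf_evidence: str | None = None
    ppi: str | None = None
    tata_bed: str | None = None
    bend_track: str | None = None
    occ_track: str | None = None
    genome_fasta: str | None = None
    propensity: str | None = None
    bin_width: int = 200
    max_distance: int = 3000
    min_samples: int = 15
    min_len: int = ps.DEFAULT_MIN_RUN
    min_bin_size: int = 90
    evidence_mode: str = "either"
    promoter_source: str = "between_cds"
    association_scope: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.max_distance <= 0 or self.max_distance % self.bin_width:
            raise ConfigError("max_distance must be a positive multiple of bin_width")
        if self.min_samples < 1 or self.min_len < 1 or self.min_bin_size < 1:
            raise ConfigError("min_samples, min_len and min_bin_size must be positive")
        if self.evidence_mode not in tfa.EVIDENCE_MODES:
            raise ConfigError(f"evidence_mode must be one of {tfa.EVIDENCE_MODES}")
        if self.promoter_source not in ("between_cds", "between_tss"):
            raise ConfigError("promoter_source must be 'between_cds' or 'between_tss'")
        if self.association_scope not in ("all", "h2h"):
            raise ConfigError("association_scope must be 'all' or 'h2h'")
        if self.genes_format not in ("gff3", "tsv"):
            raise ConfigError("genes_format must be 'gff3' or 'tsv'")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; unknown keys and missing files fail."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys {sorted(unknown)}")
    for req in ("genes", "chrom_lengths", "out_dir"):
        if req not in doc:
            raise ConfigError(f"{path}: missing required key {req!r}")
    cfg = RunConfig(**doc)
    for name in ("genes", "chrom_lengths", "tss", "go_edges", "go_annotations",
                 "tf_evidence", "ppi", "tata_bed", "bend_track", "occ_track",
                 "genome_fasta", "propensity"):
        value = getattr(cfg, name)
        if value is not None and not Path(value).exists():
            raise ConfigError(f"{path}: {name} file {value} does not exist")
    for p in cfg.expression:
        if not Path(p).exists():
            raise ConfigError(f"{path}: expression file {p} does not exist")
    return cfg


# ---------------------------------------------------------------------------
# Helpers


def _value_histogram(values: Sequence[float], lo: float, hi: float, width: float) -> pd.DataFrame:
    """Fractional histogram of an association index over defined values."""
    vals = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    edges = np.arange(lo, hi + width / 2, width)
    counts, _ = np.histogram(vals, bins=edges)
    frac = counts / vals.size if vals.size else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts, "fraction": frac})


def _grouped_histograms(
    groups: Mapping[str, Sequence[float]], lo: float, hi: float, width: float
) -> pd.DataFrame:
    frames = []
    for name, vals in groups.items():
        df = _value_histogram(vals, lo, hi, width)
        df.insert(0, "group", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6g", na_rep="NA")


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(cfg: RunConfig, stages: Iterable[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the report bundle.

    Returns the headline statistics also written to ``headline.json``.
    """
    requested = set(stages) if stages is not None else set(STAGES)
    bad = requested - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages {sorted(bad)}")
    if requested & {"tf", "promoter"}:
        requested.add("assoc")
    requested.add("pairs")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    headline: dict = {}

    # --- stage: pairs -------------------------------------------------------
    genes = gp.read_gene_annotations(cfg.genes, fmt=cfg.genes_format)
    if cfg.tss:
        genes = gp.apply_tss_table(genes, gp.read_tss_table(cfg.tss))
    chrom_lengths = gp.read_chrom_lengths(cfg.chrom_lengths)
    candidates = gp.form_adjacent_pairs(genes)
    kept = gp.filter_overlapping(candidates)
    pairs = gp.adjacent_pairs(genes)
    genes_by_id = {g.gene_id: g for g in genes}
    h2h = [p for p in pairs if p.pair_class == "h2h"]
    class_counts = {c: sum(p.pair_class == c for p in pairs) for c in gp.PAIR_CLASSES}
    headline["counts"] = {
        "n_genes": len(genes),
        "n_candidate_pairs": len(candidates),
        "n_overlapping_excluded": len(candidates) - len(kept),
        "n_pairs": len(pairs),
        **{f"n_{c}": n for c, n in class_counts.items()},
        **{f"pct_{c}": 100.0 * n / len(pairs) if pairs else None
           for c, n in class_counts.items()},
    }
    logger.info("pair counts: %s", headline["counts"])

    summary = gp.chromosome_summary(genes, pairs, chrom_lengths)
    _write(summary, out_dir, "table1_chromosome_summary.tsv")
    _write(
        pd.DataFrame(
            [
                {
                    "left_gene": p.left_gene, "right_gene": p.right_gene,
                    "chrom": p.chrom, "pair_class": p.pair_class,
                    "cr_distance": p.cr_distance, "tss_distance": p.tss_distance,
                }
                for p in pairs
            ]
        ),
        out_dir, "pairs.tsv",
    )

    cr_groups = {"all": [p.cr_distance for p in pairs]}
    for c in gp.PAIR_CLASSES:
        cr_groups[c] = [p.cr_distance for p in pairs if p.pair_class == c]
    cr_frames = []
    for name, vals in cr_groups.items():
        df = gp.bin_distances(vals, cfg.bin_width, cfg.max_distance).to_frame()
        df.insert(0, "group", name)
        cr_frames.append(df)
    _write(pd.concat(cr_frames, ignore_index=True), out_dir, "fig1_cr_distance_hist.tsv")

    # --- stage: assoc -------------------------------------------------------
    scores: dict | None = None
    labels: dict | None = None
    if "assoc" in requested:
        datasets = am.load_expression(cfg.expression, cfg.min_samples) if cfg.expression else []
        dag = None
        if cfg.go_edges and cfg.go_annotations:
            dag = am.propagate_annotations(am.GoDag.from_tables(cfg.go_edges, cfg.go_annotations))
        if not datasets:
            logger.warning("no expression datasets: co-expression will be undefined")
        if dag is None:
            logger.warning("no GO inputs: functional similarity will be undefined")
        scores = am.compute_scores(pairs, datasets, dag)
        sims = {k: s.functional_similarity for k, s in scores.items()}
        if any(v is not None for v in sims.values()):
            ref = [p.key for p in (h2h if cfg.association_scope == "h2h" else pairs)]
            labels = am.split_by_association(sims, reference_keys=ref)
        else:
            labels = {k: "low" for k in sims}
        _write(
            pd.DataFrame(
                [
                    {
                        "left_gene": p.left_gene, "right_gene": p.right_gene,
                        "pair_class": p.pair_class,
                        "coexpression": scores[p.key].coexpression,
                        "functional_similarity": scores[p.key].functional_similarity,
                        "association_label": labels[p.key],
                    }
                    for p in pairs
                ]
            ),
            out_dir, "scores.tsv",
        )
        tss_groups = {
            "h2h": [p.tss_distance for p in h2h if p.tss_distance is not None],
            "h2h_high": [p.tss_distance for p in h2h
                         if p.tss_distance is not None and labels[p.key] == "high"],
            "h2h_low": [p.tss_distance for p in h2h
                        if p.tss_distance is not None and labels[p.key] == "low"],
        }
        tss_frames = []
        for name, vals in tss_groups.items():
            df = gp.bin_distances(vals, cfg.bin_width, cfg.max_distance).to_frame()
            df.insert(0, "group", name)
            tss_frames.append(df)
        _write(pd.concat(tss_frames, ignore_index=True), out_dir, "fig1_tss_distance_hist.tsv")
        headline["association"] = {
            "n_datasets_used": len(datasets),
            "n_pairs_with_coexpression": sum(
                s.coexpression is not None for s in scores.values()
            ),
            "n_pairs_with_similarity": sum(
                s.functional_similarity is not None for s in scores.values()
            ),
            "n_h2h_high": sum(labels[p.key] == "high" for p in h2h),
            "n_h2h_low": sum(labels[p.key] == "low" for p in h2h),
        }

    # --- stage: tf ----------------------------------------------------------
    if "tf" in requested:
        if not cfg.tf_evidence:
            logger.warning("no TF evidence table configured: skipping TF stages")
        else:
            assert scores is not None
            evidence = tfa.load_evidence(cfg.tf_evidence)
            ppi = tfa.load_ppi(cfg.ppi) if cfg.ppi else set()
            trend: dict = {}
            for mode in ("binding", "regulation"):
                frames = []
                for pclass in gp.PAIR_CLASSES:
                    cpairs = [p for p in pairs if p.pair_class == pclass]
                    if not cpairs:
                        continue
                    bins = tfa.association_by_common_tf_count(
                        cpairs, scores, evidence, mode, cfg.min_bin_size
                    )
                    tab = bins.table.copy()
                    tab.insert(0, "pair_class", pclass)
                    frames.append(tab)
                    trend[f"{mode}_{pclass}"] = {
                        "pcc_coexpression": bins.pcc_coexpression,
                        "pcc_similarity": bins.pcc_similarity,
                    }
                if frames:
                    _write(pd.concat(frames, ignore_index=True), out_dir, f"table2_{mode}.tsv")
            headline["tf_trend_pcc"] = trend

            table3 = tfa.tf_score_table(h2h, scores, evidence, ppi, cfg.evidence_mode)
            _write(table3, out_dir, "table3_tf_scores.tsv")
            listing = []
            for tf in table3["tf_id"]:
                for p in h2h:
                    if tf in tfa.common_tfs(p.left_gene, p.right_gene, evidence, cfg.evidence_mode):
                        listing.append({"tf_id": tf, "left_gene": p.left_gene,
                                        "right_gene": p.right_gene})
            _write(pd.DataFrame(listing, columns=["tf_id", "left_gene", "right_gene"]),
                   out_dir, "table4_tf_pairs.tsv")

    # --- stage: promoter ----------------------------------------------------
    if "promoter" in requested:
        assert scores is not None
        regions = {
            p.key: ps.bidirectional_promoter_region(p, genes_by_id, cfg.promoter_source)
            for p in h2h
            if cfg.promoter_source == "between_cds"
            or (genes_by_id[p.left_gene].tss is not None
                and genes_by_id[p.right_gene].tss is not None)
        }
        promoter_rows = {
            key: {"left_gene": key[0], "right_gene": key[1],
                  "chrom": r.chrom, "region_start": r.start, "region_end": r.end}
            for key, r in regions.items()
        }

        if cfg.tata_bed:
            boxes = ps.read_tata_bed(cfg.tata_bed)
            tata_class = {key: ps.classify_tata(r, boxes) for key, r in regions.items()}
            for key, cls in tata_class.items():
                promoter_rows[key]["tata_class"] = cls
            _write(
                _grouped_histograms(
                    _split_scores(tata_class, scores, "coexpression"), 0.0, 1.0, 0.1
                ),
                out_dir, "fig2_tata_coexpression.tsv",
            )
            sim_hi = _sim_upper(scores)
            _write(
                _grouped_histograms(
                    _split_scores(tata_class, scores, "functional_similarity"),
                    0.0, sim_hi, 0.5,
                ),
                out_dir, "fig2_tata_similarity.tsv",
            )
            headline["tata"] = {
                "n_tata_containing": sum(v == "tata_containing" for v in tata_class.values()),
                "n_tata_less": sum(v == "tata_less" for v in tata_class.values()),
            }
        else:
            logger.warning("no TATA interval file configured: skipping TATA stage")

        bend = occ = None
        if cfg.bend_track:
            bend = ps.read_track_bedgraph(cfg.bend_track, chrom_lengths, "bendability")
        elif cfg.genome_fasta and cfg.propensity:
            from Bio import SeqIO

            table = ps.read_propensity_table(cfg.propensity)
            bend = ps.GenomeTrack("bendability", {
                rec.id: ps.bendability_track(str(rec.seq), table)
                for rec in SeqIO.parse(cfg.genome_fasta, "fasta")
            })
        if cfg.occ_track:
            occ = ps.read_track_bedgraph(cfg.occ_track, chrom_lengths, "occupancy")

        if bend is not None and occ is not None:
            bend_avg = ps.genome_mean(bend)
            occ_avg = ps.genome_mean(occ)
            acc_class = {}
            for key, r in regions.items():
                acc_class[key] = ps.classify_accessibility(
                    r, bend, occ, bend_avg, occ_avg, cfg.min_len
                )
                promoter_rows[key]["accessibility_class"] = acc_class[key]
                promoter_rows[key]["longest_joint_run_bp"] = (
                    0 if r.is_empty else ps.longest_joint_run(r, bend, occ, bend_avg, occ_avg)
                )
            _write(
                _grouped_histograms(
                    _split_scores(acc_class, scores, "coexpression"), 0.0, 1.0, 0.1
                ),
                out_dir, "fig3_accessibility_coexpression.tsv",
            )
            _write(
                _grouped_histograms(
                    _split_scores(acc_class, scores, "functional_similarity"),
                    0.0, _sim_upper(scores), 0.5,
                ),
                out_dir, "fig3_accessibility_similarity.tsv",
            )
            headline["accessibility"] = {
                "bend_genome_mean": bend_avg,
                "occ_genome_mean": occ_avg,
                "n_more_accessible": sum(v == "more_accessible" for v in acc_class.values()),
                "n_less_accessible": sum(v == "less_accessible" for v in acc_class.values()),
            }
        else:
            logger.warning("tracks unavailable: skipping accessibility stage")

        _write(pd.DataFrame(list(promoter_rows.values())), out_dir, "promoters.tsv")

    with open(out_dir / "headline.json", "w") as fh:
        json.dump(_jsonable(headline), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return headline


def _jsonable(obj):
    """Recursively convert numpy scalars and NaN to JSON-safe values."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _split_scores(
    classes: Mapping[tuple[str, str], str],
    scores: Mapping[tuple[str, str], am.AssociationScores],
    attr: str,
) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {}
    for key, cls in classes.items():
        v = getattr(scores[key], attr)
        if v is not None:
            groups.setdefault(cls, []).append(v)
    return groups


def _sim_upper(scores: Mapping[tuple[str, str], am.AssociationScores]) -> float:
    sims = [s.functional_similarity for s in scores.values()
            if s.functional_similarity is not None]
    return float(np.ceil(max(sims) * 2) / 2) + 0.5 if sims else 1.0
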