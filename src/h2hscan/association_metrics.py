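"""Pair-association indices: co-expression and GO functional similarity.

Co-expression of a gene pair is the highest absolute Pearson correlation of
their expression profiles across all qualifying expression datasets (datasets
with fewer than 15 samples, or not covering both genes, are ignored).  Taking
the maximum rather than the mean keeps pairs that co-express only under a
specific condition.

Functional similarity is a Resnik-style information-content measure on the
biological-process GO hierarchy:

    Sim(a, b) = −ln( min_t gene(t) / gene(root) )

where t ranges over the GO terms shared by both genes' propagated annotation
closures and gene(t) is the number of genes annotated at or below t after
true-path propagation.  The most specific (smallest) shared term dominates;
sharing only the root gives Sim = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputFormatError

logger = logging.getLogger(__name__)

MIN_SAMPLES = 15


@dataclass
class ExpressionDataset:
    """One expression matrix: genes (rows) × samples (columns)."""

    dataset_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"dataset {self.dataset_id!r}: duplicated genes {dups[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def profile(self, gene: str) -> np.ndarray | None:
        if gene not in self.values.index:
            return None
        return self.values.loc[gene].to_numpy(dtype=float)


def load_expression(
    paths: Iterable[str | Path], min_samples: int = MIN_SAMPLES
) -> list[ExpressionDataset]:
    """Load expression TSVs (first column gene_id) and apply the sample filter.

    Datasets with fewer than ``min_samples`` samples are dropped (a dataset
    with exactly ``min_samples`` is retained).  A non-numeric cell is a hard
    error naming the gene and sample.
    """
    kept: list[ExpressionDataset] = []
    n_dropped = 0
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise InputFormatError(
                f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )
        ds = ExpressionDataset(path.stem, numeric)
        if ds.n_samples < min_samples:
            n_dropped += 1
            continue
        kept.append(ds)
    if n_dropped:
        logger.info(
            "dropped %d expression datasets with fewer than %d samples; %d retained",
            n_dropped, min_samples, len(kept),
        )
    return kept


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xd @ yd) / (sx * sy), -1.0, 1.0))


def pair_coexpression(
    a: str, b: str, datasets: Sequence[ExpressionDataset]
) -> float | None:
    """Max |PCC| of the two genes over datasets containing both.

    Datasets missing either gene, or where either profile has zero variance,
    are ignored for this pair.  ``None`` when no dataset qualifies.
    """
    best: float | None = None
    for ds in datasets:
        xa, xb = ds.profile(a), ds.profile(b)
        if xa is None or xb is None:
            continue
        r = pearson(xa, xb)
        if math.isnan(r):
            continue
        if best is None or abs(r) > best:
            best = abs(r)
    return best


# ---------------------------------------------------------------------------
# GO DAG and Resnik similarity


class GoDag:
    """A GO term hierarchy (child→parent DAG) with gene annotations.

    ``parents`` maps each term to its direct parents; the root is the unique
    term without parents.  ``annotations`` maps genes to their *direct* terms;
    propagated per-term gene counts (the true-path rule) are filled by
    :func:`propagate_annotations` and cached.
    """

    def __init__(
        self,
        parents: Mapping[str, set[str] | Sequence[str]],
        annotations: Mapping[str, set[str] | Sequence[str]],
        root: str | None = None,
    ) -> None:
        graph = nx.DiGraph()
        for child, ps in parents.items():
            graph.add_node(child)
            for p in ps:
                graph.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("cycle detected in GO term hierarchy")
        roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
        if root is None:
            if len(roots) != 1:
                raise ValueError(f"expected a unique root term, found {sorted(roots)}")
            root = roots[0]
        elif root not in graph.nodes:
            raise ValueError(f"declared root {root!r} not in the hierarchy")
        self.root = root
        self.graph = graph
        self.terms: set[str] = set(graph.nodes)
        self.annotations: dict[str, set[str]] = {}
        for gene, terms in annotations.items():
            known = {t for t in terms if t in self.terms}
            unknown = set(terms) - known
            if unknown:
                logger.warning(
                    "gene %s annotated to %d unknown terms (dropped)", gene, len(unknown)
                )
            if known:
                self.annotations[gene] = known
        self.gene_count: dict[str, int] | None = None
        self._ancestors: dict[str, frozenset[str]] = {}
        self._gene_closure: dict[str, frozenset[str]] = {}

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_tables(
        cls, edges_path: str | Path, annotations_path: str | Path, root: str | None = None
    ) -> "GoDag":
        """Build from a (child, parent) edge TSV and a (gene, term) TSV."""
        edges = pd.read_csv(edges_path, sep="\t", header=None, dtype=str, comment="#")
        if str(edges.iloc[0, 0]).lower() in ("child", "term_id"):
            edges = edges.iloc[1:]
        parents: dict[str, set[str]] = {}
        for child, parent in zip(edges.iloc[:, 0], edges.iloc[:, 1]):
            parents.setdefault(str(child), set()).add(str(parent))
            parents.setdefault(str(parent), set())
        anns = pd.read_csv(annotations_path, sep="\t", header=None, dtype=str, comment="#")
        if str(anns.iloc[0, 0]).lower() == "gene_id":
            anns = anns.iloc[1:]
        annotations: dict[str, set[str]] = {}
        for gene, term in zip(anns.iloc[:, 0], anns.iloc[:, 1]):
            annotations.setdefault(str(gene), set()).add(str(term))
        return cls(parents, annotations, root=root)

    @classmethod
    def from_obo(
        cls,
        obo_path: str | Path,
        annotations: Mapping[str, set[str]],
        namespace: str = "biological_process",
        relations: tuple[str, ...] = ("is_a",),
    ) -> "GoDag":
        """Build from an OBO file restricted to one namespace and edge types.

        Only ``is_a`` edges are followed by default; ``part_of`` can be added
        through ``relations``.
        """
        import obonet

        graph = obonet.read_obo(str(obo_path))
        in_ns = {
            n for n, d in graph.nodes(data=True)
            if d.get("namespace", namespace) == namespace
        }
        parents: dict[str, set[str]] = {t: set() for t in in_ns}
        for child, parent, key in graph.edges(keys=True):
            if key in relations and child in in_ns and parent in in_ns:
                parents[child].add(parent)
        return cls(parents, annotations)

    # -- closures ------------------------------------------------------------

    def ancestor_closure(self, term: str) -> frozenset[str]:
        """The term plus all its ancestors up to the root."""
        cached = self._ancestors.get(term)
        if cached is None:
            # edges point child→parent, so ancestors are graph descendants
            cached = frozenset({term} | nx.descendants(self.graph, term))
            self._ancestors[term] = cached
        return cached

    def term_closure(self, gene: str) -> frozenset[str]:
        """All terms the gene is annotated to, directly or by propagation."""
        cached = self._gene_closure.get(gene)
        if cached is None:
            closure: set[str] = set()
            for t in self.annotations.get(gene, ()):
                closure |= self.ancestor_closure(t)
            cached = frozenset(closure)
            self._gene_closure[gene] = cached
        return cached


def propagate_annotations(dag: GoDag) -> GoDag:
    """Fill propagated per-term gene counts (each gene once per ancestor term)."""
    counts: dict[str, int] = {t: 0 for t in dag.terms}
    for gene in dag.annotations:
        for t in dag.term_closure(gene):
            counts[t] += 1
    dag.gene_count = counts
    return dag


def functional_similarity(a: str, b: str, dag: GoDag) -> float | None:
    """Resnik −ln similarity of two genes on the propagated DAG.

    ``None`` when either gene carries no annotation.  Always ≥ 0 for two
    annotated genes, since the root is a shared term of probability 1.
    """
    if dag.gene_count is None:
        propagate_annotations(dag)
    assert dag.gene_count is not None
    ca, cb = dag.term_closure(a), dag.term_closure(b)
    if not ca or not cb:
        return None
    common = ca & cb
    if not common:
        return None
    root_count = dag.gene_count[dag.root]
    min_count = min(dag.gene_count[t] for t in common)
    return -math.log(min_count / root_count)


# ---------------------------------------------------------------------------
# Scoring containers


@dataclass(frozen=True)
class AssociationScores:
    """Both association indices for one pair; ``None`` marks undefined."""

    left_gene: str
    right_gene: str
    coexpression: float | None
    functional_similarity: float | None


def compute_scores(
    pairs: Iterable,
    datasets: Sequence[ExpressionDataset],
    dag: GoDag | None,
) -> dict[tuple[str, str], AssociationScores]:
    """Score every pair; keys are (left_gene, right_gene)."""
    scores: dict[tuple[str, str], AssociationScores] = {}
    for p in pairs:
        coexpr = pair_coexpression(p.left_gene, p.right_gene, datasets) if datasets else None
        sim = functional_similarity(p.left_gene, p.right_gene, dag) if dag is not None else None
        scores[(p.left_gene, p.right_gene)] = AssociationScores(
            p.left_gene, p.right_gene, coexpr, sim
        )
    return scores


def split_by_association(
    similarities: Mapping[tuple[str, str], float | None],
    reference_keys: Iterable[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], str]:
    """Label each pair ``high`` or ``low`` against the average similarity.

    The average is taken over ``reference_keys`` (default: all keys) with a
    defined similarity — the "genome average".  A pair is ``high`` only if its
    similarity is defined and strictly exceeds the average; undefined
    similarities and exact ties go to ``low``.
    """
    ref = list(reference_keys) if reference_keys is not None else list(similarities)
    defined = [similarities[k] for k in ref if similarities.get(k) is not None]
    if not defined:
        raise ValueError("no pair has a defined functional similarity")
    avg = float(np.mean(defined))
    return {
        k: "high" if (v is not None and v > avg) else "low"
        for k, v in similarities.items()
    }
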