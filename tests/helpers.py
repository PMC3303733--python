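"""Shared test utilities: fixture builders and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths: the Resnik
oracle enumerates ancestor closures by explicit stack walking and counts
genes by membership testing; the segment oracle enumerates all subintervals.
"""

from __future__ import annotations

import math

import numpy as np

from h2hscan.genome_pairs import AdjacentPair, GeneModel


def gene(gid, start, end, strand="+", chrom="chrI", tss=None):
    return GeneModel(gid, chrom, strand, start, end, tss=tss)


def pair(left="gL", right="gR", cls="h2h", cr=100, chrom="chrI", tssd=None):
    return AdjacentPair(left, right, chrom, cls, cr, tssd)


# ---------------------------------------------------------------------------
# Resnik oracle


def random_dag(rng: np.random.Generator, n_terms: int = 30, n_genes: int = 50):
    """A random connected DAG (term 0 is root; terms may have 1-2 parents)."""
    parents: dict[str, set[str]] = {"t0": set()}
    for i in range(1, n_terms):
        k = 1 + int(rng.random() < 0.3)
        ps = rng.choice(i, size=min(k, i), replace=False)
        parents[f"t{i}"] = {f"t{int(p)}" for p in ps}
    annotations: dict[str, set[str]] = {}
    for g in range(n_genes):
        if rng.random() < 0.9:
            n_ann = int(rng.integers(1, 4))
            terms = rng.choice(n_terms, size=n_ann, replace=False)
            annotations[f"g{g}"] = {f"t{int(t)}" for t in terms}
    return parents, annotations


def bruteforce_resnik(parents, annotations, a, b):
    """Sim(a,b) by explicit closure walking and per-term membership counts."""

    def closure_of_gene(g):
        up: set[str] = set()
        stack = list(annotations.get(g, ()))
        while stack:
            t = stack.pop()
            if t not in up:
                up.add(t)
                stack.extend(parents.get(t, ()))
        return up

    ca, cb = closure_of_gene(a), closure_of_gene(b)
    if not ca or not cb:
        return None
    common = ca & cb
    if not common:
        return None
    closures = {g: closure_of_gene(g) for g in annotations}

    def count(t):
        return sum(1 for g in closures if t in closures[g])

    root = next(t for t, ps in parents.items() if not ps)
    return -math.log(min(count(t) for t in common) / count(root))


# ---------------------------------------------------------------------------
# Accessible-segment oracle


def bruteforce_segments(mask, min_len):
    """All maximal qualifying runs by O(n^2) subinterval enumeration."""
    mask = list(mask)
    n = len(mask)
    qualifying = [
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if all(mask[i : j + 1])
    ]
    return [
        (i, j)
        for (i, j) in qualifying
        if (i == 0 or not mask[i - 1])
        and (j == n - 1 or not mask[j + 1])
        and j - i + 1 >= min_len
    ]


def bruteforce_bendability(seq, table):
    """Per-base mean over covering tri-nucleotide windows, by enumeration."""
    L = len(seq)
    out = []
    for i in range(L):
        vals = []
        for s in range(i - 2, i + 1):
            if 0 <= s <= L - 3:
                w = seq[s : s + 3]
                if set(w) <= set("ACGT"):
                    vals.append(table[w])
        out.append(sum(vals) / len(vals) if vals else float("nan"))
    return np.array(out)
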