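"""Ancestral genotype reconstruction and mutational-distance histograms.

A multi-region or single-cell experiment yields one mutational profile per
sample: the set of mutations clonal to the sample, i.e. the genotype of
the sample's most recent common ancestor (MRCA) cell. Intersecting the
profiles of two samples reconstructs the genotype of a deeper ancestral
cell, and the two set differences

    y1 = |A \\ (A n B)|,   y2 = |B \\ (A n B)|

are the mutational distances of the two ancestral cells to their common
ancestor. Pooling these distances over sample combinations produces the
observed distance histogram — the sufficient statistic for inferring the
per-division mutation rate and the per-cell survival rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SampleProfile",
    "DistanceHistogram",
    "pairwise_distances",
    "ancestral_profile",
    "build_histogram",
    "tree_distances",
]


@dataclass(frozen=True)
class SampleProfile:
    """Clonal mutation set of one sample: the genotype of its MRCA cell."""

    sample_id: str
    mutations: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutations", frozenset(self.mutations))

    def __len__(self) -> int:
        return len(self.mutations)


class DistanceHistogram:
    """Counts of observed mutational distances.

    Every unordered pair of ancestral genotypes contributes two distances
    (one per lineage leaving the common ancestor), so the total count is
    twice the number of pairs considered.
    """

    def __init__(self, counts: Mapping[int, int] | None = None) -> None:
        self.counts: dict[int, int] = {}
        if counts:
            for y, c in counts.items():
                if y < 0 or int(y) != y:
                    raise ValueError(f"distances must be non-negative integers, got {y}")
                if c < 1 or int(c) != c:
                    raise ValueError(f"counts must be positive integers, got {c}")
                self.counts[int(y)] = int(c)

    @classmethod
    def from_distances(cls, distances: Iterable[int]) -> "DistanceHistogram":
        h = cls()
        for y in distances:
            h.add(int(y))
        return h

    def add(self, y: int, count: int = 1) -> None:
        if y < 0:
            raise ValueError(f"distances must be non-negative, got {y}")
        self.counts[y] = self.counts.get(y, 0) + count

    @property
    def n_pairs(self) -> int:
        """Total number of recorded distances (two per unordered pair)."""
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.n_pairs

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted support and counts as integer arrays."""
        ys = np.array(sorted(self.counts), dtype=int)
        cs = np.array([self.counts[y] for y in ys], dtype=int)
        return ys, cs

    def mean(self) -> float:
        ys, cs = self.as_arrays()
        return float((ys * cs).sum() / cs.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, DistanceHistogram) and self.counts == other.counts

    def __repr__(self) -> str:
        return f"DistanceHistogram(n={self.n_pairs}, support=0..{max(self.counts, default=0)})"

    def to_csv(self, path) -> None:
        import pandas as pd

        ys, cs = self.as_arrays()
        pd.DataFrame({"y": ys, "count": cs}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DistanceHistogram":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(dict(zip(df["y"].astype(int), df["count"].astype(int))))


def pairwise_distances(a: SampleProfile, b: SampleProfile) -> tuple[int, int]:
    """Mutational distances of two profiles to their common ancestor.

    Returns ``(y1, y2)`` with ``y1 = |A \\ (A n B)|`` and
    ``y2 = |B \\ (A n B)|``; their sum is the symmetric difference.
    """
    common = a.mutations & b.mutations
    return len(a.mutations) - len(common), len(b.mutations) - len(common)


def ancestral_profile(profiles: Iterable[SampleProfile]) -> SampleProfile:
    """Genotype of the common ancestor of a set of samples (intersection)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    muts = frozenset.intersection(*(p.mutations for p in profiles))
    name = "^".join(p.sample_id for p in profiles)
    return SampleProfile(name, muts)


def _merge_events(profiles: list[SampleProfile]) -> list[tuple[int, int, int, bool, bool]]:
    """Agglomerative intersection clustering of profiles.

    Repeatedly merges the pair of active genotypes sharing the most
    mutations, replacing them by their intersection (the genotype of
    their common ancestor). For profiles generated on a cell lineage tree
    this reconstructs the genealogy of the samples exactly, one merge per
    coalescent (branching) event. Returns one tuple per merge:
    ``(ancestor_size, y1, y2, a_is_leaf, b_is_leaf)``.
    """
    active: list[tuple[frozenset, bool]] = []
    seen: set[frozenset] = set()
    for p in profiles:
        if p.mutations not in seen:
            seen.add(p.mutations)
            active.append((p.mutations, True))
    merges: list[tuple[int, int, int, bool, bool]] = []
    while len(active) > 1:
        best = (-1, 0, 1)
        for i in range(len(active)):
            a = active[i][0]
            for j in range(i + 1, len(active)):
                ov = len(a & active[j][0])
                if ov > best[0]:
                    best = (ov, i, j)
        _, i, j = best
        (a, a_leaf), (b, b_leaf) = active[i], active[j]
        anc = a & b
        merges.append((len(anc), len(a) - len(anc), len(b) - len(anc), a_leaf, b_leaf))
        active = [active[k] for k in range(len(active)) if k not in (i, j)]
        active.append((anc, False))
    return merges


def build_histogram(
    profiles: Iterable[SampleProfile],
    max_branchings: int | None = None,
    include_terminal: bool = True,
    pairs: str = "adjacent",
    combination_depth: int = 2,
) -> DistanceHistogram:
    """Mutational-distance histogram from a collection of sample profiles.

    The default ``pairs="adjacent"`` scheme iterates intersections over
    increasing combinations of samples, reconstructing the genealogy of
    the sampled lineages: each branching event contributes the two
    distances between the merging genotypes and their common ancestor
    (one unordered pair, two distances). These per-event sibling
    distances are what the compound coalescent model describes; pooling
    distances across *non-adjacent* ancestral pairs (``pairs="all"``,
    every unordered pair of genotypes obtained by intersecting up to
    ``combination_depth`` samples) mixes spans of several branching
    intervals and is kept only for comparison.

    ``max_branchings`` restricts to the earliest branching events, ranked
    by mutations carried by the ancestor (a molecular-clock proxy for
    event time). ``include_terminal=False`` drops distances measured on
    branches ending in an input profile rather than a reconstructed
    ancestor; for single-cell profiles such terminal branches span the
    whole remaining lifetime of the tissue instead of a single branching
    interval.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if max_branchings is not None and max_branchings < 1:
        raise ValueError("max_branchings must be >= 1")
    hist = DistanceHistogram()
    if pairs == "adjacent":
        merges = sorted(_merge_events(profiles))  # earliest ancestors first
        if max_branchings is not None:
            merges = merges[:max_branchings]
        for _, y1, y2, a_leaf, b_leaf in merges:
            if include_terminal or not a_leaf:
                hist.add(y1)
            if include_terminal or not b_leaf:
                hist.add(y2)
        return hist
    if pairs != "all":
        raise ValueError(f"unknown pairs scheme {pairs!r}")
    if combination_depth < 1:
        raise ValueError("combination_depth must be >= 1")
    seen: dict[frozenset, SampleProfile] = {}
    for k in range(1, combination_depth + 1):
        for combo in combinations(profiles, k):
            anc = ancestral_profile(combo) if k > 1 else combo[0]
            if anc.mutations not in seen:
                seen[anc.mutations] = anc
    pool = sorted(seen.values(), key=lambda p: (len(p), p.sample_id))
    if max_branchings is not None:
        pool = pool[:max_branchings]
    for a, b in combinations(pool, 2):
        y1, y2 = pairwise_distances(a, b)
        hist.add(y1)
        hist.add(y2)
    return hist


def _as_int_length(edge_length, node_label) -> int:
    if edge_length is None:
        return 0
    rounded = round(edge_length)
    if abs(edge_length - rounded) > 1e-9:
        warnings.warn(
            f"non-integer branch length {edge_length} at {node_label}; "
            "rounding to the nearest mutation count",
            stacklevel=3,
        )
    return int(rounded)


def tree_distances(tree, max_branchings: int) -> DistanceHistogram:
    """Distance histogram from a phylogeny with mutation-count branches.

    ``tree`` is a :class:`dendropy.Tree` whose branch lengths are integer
    mutation counts (as produced by single-cell phylogeny reconstruction).
    The ``max_branchings`` earliest internal nodes — ranked by cumulative
    mutations from the root, a molecular-clock proxy for event time —
    each contribute the mutation counts of their two child branches as a
    pair of sibling distances. Polytomies are resolved into ladders of
    zero-length branches before counting.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise TypeError("tree must be a dendropy.Tree")
    if max_branchings < 1:
        raise ValueError("max_branchings must be >= 1")
    tree = tree.clone(depth=1)
    polytomies = [
        nd for nd in tree.preorder_node_iter() if len(nd.child_nodes()) > 2
    ]
    if polytomies:
        warnings.warn(
            f"resolving {len(polytomies)} polytomies as zero-length ladders",
            stacklevel=2,
        )
        tree.resolve_polytomies()
    # cumulative integer mutations from root to each node
    depth: dict[int, int] = {}
    internal = []
    for nd in tree.preorder_node_iter():
        d = 0 if nd.parent_node is None else depth[id(nd.parent_node)] + _as_int_length(
            nd.edge.length, nd
        )
        depth[id(nd)] = d
        if nd.child_nodes():
            internal.append(nd)
    internal.sort(key=lambda nd: depth[id(nd)])
    hist = DistanceHistogram()
    for nd in internal[:max_branchings]:
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValueError("tree must be binary after polytomy resolution")
        for child in children:
            hist.add(_as_int_length(child.edge.length, child))
    return hist
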