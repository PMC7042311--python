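"""Stochastic tissue growth with lineage recording and biopsy sampling.

Implements the embedded jump chain of a Gillespie birth-death process: at
every event a random eligible cell divides, and each surviving daughter
inherits the parent's mutations plus a Poisson(``muL``) number of novel
ones. Cell death comes in two semantics: ``explicit`` (default), where
each daughter independently dies with probability
``alpha = (1-beta)/(1+beta)`` and extinct populations are restarted
(conditioning on survival); and ``effective``, where a division directly
yields two survivors with probability ``beta`` or one otherwise. The
complete division history is recorded, so exact ancestral genotypes and
mutational distances are always recoverable.

Two modes are provided: ``well-mixed`` (every live cell is eligible) and
``spatial-2D`` (cells on a square lattice; only cells with a free
von-Neumann neighbour divide, giving boundary-driven growth; a
single-survivor division replaces the parent in place and leaves no
vacancy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceHistogram, SampleProfile, build_histogram

__all__ = [
    "SimConfig",
    "SeqConfig",
    "Tissue",
    "BulkSample",
    "simulate_tissue",
    "take_samples",
    "sequencing_noise",
    "clonal_profile",
    "ground_truth_distances",
]

_NEIGHBOURS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass(frozen=True)
class SimConfig:
    """Tissue growth settings.

    ``target_cells`` defaults to 10^4, a desk-scale stand-in for the
    ~10^6-cell tissues the model targets; lineage statistics converge well
    before that size. ``grid_side`` only applies to spatial mode and must
    accommodate ``target_cells``.
    """

    muL: float = 1.14
    beta: float = 0.96
    target_cells: int = 10_000
    mode: str = "well-mixed"
    death: str = "explicit"
    grid_side: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_cells < 2:
            raise ValueError("target_cells must be >= 2")
        if not (0 < self.beta <= 1):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.muL < 0:
            raise ValueError("muL must be >= 0")
        if self.mode not in ("well-mixed", "spatial-2D"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.death not in ("explicit", "effective"):
            raise ValueError(f"unknown death semantics {self.death!r}")


@dataclass(frozen=True)
class SeqConfig:
    """Sequencing-noise settings: mean depth and clonality calling."""

    mean_depth: float = 100.0
    clonal_vaf_threshold: float = 0.3
    diploid: bool = False

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if not (0 <= self.clonal_vaf_threshold < 1):
            raise ValueError("clonal_vaf_threshold must be in [0, 1)")


class Tissue:
    """Simulated cell population with its full division history.

    Every cell that ever existed is a node; node 0 is the founding cell.
    ``parent[k]`` is the parent node, ``n_new[k]`` the number of novel
    mutations acquired at birth of node ``k``, and ``mut_start[k]`` the
    first of its contiguous block of mutation identifiers. A node's full
    genotype is the union of the blocks along its root path.
    """

    def __init__(
        self,
        parent: np.ndarray,
        n_new: np.ndarray,
        mut_start: np.ndarray,
        alive: np.ndarray,
        config: SimConfig,
        n_branching_divisions: int,
        n_nonbranching_divisions: int,
        positions: np.ndarray | None = None,
    ) -> None:
        self.parent = parent
        self.n_new = n_new
        self.mut_start = mut_start
        self.alive = alive
        self.config = config
        self.n_branching_divisions = n_branching_divisions
        self.n_nonbranching_divisions = n_nonbranching_divisions
        self.positions = positions

    @property
    def n_cells(self) -> int:
        return int(self.alive.size)

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def n_mutations(self) -> int:
        return int(self.n_new.sum())

    def lineage_path(self, node: int) -> list[int]:
        """Nodes from the root down to ``node`` (inclusive)."""
        path = []
        k = int(node)
        while k != -1:
            path.append(k)
            k = int(self.parent[k])
        return path[::-1]

    def mutation_set(self, node: int) -> frozenset[int]:
        """Full genotype of a node as a set of mutation identifiers."""
        muts: list[int] = []
        for k in self.lineage_path(node):
            s, n = int(self.mut_start[k]), int(self.n_new[k])
            muts.extend(range(s, s + n))
        return frozenset(muts)

    def mrca(self, nodes) -> int:
        """Most recent common ancestor node of a collection of nodes."""
        nodes = list(nodes)
        if not nodes:
            raise ValueError("need at least one node")
        common = set(self.lineage_path(nodes[0]))
        for k in nodes[1:]:
            common &= set(self.lineage_path(k))
            if len(common) == 1:
                break
        # deepest node among the common ancestors = last on any root path
        for k in reversed(self.lineage_path(nodes[0])):
            if k in common:
                return k
        raise RuntimeError("lineage record has no common root")  # pragma: no cover

    def sample_genealogy(self, tips) -> tuple[dict[int, int], dict[int, int]]:
        """Reduced genealogy of a set of tip nodes.

        Returns ``(parent_map, branch_mutations)`` over the coalescent
        nodes of the tips: each tip and each node where two tip lineages
        merge, with unary ancestors contracted. ``branch_mutations[k]``
        counts the novel mutations between ``k`` and its reduced parent.
        """
        tips = [int(t) for t in tips]
        visited: dict[int, set[int]] = {}  # node -> children through which tips pass
        on_path: set[int] = set()
        for t in tips:
            path = self.lineage_path(t)
            on_path.update(path)
            for child, par in zip(path[1:], path[:-1]):
                visited.setdefault(par, set()).add(child)
        # coalescent nodes: tips, plus nodes where >= 2 tip lineages merge
        keep = set(tips) | {k for k, ch in visited.items() if len(ch) >= 2}
        root = self.mrca(tips)
        keep.add(root)
        parent_map: dict[int, int] = {}
        branch_mutations: dict[int, int] = {}
        for k in keep:
            if k == root:
                continue
            # walk up accumulating mutations until the next kept ancestor
            p = int(self.parent[k])
            nm = int(self.n_new[k])
            while p not in keep:
                nm += int(self.n_new[p])
                p = int(self.parent[p])
            parent_map[k] = p
            branch_mutations[k] = nm
        return parent_map, branch_mutations


@dataclass(frozen=True)
class BulkSample:
    """A biopsy: member cell nodes and per-mutation cell fractions."""

    sample_id: str
    cells: tuple[int, ...]
    fractions: dict[int, float]
    location: tuple[int, int] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def simulate_tissue(config: SimConfig, rng: np.random.Generator | None = None) -> Tissue:
    """Grow a tissue to ``config.target_cells`` cells, recording lineage."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.mode == "spatial-2D":
        return _simulate_spatial(config, rng)
    return _simulate_well_mixed(config, rng)


def _simulate_well_mixed(config: SimConfig, rng: np.random.Generator) -> Tissue:
    target, beta, muL = config.target_cells, config.beta, config.muL
    alpha = (1.0 - beta) / (1.0 + beta) if config.death == "explicit" else 0.0
    while True:  # restart on extinction (explicit-death mode only)
        parent = [-1]
        n_new = [0]  # founding cell defines the mutation baseline
        mut_start = [0]
        next_mut = 0
        alive = [0]
        n_branch = 0
        n_nonbranch = 0
        extinct = False
        while len(alive) < target:
            idx = rng.integers(len(alive))
            cell = alive[idx]
            if config.death == "explicit":
                # each daughter independently survives with prob 1 - alpha
                n_daughters = int(rng.random() >= alpha) + int(rng.random() >= alpha)
            else:
                n_daughters = 2 if rng.random() < beta else 1
            children = []
            for _ in range(n_daughters):
                nm = int(rng.poisson(muL))
                parent.append(cell)
                n_new.append(nm)
                mut_start.append(next_mut)
                next_mut += nm
                children.append(len(parent) - 1)
            if n_daughters == 2:
                n_branch += 1
                alive[idx] = children[0]
                alive.append(children[1])
            elif n_daughters == 1:
                n_nonbranch += 1
                alive[idx] = children[0]
            else:  # both daughters died; the lineage ends here
                alive[idx] = alive[-1]
                alive.pop()
                if not alive:
                    extinct = True
                    break
        if not extinct:
            return Tissue(
                np.asarray(parent, dtype=np.int64),
                np.asarray(n_new, dtype=np.int64),
                np.asarray(mut_start, dtype=np.int64),
                np.asarray(alive, dtype=np.int64),
                config,
                n_branch,
                n_nonbranch,
            )


def _simulate_spatial(config: SimConfig, rng: np.random.Generator) -> Tissue:
    target, beta, muL = config.target_cells, config.beta, config.muL
    alpha = (1.0 - beta) / (1.0 + beta) if config.death == "explicit" else 0.0
    side = config.grid_side or int(np.ceil(2.5 * np.sqrt(target)))
    if side * side < target:
        raise ValueError(
            f"grid of side {side} cannot hold {target} cells; increase grid_side"
        )
    while True:
        tissue = _spatial_attempt(config, rng, side, alpha)
        if tissue is not None:
            return tissue


def _spatial_attempt(config, rng, side, alpha):
    target, beta, muL = config.target_cells, config.beta, config.muL
    centre = side // 2
    parent = [-1]
    n_new = [0]
    mut_start = [0]
    next_mut = 0
    occupied: dict[tuple[int, int], int] = {(centre, centre): 0}
    pos_of: dict[int, tuple[int, int]] = {0: (centre, centre)}
    # eligible = occupied sites with at least one free neighbour
    eligible = [(centre, centre)]
    eligible_set = {(centre, centre)}
    n_branch = 0
    n_nonbranch = 0

    def free_neighbours(p):
        x, y = p
        out = []
        for dx, dy in _NEIGHBOURS:
            q = (x + dx, y + dy)
            if 0 <= q[0] < side and 0 <= q[1] < side and q not in occupied:
                out.append(q)
        return out

    while len(occupied) < target:
        if not eligible:
            raise RuntimeError(
                f"spatial grid jammed at {len(occupied)} cells before reaching "
                f"{target}; increase grid_side"
            )
        k = rng.integers(len(eligible))
        p = eligible[k]
        free = free_neighbours(p)
        if not free:
            # stale entry: site became enclosed
            eligible_set.discard(p)
            eligible[k] = eligible[-1]
            eligible.pop()
            continue
        cell = occupied[p]
        if config.death == "explicit":
            n_daughters = int(rng.random() >= alpha) + int(rng.random() >= alpha)
        else:
            n_daughters = 2 if rng.random() < beta else 1

        def _new_node(parent_node):
            nonlocal next_mut
            nm = int(rng.poisson(muL))
            parent.append(parent_node)
            n_new.append(nm)
            mut_start.append(next_mut)
            next_mut += nm
            return len(parent) - 1

        if n_daughters == 2:
            n_branch += 1
            c1 = _new_node(cell)
            c2 = _new_node(cell)
            q = free[rng.integers(len(free))]
            occupied[p] = c1
            pos_of.pop(cell, None)
            pos_of[c1] = p
            occupied[q] = c2
            pos_of[c2] = q
            for site in (q,):
                if free_neighbours(site) and site not in eligible_set:
                    eligible.append(site)
                    eligible_set.add(site)
            # neighbours of q may have lost their last free site
            for dx, dy in _NEIGHBOURS:
                nb = (q[0] + dx, q[1] + dy)
                if nb in occupied and nb in eligible_set and not free_neighbours(nb):
                    eligible_set.discard(nb)
                    eligible.remove(nb)
        elif n_daughters == 1:
            n_nonbranch += 1
            c1 = _new_node(cell)
            occupied[p] = c1
            pos_of.pop(cell, None)
            pos_of[c1] = p
        else:  # both daughters died: the site empties
            del occupied[p]
            pos_of.pop(cell, None)
            if p in eligible_set:
                eligible_set.discard(p)
                eligible.remove(p)
            if not occupied:
                return None  # extinction; caller restarts
            # neighbours regain a free site and become eligible again
            for dx, dy in _NEIGHBOURS:
                nb = (p[0] + dx, p[1] + dy)
                if nb in occupied and nb not in eligible_set:
                    eligible.append(nb)
                    eligible_set.add(nb)
    n_nodes = len(parent)
    positions = np.full((n_nodes, 2), -1, dtype=np.int64)
    alive_nodes = []
    for p, node in occupied.items():
        positions[node] = p
        alive_nodes.append(node)
    return Tissue(
        np.asarray(parent, dtype=np.int64),
        np.asarray(n_new, dtype=np.int64),
        np.asarray(mut_start, dtype=np.int64),
        np.asarray(sorted(alive_nodes), dtype=np.int64),
        config,
        n_branch,
        n_nonbranch,
        positions=positions,
    )


def _sample_fractions(tissue: Tissue, cells: list[int]) -> dict[int, float]:
    """Per-mutation carrier fraction over the sampled cells."""
    node_count: dict[int, int] = {}
    for c in cells:
        for k in tissue.lineage_path(c):
            node_count[k] = node_count.get(k, 0) + 1
    n = len(cells)
    fractions: dict[int, float] = {}
    for k, cnt in node_count.items():
        s, nm = int(tissue.mut_start[k]), int(tissue.n_new[k])
        f = cnt / n
        for mut in range(s, s + nm):
            fractions[mut] = f
    return fractions


def take_samples(
    tissue: Tissue,
    n_samples: int,
    cells_per_sample: int = 1,
    strategy: str = "maximal-distance",
    rng: np.random.Generator | None = None,
) -> list[BulkSample]:
    """Draw biopsies from the final tissue.

    In spatial mode a sample is a contiguous patch grown around a centre;
    ``maximal-distance`` places centres by greedy farthest-point selection
    (the multi-region sampling design), ``random`` places them uniformly.
    In well-mixed mode samples are disjoint uniform subsets of live cells.
    """
    if rng is None:
        rng = np.random.default_rng(tissue.config.seed + 1)
    if strategy not in ("maximal-distance", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if n_samples * cells_per_sample > tissue.n_cells:
        raise ValueError(
            f"{n_samples} x {cells_per_sample} cells requested but only "
            f"{tissue.n_cells} alive"
        )
    if tissue.positions is None:
        chosen = rng.choice(tissue.alive, size=n_samples * cells_per_sample, replace=False)
        groups = chosen.reshape(n_samples, cells_per_sample)
        return [
            BulkSample(
                sample_id=f"S{j:03d}",
                cells=tuple(int(c) for c in groups[j]),
                fractions=_sample_fractions(tissue, list(groups[j])),
            )
            for j in range(n_samples)
        ]
    return _take_spatial_samples(tissue, n_samples, cells_per_sample, strategy, rng)


def _take_spatial_samples(tissue, n_samples, cells_per_sample, strategy, rng):
    pos = {tuple(tissue.positions[c]): int(c) for c in tissue.alive}
    coords = np.array(sorted(pos))
    if strategy == "random":
        centres = coords[rng.choice(len(coords), size=n_samples, replace=False)]
    else:
        # greedy farthest-point: start from a random cell, then repeatedly
        # add the cell maximising its distance to the chosen centres
        first = coords[rng.integers(len(coords))]
        centres = [first]
        d2 = np.sum((coords - first) ** 2, axis=1)
        for _ in range(n_samples - 1):
            nxt = coords[int(np.argmax(d2))]
            centres.append(nxt)
            d2 = np.minimum(d2, np.sum((coords - nxt) ** 2, axis=1))
        centres = np.array(centres)
    samples = []
    taken: set[tuple[int, int]] = set()
    for j, centre in enumerate(centres):
        patch = _grow_patch(pos, tuple(centre), cells_per_sample, taken)
        if len(patch) < cells_per_sample:
            raise RuntimeError(
                f"could not grow a contiguous patch of {cells_per_sample} cells"
            )
        taken |= set(patch)
        cells = [pos[p] for p in patch]
        samples.append(
            BulkSample(
                sample_id=f"S{j:03d}",
                cells=tuple(cells),
                fractions=_sample_fractions(tissue, cells),
                location=tuple(int(v) for v in centre),
            )
        )
    return samples


def _grow_patch(pos, centre, size, taken):
    """Breadth-first contiguous patch of occupied, untaken sites."""
    if centre not in pos or centre in taken:
        # fall back to nearest available occupied site
        avail = [p for p in pos if p not in taken]
        if not avail:
            return []
        centre = min(avail, key=lambda p: (p[0] - centre[0]) ** 2 + (p[1] - centre[1]) ** 2)
    patch = [centre]
    seen = {centre}
    queue = [centre]
    while queue and len(patch) < size:
        x, y = queue.pop(0)
        for dx, dy in _NEIGHBOURS:
            q = (x + dx, y + dy)
            if q in pos and q not in seen and q not in taken:
                seen.add(q)
                patch.append(q)
                queue.append(q)
                if len(patch) == size:
                    break
    return patch


def sequencing_noise(
    sample: BulkSample,
    seq: SeqConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthesise a noisy read-count table for one biopsy.

    Per mutation: depth ``k ~ Poisson(mean_depth)`` and variant reads
    ``~ Binomial(k, f)`` where ``f`` is the fraction of sampled cells
    carrying the mutation (halved when ``diploid`` is set, modelling a
    heterozygous variant). Rows with zero depth keep a missing VAF.
    """
    muts = sorted(sample.fractions)
    f = np.array([sample.fractions[m] for m in muts], dtype=float)
    if seq.diploid:
        f = f / 2.0
    depth = rng.poisson(seq.mean_depth, size=len(muts))
    alt = rng.binomial(depth, f)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    return pd.DataFrame(
        {
            "mutation": muts,
            "depth": depth,
            "alt_reads": alt,
            "vaf": vaf,
            "sample": sample.sample_id,
        }
    )


def clonal_profile(table: pd.DataFrame, seq: SeqConfig) -> SampleProfile:
    """Call the sample's clonal (MRCA) genotype from a noisy variant table.

    A mutation is clonal when its observed VAF reaches the threshold
    (halved threshold under the diploid flag, matching the halved
    expected VAF of a clonal heterozygous variant).
    """
    if table.empty:
        raise ValueError("variant table is empty")
    thr = seq.clonal_vaf_threshold / 2.0 if seq.diploid else seq.clonal_vaf_threshold
    called = table[(table["depth"] > 0) & (table["vaf"] >= thr)]
    sid = str(table["sample"].iloc[0]) if "sample" in table else "sample"
    return SampleProfile(sid, frozenset(called["mutation"].tolist()))


def true_sample_profile(tissue: Tissue, sample: BulkSample) -> SampleProfile:
    """Exact MRCA genotype of a biopsy from the lineage record."""
    mrca = tissue.mrca(sample.cells)
    return SampleProfile(sample.sample_id, tissue.mutation_set(mrca))


def sample_genealogy_newick(tissue: Tissue, samples: list[BulkSample]) -> str:
    """Newick genealogy of the samples' MRCA cells.

    Branch lengths are integer mutation counts; tips are labelled with
    sample ids (joined with ``|`` when samples share an MRCA cell).
    """
    tip_labels: dict[int, list[str]] = {}
    for s in samples:
        node = tissue.mrca(s.cells)
        tip_labels.setdefault(node, []).append(s.sample_id)
    tips = sorted(tip_labels)
    if len(tips) == 1:
        only = tips[0]
        return f"{'|'.join(tip_labels[only])}:0;"
    parent_map, branch = tissue.sample_genealogy(tips)
    children: dict[int, list[int]] = {}
    for k, p in parent_map.items():
        children.setdefault(p, []).append(k)
    root = tissue.mrca(tips)

    def render(node: int) -> str:
        label = "|".join(tip_labels.get(node, []))
        kids = sorted(children.get(node, []))
        inner = f"({','.join(render(c) for c in kids)})" if kids else ""
        length = f":{branch[node]}" if node in branch else ""
        return f"{inner}{label}{length}"

    return render(root) + ";"


def ground_truth_distances(
    tissue: Tissue,
    samples: list[BulkSample],
    max_branchings: int | None = None,
    include_terminal: bool | None = None,
) -> DistanceHistogram:
    """Noise-free mutational-distance histogram from the lineage record.

    Computes each sample's exact MRCA genotype and builds the per-event
    sibling-distance histogram (see
    :func:`mutdist.distances.build_histogram`). ``max_branchings``
    optionally restricts to the earliest branching events.
    ``include_terminal=None`` resolves to False for single-cell samples —
    whose terminal branches span the tissue's whole remaining growth
    rather than one branching interval — and True for bulk samples,
    whose profiles are already ancestral genotypes.
    """
    for s in samples:
        if np.max(s.cells) >= tissue.n_nodes:
            raise ValueError(f"sample {s.sample_id} references unknown cells")
    if include_terminal is None:
        include_terminal = any(len(s.cells) > 1 for s in samples)
    profiles = [true_sample_profile(tissue, s) for s in samples]
    return build_histogram(
        profiles, max_branchings=max_branchings, include_terminal=include_terminal
    )
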