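"""The complete quad-tree of transitions and consecutive-path statistics.

Every transition prefix+base of order k is an edge on level k+1 of a
complete 4-ary tree: nodes are k-mers (the root is the empty string) and
the edge for transition w -> b connects node w to node wb.  Consecutively
favored/disfavored paths (CFPs/CDPs) are parent-to-child chains of at least
two selected edges; the enrichment test compares the fraction of selected
edges covered by such chains against level-preserving random reselections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._alphabet import BASES, kmer_to_code
from .transitions import Transition, as_transition, enumerate_transitions


@dataclass(frozen=True)
class QuadTree:
    """Complete quad-tree of height ``max_order + 1``.

    Nodes are all k-mers for k = 0..height (k = 0 is the empty-string
    root); the edge set is exactly the enumerated transitions, transition
    order k sitting on level k+1.
    """

    max_order: int

    @property
    def height(self) -> int:
        return self.max_order + 1

    @property
    def n_nodes(self) -> int:
        return 1 + sum(4**lv for lv in range(1, self.height + 1))

    @property
    def n_edges(self) -> int:
        return sum(4**lv for lv in range(1, self.height + 1))

    def edges(self) -> list[Transition]:
        return enumerate_transitions(self.max_order)

    def level_size(self, level: int) -> int:
        if not 1 <= level <= self.height:
            raise ValueError(f"level must be in 1..{self.height}")
        return 4**level

    @staticmethod
    def parent(node: str) -> str:
        """Parent of a node (its k-mer minus the last base)."""
        if not node:
            raise ValueError("the root has no parent")
        return node[:-1]

    def contains_edge(self, t: Transition | str) -> bool:
        return as_transition(t).level <= self.height


def build_tree(max_order: int) -> QuadTree:
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    return QuadTree(max_order)


@dataclass
class Run:
    """One maximal consecutive run of selected edges (top to bottom)."""

    words: tuple[str, ...]

    @property
    def start_level(self) -> int:
        return len(self.words[0])

    @property
    def end_level(self) -> int:
        return len(self.words[-1])

    @property
    def length(self) -> int:
        return len(self.words)

    @property
    def spelling(self) -> str:
        """The k-mer spelled by the run's deepest node."""
        return self.words[-1]


@dataclass
class PathSet:
    """Maximal runs plus the covered-edge statistics.

    ``covered`` holds every selected edge lying on at least one run of
    length >= min_len (edges shared by several runs counted once);
    ``fraction_in_paths`` = |covered| / |selected|.
    """

    runs: list[Run]
    covered: frozenset[str]
    n_selected: int
    min_len: int

    @property
    def fraction_in_paths(self) -> float:
        return len(self.covered) / self.n_selected if self.n_selected else 0.0

    def full_length_runs(self, height: int) -> list[Run]:
        """Runs spanning levels 1..height; each spells one height-mer."""
        return [r for r in self.runs
                if r.start_level == 1 and r.end_level == height]


def _normalise_selected(selected: Iterable) -> set[str]:
    return {as_transition(t).word for t in selected}


def find_consecutive_paths(tree: QuadTree, selected: Iterable,
                           min_len: int = 2) -> PathSet:
    """Maximal consecutive runs within a selected edge set.

    A run is a chain of selected edges along parent-to-child tree edges;
    maximal runs are enumerated leaf-upwards (two runs may share their
    upper edges, as sibling branches do).  Runs shorter than ``min_len``
    are not reported and their edges are not covered.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2 (a path connects edges)")
    words = _normalise_selected(selected)
    for w in words:
        if len(w) > tree.height:
            raise ValueError(f"edge {w!r} lies outside a height-{tree.height} tree")
    # chain depth above (inclusive) — process shallow to deep
    depth: dict[str, int] = {}
    for w in sorted(words, key=len):
        parent_edge = w[:-1]
        depth[w] = depth[parent_edge] + 1 if parent_edge in words else 1
    # chain height below (inclusive) — process deep to shallow
    below: dict[str, int] = {}
    for w in sorted(words, key=len, reverse=True):
        kids = [below[w + b] for b in BASES if w + b in words]
        below[w] = 1 + max(kids) if kids else 1
    covered = frozenset(
        w for w in words if depth[w] + below[w] - 1 >= min_len
    )
    runs: list[Run] = []
    leaves = [w for w in words if not any(w + b in words for b in BASES)]
    for leaf in sorted(leaves, key=lambda w: (len(w), w)):
        chain = [leaf]
        while chain[-1][:-1] in words:
            chain.append(chain[-1][:-1])
        if len(chain) >= min_len:
            runs.append(Run(tuple(reversed(chain))))
    return PathSet(runs=runs, covered=covered, n_selected=len(words),
                   min_len=min_len)


def _covered_count_batch(sel: list[np.ndarray], min_len: int) -> np.ndarray:
    """Covered-edge counts for a batch of selections.

    ``sel[L-1]``: boolean (B, 4**L) selection on level L.  Chain depth and
    height are propagated level-wise; an edge is covered when the maximal
    chain through it reaches min_len.
    """
    H = len(sel)
    B = sel[0].shape[0]
    depth = [None] * H
    for L in range(H):
        d = sel[L].astype(np.int16)
        if L > 0:
            d += sel[L] * np.repeat(depth[L - 1], 4, axis=1)
        depth[L] = d
    below = [None] * H
    for L in range(H - 1, -1, -1):
        h = sel[L].astype(np.int16)
        if L + 1 < H:
            kids = below[L + 1].reshape(B, -1, 4).max(axis=2)
            h += sel[L] * kids
        below[L] = h
    total = np.zeros(B, dtype=np.int64)
    for L in range(H):
        total += np.sum(sel[L] & (depth[L] + below[L] - 1 >= min_len), axis=1)
    return total


def _sample_level_batch(rng: np.random.Generator, B: int, size: int,
                        count: int) -> np.ndarray:
    """B independent uniform draws of ``count`` of ``size`` items, as a
    boolean (B, size) mask (without replacement within a draw)."""
    out = np.zeros((B, size), dtype=bool)
    if count == 0:
        return out
    if count == size:
        out[:] = True
        return out
    r = rng.random((B, size))
    idx = np.argpartition(r, count - 1, axis=1)[:, :count]
    np.put_along_axis(out, idx, True, axis=1)
    return out


def path_enrichment_test(tree: QuadTree, selected: Iterable,
                         n_perm: int = 1_000_000, seed: int = 0,
                         min_len: int = 2, add_one: bool = False,
                         batch_size: int = 2048
                         ) -> tuple[float, float]:
    """Level-preserving permutation test of the covered-path fraction.

    Each permutation re-selects, uniformly without replacement within each
    level, the same number of edges per level as observed, and recomputes
    the fraction of selected edges covered by runs of length >= min_len.
    Returns (observed fraction, empirical P) with P the fraction of
    permutations reaching an equal or higher covered fraction (r/n rule;
    (r+1)/(n+1) behind ``add_one``).
    """
    words = _normalise_selected(selected)
    if not words:
        raise ValueError("selected edge set must be non-empty")
    obs = find_consecutive_paths(tree, words, min_len=min_len)
    obs_covered = len(obs.covered)
    H = tree.height
    counts = [sum(1 for w in words if len(w) == L) for L in range(1, H + 1)]
    rng = np.random.default_rng(seed)
    n_hits = 0
    done = 0
    while done < n_perm:
        B = min(batch_size, n_perm - done)
        sel = [
            _sample_level_batch(rng, B, 4**L, counts[L - 1])
            for L in range(1, H + 1)
        ]
        cov = _covered_count_batch(sel, min_len)
        n_hits += int(np.sum(cov >= obs_covered))
        done += B
    if add_one:
        p = (n_hits + 1) / (n_perm + 1)
    else:
        p = n_hits / n_perm
    return obs.fraction_in_paths, p


def to_dot(tree: QuadTree, favored: Iterable = (), disfavored: Iterable = (),
           max_level: int | None = None) -> str:
    """DOT export of the (possibly truncated) tree, favored edges red and
    disfavored edges green."""
    fav = _normalise_selected(favored)
    dis = _normalise_selected(disfavored)
    H = min(tree.height, max_level or tree.height)
    lines = ["digraph quadtree {", '  node [shape=point];',
             '  root [label="", shape=circle];']

    def node_name(w: str) -> str:
        return "root" if w == "" else f"n_{w}"

    frontier = [""]
    for _ in range(H):
        nxt = []
        for w in frontier:
            for b in BASES:
                child = w + b
                color = ("red" if child in fav
                         else "green" if child in dis else "gray")
                lines.append(
                    f'  {node_name(w)} -> {node_name(child)} '
                    f'[color={color}];'
                )
                nxt.append(child)
        frontier = nxt
    lines.append("}")
    return "\n".join(lines)
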