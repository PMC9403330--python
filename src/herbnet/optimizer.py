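"""Exact top-F search over compositions of exactly k plants.

The search space is the C(T, k) subsets of the T plants.  A complete search
scores every subset; the branch-and-bound search explores a tree of partial
selections and prunes any branch whose optimistic bound cannot beat the
currently retained F-th best score, while provably returning the same ranked
top-F list as the complete search.

Three node-ordering strategies are provided — breadth-first (FIFO queue),
depth-first (stack, include-branch first), and best-first (priority queue
keyed on the bound) — combined with two branching schemes: *binary* (each
node spawns an include child and an exclude child for the next plant in
sorted order) and *wide* (each node spawns one child per still-eligible plant
index, enumerating combinations directly).

Bound: with plants sorted by descending standalone value, a node with profit
``p`` and ``r`` slots left can gain at most the sum of the ``r`` largest
remaining standalone values, because the score is subadditive (each added
plant contributes at most its own total value).

Pruning threshold: candidates are retained in a bounded top-F structure;
a branch is pruned only when its bound is *strictly below* the F-th best
retained score.  Bounds equal to the threshold are kept so that score ties at
the cut-off resolve by the same deterministic rule (lexicographically
smallest plant set preferred) in every strategy, keeping all strategies
byte-identical to the complete search.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from collections import deque
from dataclasses import dataclass, field
from math import comb, inf
from typing import Iterable, Mapping

from .network_model import ValidationError
from .scoring import FormulaCandidate, as_profile_map, make_candidate, plant_total_value
from .traversal import PlantProteinProfile

__all__ = [
    "SearchConfig",
    "SearchNode",
    "SearchResult",
    "TopFQueue",
    "sort_plants",
    "bound",
    "branch_and_bound",
    "complete_search",
    "dominance_filter",
]

STRATEGIES = ("brfs", "dfs", "bfs", "complete")
BRANCHINGS = ("binary", "wide")


@dataclass
class SearchConfig:
    """Parameters of one top-F composition search.

    k: exact number of plants per composition; top_f: candidates retained;
    strategy: node-ordering scheme ('complete' disables pruning entirely);
    branching: 'binary' or 'wide' ('wide' only with brfs, the pairing the
    method was designed for); dominance_filter: drop dominated plants first;
    max_nodes: guard on C(T, k) for the complete search; bfs_key: ordering
    key of the best-first queue ('bound' or 'profit').
    """

    k: int
    top_f: int = 10
    strategy: str = "brfs"
    branching: str = "binary"
    dominance_filter: bool = False
    seed: int | None = None
    max_nodes: int = 10_000_000
    bfs_key: str = "bound"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.top_f < 1:
            raise ValidationError("top_f must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.branching not in BRANCHINGS:
            raise ValidationError(f"unknown branching {self.branching!r}")
        if self.branching == "wide" and self.strategy not in ("brfs", "complete"):
            raise ValidationError("wide branching is only supported with brfs")
        if self.bfs_key not in ("bound", "profit"):
            raise ValidationError(f"unknown bfs_key {self.bfs_key!r}")


@dataclass
class SearchNode:
    """A partial selection: chosen plant indices (ascending) plus its bound."""

    chosen: tuple[int, ...]
    level: int  # next index eligible for inclusion
    profit: float
    bound: float

    @property
    def weight(self) -> int:
        return len(self.chosen)


@dataclass
class SearchResult:
    candidates: list[FormulaCandidate]
    nodes_generated: int
    nodes_pruned: int

    @property
    def scores(self) -> list[float]:
        return [c.score for c in self.candidates]


class _Entry:
    """Heap entry ordered worst-first: lower score, then lexicographically
    larger plant set, is 'smaller' (popped first)."""

    __slots__ = ("score", "plants", "candidate")

    def __init__(self, candidate: FormulaCandidate) -> None:
        self.score = candidate.score
        self.plants = candidate.plants
        self.candidate = candidate

    def __lt__(self, other: "_Entry") -> bool:
        if self.score != other.score:
            return self.score < other.score
        return self.plants > other.plants


class TopFQueue:
    """Bounded min-heap retaining the F best candidates seen so far.

    Score ties are broken toward the lexicographically smallest plant set, a
    total order, so the retained set is independent of insertion order.
    """

    def __init__(self, top_f: int) -> None:
        if top_f < 1:
            raise ValidationError("top_f must be >= 1")
        self.top_f = top_f
        self._heap: list[_Entry] = []

    def __len__(self) -> int:
        return len(self._heap)

    @property
    def full(self) -> bool:
        return len(self._heap) >= self.top_f

    @property
    def worst_retained(self) -> float:
        """Score of the current F-th best candidate; -inf until full."""
        return self._heap[0].score if self.full else -inf

    def offer(self, candidate: FormulaCandidate) -> None:
        entry = _Entry(candidate)
        if not self.full:
            heapq.heappush(self._heap, entry)
        elif self._heap[0] < entry:
            heapq.heapreplace(self._heap, entry)

    def ranked(self) -> list[FormulaCandidate]:
        """Best-first: descending score, ties by ascending plant set."""
        return [
            e.candidate
            for e in sorted(self._heap, key=lambda e: (-e.score, e.plants))
        ]


def sort_plants(
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
) -> list[str]:
    """Plant ids by descending standalone value, ties lexicographic."""
    pmap = as_profile_map(profiles)
    if not pmap:
        raise ValidationError("no plant profiles to sort")
    return sorted(pmap, key=lambda pid: (-pmap[pid].total_value, pid))


def bound(
    node: SearchNode,
    order: list[str],
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
    k: int,
) -> float:
    """Optimistic completion bound of a partial selection.

    profit + the sum of the (k - weight) largest standalone values among the
    still-eligible plants (indices >= node.level in descending-value order);
    -inf when too few plants remain to complete the composition.
    """
    pmap = as_profile_map(profiles)
    r = k - node.weight
    eligible = order[node.level :]
    if len(eligible) < r:
        return -inf
    return node.profit + sum(plant_total_value(pmap[p]) for p in eligible[:r])


def _search_core(
    pmap: dict[str, PlantProteinProfile], cfg: SearchConfig
) -> SearchResult:
    order = sort_plants(pmap)
    T = len(order)
    k = cfg.k
    totals = [plant_total_value(pmap[p]) for p in order]
    prefix = [0.0]
    for t in totals:
        prefix.append(prefix[-1] + t)

    def cbound(profit: float, start: int, r: int) -> float:
        if T - start < r:
            return -inf
        return profit + prefix[start + r] - prefix[start]

    def score_of(idx: tuple[int, ...]) -> float:
        merged: dict[str, float] = {}
        weights: dict[str, float] = {}
        for i in idx:
            for pid, (_, pw, ew) in pmap[order[i]].proteins.items():
                if ew > merged.get(pid, 0.0):
                    merged[pid] = ew
                    weights[pid] = pw
        return sum(weights[pid] * ew for pid, ew in merged.items())

    topf = TopFQueue(cfg.top_f)
    generated = 0
    pruned = 0

    def keep(b: float) -> bool:
        # prune only strictly below the F-th best: equal-bound branches may
        # still hold a tie that wins on the lexicographic rule
        return b >= topf.worst_retained

    def offer(idx: tuple[int, ...], profit: float) -> None:
        cand = make_candidate([order[i] for i in idx], pmap)
        # make_candidate recomputes the score; trust the incremental profit
        topf.offer(
            FormulaCandidate(cand.plants, profit, cand.covered, cand.proteins)
        )

    if cfg.branching == "binary":
        root = SearchNode((), 0, 0.0, cbound(0.0, 0, k))
        generated += 1
        container: deque | list
        if cfg.strategy == "brfs":
            container = deque([root])
            pop = container.popleft
            push = container.append
        elif cfg.strategy == "dfs":
            container = [root]
            pop = container.pop
            push = container.append
        else:  # bfs: best-first priority queue
            tick = itertools.count()
            heap: list[tuple[float, int, SearchNode]] = []

            def _key(n: SearchNode) -> float:
                return n.bound if cfg.bfs_key == "bound" else n.profit

            heapq.heappush(heap, (-_key(root), next(tick), root))

            def pop() -> SearchNode:
                return heapq.heappop(heap)[2]

            def push(n: SearchNode) -> None:
                heapq.heappush(heap, (-_key(n), next(tick), n))

            container = heap

        while container:
            node = pop()
            if not keep(node.bound):
                pruned += 1
                continue
            lvl = node.level
            if lvl >= T:
                continue
            children = []
            # include child
            chosen2 = node.chosen + (lvl,)
            profit2 = score_of(chosen2)
            generated += 1
            if len(chosen2) == k:
                offer(chosen2, profit2)
            else:
                b2 = cbound(profit2, lvl + 1, k - len(chosen2))
                if keep(b2):
                    children.append(SearchNode(chosen2, lvl + 1, profit2, b2))
                else:
                    pruned += 1
            # exclude child
            generated += 1
            b3 = cbound(node.profit, lvl + 1, k - node.weight)
            if keep(b3):
                children.append(SearchNode(node.chosen, lvl + 1, node.profit, b3))
            else:
                pruned += 1
            if cfg.strategy == "dfs":
                # push exclude first so the include branch is explored first
                children.reverse()
            for child in children:
                push(child)
    else:  # wide branching with breadth-first order
        queue: deque[SearchNode] = deque()
        root = SearchNode((), 0, 0.0, cbound(0.0, 0, k))
        generated += 1
        queue.append(root)
        while queue:
            node = queue.popleft()
            if not keep(node.bound):
                pruned += 1
                continue
            w = node.weight
            for j in range(node.level, T):
                chosen2 = node.chosen + (j,)
                profit2 = score_of(chosen2)
                generated += 1
                if w + 1 == k:
                    offer(chosen2, profit2)
                else:
                    b2 = cbound(profit2, j + 1, k - w - 1)
                    if keep(b2):
                        queue.append(SearchNode(chosen2, j + 1, profit2, b2))
                    else:
                        pruned += 1

    return SearchResult(topf.ranked(), generated, pruned)


def _prepare(
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
    cfg: SearchConfig,
) -> dict[str, PlantProteinProfile]:
    pmap = as_profile_map(profiles)
    if cfg.dominance_filter:
        pmap = as_profile_map(dominance_filter(list(pmap.values()), k=cfg.k))
    if cfg.k > len(pmap):
        raise ValidationError(
            f"k={cfg.k} exceeds the {len(pmap)} available plant profiles"
        )
    return pmap


def branch_and_bound(
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
    cfg: SearchConfig,
) -> SearchResult:
    """Top-F compositions of exactly k plants, exact but pruned.

    Returns the same ranked candidate list as :func:`complete_search` for
    every strategy/branching combination, with telemetry on how many search
    nodes were generated and pruned.
    """
    pmap = _prepare(profiles, cfg)
    if cfg.strategy == "complete":
        return _complete(pmap, cfg)
    return _search_core(pmap, cfg)


def complete_search(
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
    cfg: SearchConfig,
) -> SearchResult:
    """Score every k-subset without pruning (the reference baseline)."""
    return _complete(_prepare(profiles, cfg), cfg)


def _complete(pmap: dict[str, PlantProteinProfile], cfg: SearchConfig) -> SearchResult:
    order = sort_plants(pmap)
    T = len(order)
    n_subsets = comb(T, cfg.k)
    if n_subsets > cfg.max_nodes:
        raise ValidationError(
            f"complete search over C({T},{cfg.k})={n_subsets} subsets exceeds "
            f"max_nodes={cfg.max_nodes}"
        )
    topf = TopFQueue(cfg.top_f)
    for idx in itertools.combinations(range(T), cfg.k):
        merged: dict[str, float] = {}
        weights: dict[str, float] = {}
        for i in idx:
            for pid, (_, pw, ew) in pmap[order[i]].proteins.items():
                if ew > merged.get(pid, 0.0):
                    merged[pid] = ew
                    weights[pid] = pw
        profit = sum(weights[pid] * ew for pid, ew in merged.items())
        cand = make_candidate([order[i] for i in idx], pmap)
        topf.offer(FormulaCandidate(cand.plants, profit, cand.covered, cand.proteins))
    return SearchResult(topf.ranked(), n_subsets, 0)


def _dominates(
    y: PlantProteinProfile, x: PlantProteinProfile
) -> bool:
    """True when y covers every protein of x at >= x's edge weight."""
    for pid, (_, _, ew_x) in x.proteins.items():
        rec = y.proteins.get(pid)
        if rec is None or rec[2] < ew_x:
            return False
    return True


def dominance_filter(
    profiles: Mapping[str, PlantProteinProfile] | Iterable[PlantProteinProfile],
    *,
    k: int | None = None,
) -> list[PlantProteinProfile]:
    """Drop plants whose coverage is element-wise dominated by another plant.

    A dominated plant can always be swapped for its dominator without
    lowering any set's score, so the top-1 optimum over k-subsets is
    unchanged.  Exact duplicates keep the lexicographically smallest id.
    If fewer than ``k`` plants would survive, filtering is skipped with a
    warning.
    """
    pmap = as_profile_map(profiles)
    ids = sorted(pmap)
    kept = []
    for x in ids:
        dominated = False
        for y in ids:
            if y == x or not _dominates(pmap[y], pmap[x]):
                continue
            if _dominates(pmap[x], pmap[y]):
                # mutual domination = identical coverage: keep the smaller id
                if y < x:
                    dominated = True
                    break
            else:
                dominated = True
                break
        if not dominated:
            kept.append(pmap[x])
    if k is not None and len(kept) < k:
        warnings.warn(
            f"dominance filter would leave {len(kept)} < k={k} plants; skipped"
        )
        return [pmap[i] for i in ids]
    return kept
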