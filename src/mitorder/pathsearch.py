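"""Exhaustive k-path enumeration and exact rearrangement distances.

The engine is a depth-first backtracking search over evolutionary scenarios:
a k-path between genomes G and G' is a sequence of k single rearrangements
turning G into G'.  At every node a three-valued test decides whether the
current partial path is a solution (YES), provably cannot be extended into
one (NO), or needs further exploration (INDETERMINATE).  Two admissible
pruning rules keep the search tractable without losing completeness:

* shared-block pruning (HT1): rearrangements whose cuts would sever an
  adjacency shared between the current genome and the target are skipped.
  Some valid paths are pruned, but at least one cut-free minimal path always
  survives, so distances are unaffected.
* breakpoint lower bound (HT2): one rearrangement removes at most three
  breakpoints, so a genome with more than ``3 * (steps remaining)``
  breakpoints against the target can be abandoned.

The exact distance is obtained by iterative deepening: k-path searches at
k = 0, 1, 2, ... until the first k with a solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genome import Genome, GenomeError, canonical_array, decode, encode
from .rearrangements import _neighbor_arrays, nb_breakpoints

__all__ = [
    "TestResult",
    "SearchState",
    "SearchBudgetExceeded",
    "Path",
    "heuristic_test",
    "enumerate_k_paths",
    "distance",
    "enumerate_minimal_paths",
    "is_path",
    "path_has_cut",
]

DEFAULT_K_MAX = 8


class TestResult(Enum):
    YES = "YES"
    NO = "NO"
    INDETERMINATE = "INDETERMINATE"


class SearchBudgetExceeded(RuntimeError):
    """The distance exceeds the search budget; never a wrong value."""

    def __init__(self, k_max: int):
        super().__init__(f"no path of length <= {k_max} found")
        self.k_max = k_max


@dataclass(frozen=True)
class SearchState:
    """Snapshot of the backtracking search: a path from the source to
    ``current`` in ``steps_used`` steps, with ``budget`` total steps."""

    current: Genome
    target: Genome
    steps_used: int
    budget: int
    use_ht1: bool = True
    use_ht2: bool = True

    def __post_init__(self):
        if not (0 <= self.steps_used <= self.budget):
            raise ValueError("steps_used must lie in [0, budget]")


@dataclass(frozen=True)
class Path:
    """A sequence of genomes, consecutive ones a single rearrangement apart."""

    genomes: tuple[Genome, ...]

    @property
    def length(self) -> int:
        return len(self.genomes) - 1

    def __iter__(self):
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, i):
        return self.genomes[i]

    def reversed(self) -> "Path":
        return Path(tuple(reversed(self.genomes)))


def heuristic_test(state: SearchState) -> TestResult:
    """Classify a partial path: YES (a solution), NO (a dead end), or
    INDETERMINATE.

    Dead ends: the budget is spent away from the target; the target was
    reached early (no rearrangement is a no-op, so the path cannot linger);
    or, with HT2, the breakpoint count exceeds three per remaining step.
    """
    at_target = state.current == state.target
    remaining = state.budget - state.steps_used
    if at_target:
        return TestResult.YES if remaining == 0 else TestResult.NO
    if remaining == 0:
        return TestResult.NO
    if state.use_ht2:
        if nb_breakpoints(state.current, state.target) > 3 * remaining:
            return TestResult.NO
    return TestResult.INDETERMINATE


class _Engine:
    """Array-level search context for one genome pair."""

    def __init__(self, source: Genome, target: Genome, use_ht1: bool, use_ht2: bool):
        if source.circular != target.circular:
            raise GenomeError("cannot mix topologies")
        if source.gene_set != target.gene_set:
            raise GenomeError("path search requires identical gene sets")
        self.circular = source.circular
        self.order = sorted(source.gene_set)
        self.n = source.n
        self.x0 = encode(source, self.order)
        self.t = encode(target, self.order)
        self.use_ht1 = use_ht1
        self.use_ht2 = use_ht2
        n = self.n
        succ = np.zeros(2 * n + 1, dtype=np.int64)
        self._succ_valid = np.zeros(2 * n + 1, dtype=bool)
        pairs = list(zip(self.t, self.t[1:]))
        if self.circular:
            pairs.append((self.t[-1], self.t[0]))
        for a, b in pairs:
            succ[int(a) + n] = int(b)
            self._succ_valid[int(a) + n] = True
            succ[-int(b) + n] = -int(a)
            self._succ_valid[-int(b) + n] = True
        self.succ = succ

    def _shared_mask(self, x: np.ndarray) -> np.ndarray:
        """shared[i] is True when the adjacency after position i is present
        in the target (i.e. not a breakpoint)."""
        n = self.n
        if self.circular:
            nxt = np.roll(x, -1)
            idx = x + n
            return self._succ_valid[idx] & (self.succ[idx] == nxt)
        idx = x[:-1] + n
        return self._succ_valid[idx] & (self.succ[idx] == x[1:])

    def bp(self, x: np.ndarray) -> int:
        mask = self._shared_mask(x)
        total = self.n if self.circular else self.n - 1
        return total - int(mask.sum())

    def _children(self, x: np.ndarray, remaining_after: int):
        """Deduplicated viable children of x with ``remaining_after`` steps
        left after the move, in canonical order."""
        shared = self._shared_mask(x)
        cand: dict[bytes, tuple[np.ndarray, int]] = {}
        for child, cuts in _neighbor_arrays(x, self.circular):
            if self.use_ht1 and any(shared[c] for c in cuts):
                continue
            bpc = self.bp(child)
            if bpc == 0:
                if remaining_after != 0:
                    continue  # a path never revisits the target
            else:
                if remaining_after == 0:
                    continue
                if self.use_ht2 and bpc > 3 * remaining_after:
                    continue
            key = canonical_array(child, self.circular).tobytes()
            if key not in cand:
                cand[key] = (child, bpc)
        return [cand[k] for k in sorted(cand)]

    def search(self, k: int, collect_all: bool):
        """All k-paths from source to target (or the first one found when
        ``collect_all`` is false)."""
        results: list[list[np.ndarray]] = []
        bp0 = self.bp(self.x0)
        if bp0 == 0:
            return [[self.x0]] if k == 0 else []
        if k == 0:
            return []
        if self.use_ht2 and bp0 > 3 * k:
            return []
        seq = [self.x0]

        def rec(x: np.ndarray, r: int) -> bool:
            for child, bpc in self._children(x, k - r - 1):
                seq.append(child)
                if bpc == 0:  # r + 1 == k here: a solution
                    results.append([a.copy() for a in seq])
                    seq.pop()
                    if not collect_all:
                        return True
                    continue
                done = rec(child, r + 1)
                seq.pop()
                if done:
                    return True
            return False

        rec(self.x0, 0)
        return results

    def to_path(self, seq) -> Path:
        return Path(tuple(decode(a, self.order, self.circular) for a in seq))


def enumerate_k_paths(
    source: Genome,
    target: Genome,
    k: int,
    use_ht1: bool = True,
    use_ht2: bool = True,
) -> list[Path]:
    """Complete enumeration of the k-paths from ``source`` to ``target``.

    Paths are genome sequences: operation parameter choices that produce the
    same intermediate genomes count as one path.  With ``use_ht1`` some valid
    paths may be pruned (never all minimal ones); with ``use_ht1=False`` the
    enumeration is exhaustive, as required for ancestral inference.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    eng = _Engine(source, target, use_ht1, use_ht2)
    return [eng.to_path(seq) for seq in eng.search(k, collect_all=True)]


def distance(
    source: Genome,
    target: Genome,
    k_max: int = DEFAULT_K_MAX,
    use_ht1: bool = True,
    use_ht2: bool = True,
) -> int:
    """Exact minimal path length by iterative deepening.

    Raises :class:`SearchBudgetExceeded` when the distance exceeds ``k_max``;
    the heuristics prune work but never change the result.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    eng = _Engine(source, target, use_ht1, use_ht2)
    if eng.bp(eng.x0) == 0:
        return 0
    for k in range(1, k_max + 1):
        if eng.search(k, collect_all=False):
            return k
    raise SearchBudgetExceeded(k_max)


def enumerate_minimal_paths(
    source: Genome,
    target: Genome,
    use_ht1: bool = False,
    k_max: int = DEFAULT_K_MAX,
) -> list[Path]:
    """All minimal paths between two genomes.

    Ancestral-state inference requires the exhaustive set, hence shared-block
    pruning is off by default here.
    """
    d = distance(source, target, k_max=k_max, use_ht1=use_ht1, use_ht2=True)
    return enumerate_k_paths(source, target, d, use_ht1=use_ht1, use_ht2=True)


# -- path predicates -------------------------------------------------------


def is_path(genomes) -> bool:
    """True iff consecutive genomes differ by exactly one rearrangement."""
    from .rearrangements import enumerate_neighbors

    gs = list(genomes)
    if len(gs) < 1:
        return False
    for a, b in zip(gs, gs[1:]):
        if b not in enumerate_neighbors(a):
            return False
    return True


def path_has_cut(path) -> bool:
    """A step is a cut when it destroys a block present in the path's first,
    current and last genomes."""
    from .rearrangements import _adjacency_set

    gs = list(path)
    if len(gs) < 2:
        return False
    a_first = _adjacency_set(gs[0])
    a_last = _adjacency_set(gs[-1])
    sets = [_adjacency_set(g) for g in gs]
    for i in range(len(gs) - 1):
        protected = a_first & sets[i] & a_last
        if protected - sets[i + 1]:
            return True
    return False
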