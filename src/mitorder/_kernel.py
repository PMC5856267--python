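"""Accelerated exact-distance kernel.

Same algorithm as :mod:`mitorder.pathsearch` (iterative deepening over
complete depth-first k-path searches), compiled with numba and restricted to
what the large random simulations and distance matrices need: circular
genomes, distance only, first solution wins.

On top of the breakpoint bound the kernel prunes with a second admissible
lower bound from the breakpoint graph of the two genomes: an inversion is a
2-break (it can increase the cycle count by at most 1) and a (reverse)
transposition a 3-break (at most 2), and the genomes are equal exactly when
all ``n`` cycles are trivial, so ``d >= ceil((n - cycles) / 2)``.  Both
bounds are admissible, hence the returned distances are identical to the
reference engine's (tested); the bound only reduces the explored tree.

Genomes are signed int64 arrays over the alphabet ``±1..±n``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["kernel_distance", "target_tables", "warmup"]


@njit(cache=True, inline="always")
def _ext_right(v):
    # extremity reached when leaving signed gene v rightwards
    if v > 0:
        return 2 * (v - 1) + 1
    return 2 * (-v - 1)


@njit(cache=True, inline="always")
def _ext_left(v):
    if v > 0:
        return 2 * (v - 1)
    return 2 * (-v - 1) + 1


@njit(cache=True)
def _lower_bound(x, succ, gray, n, black, visited, limit):
    """(breakpoints, admissible distance lower bound) of x vs the target.

    When the breakpoint bound alone already exceeds ``limit`` the cycle
    bound is skipped: the caller only needs to know the bound is > limit.
    """
    bp = 0
    for i in range(n):
        a = x[i]
        b = x[i + 1] if i + 1 < n else x[0]
        if succ[a + n] != b:
            bp += 1
    if bp == 0:
        return 0, 0
    if (bp + 2) // 3 > limit:
        return bp, (bp + 2) // 3
    for i in range(n):
        a = x[i]
        b = x[i + 1] if i + 1 < n else x[0]
        e1 = _ext_right(a)
        e2 = _ext_left(b)
        black[e1] = e2
        black[e2] = e1
    for i in range(2 * n):
        visited[i] = False
    c = 0
    for e in range(2 * n):
        if not visited[e]:
            c += 1
            cur = e
            while True:
                visited[cur] = True
                nb = black[cur]
                visited[nb] = True
                cur = gray[nb]
                if cur == e:
                    break
    lb = (bp + 2) // 3
    lb2 = (n - c + 1) // 2
    if lb2 > lb:
        lb = lb2
    return bp, lb


@njit(cache=True)
def _consider(tmp, succ, gray, n, k_rem, ch, sc, cnt, black, visited):
    """Score candidate ``tmp``; store it when it can still reach the target.

    Returns (new_count, found): found means tmp IS the target and exactly one
    step was spent reaching it.
    """
    bp, lb = _lower_bound(tmp, succ, gray, n, black, visited, k_rem - 1)
    if bp == 0:
        if k_rem == 1:
            return cnt, True
        return cnt, False  # a path never revisits the target early
    if 1 + lb > k_rem:
        return cnt, False
    for i in range(n):
        ch[cnt, i] = tmp[i]
    sc[cnt] = lb * 64 + bp
    return cnt + 1, False


@njit(cache=True)
def _children(x, succ, gray, n, k_rem, ch, sc, tmp, black, visited):
    """All one-rearrangement neighbors of x that may still lead to the
    target within ``k_rem`` steps.  Mirrors the structural enumeration of
    the reference engine: one inversion per cut pair, one transposition and
    three reverse transpositions per cut triple."""
    cnt = 0
    for p in range(n - 1):
        for q in range(p + 1, n):
            for i in range(n):
                tmp[i] = x[i]
            for i in range(q - p):
                tmp[p + i] = -x[q - 1 - i]
            cnt, found = _consider(tmp, succ, gray, n, k_rem, ch, sc, cnt, black, visited)
            if found:
                return cnt, True
    for p in range(n - 2):
        for q in range(p + 1, n - 1):
            for r in range(q + 1, n):
                # blocks: A=x[:p], B=x[p:q], C=x[q:r], D=x[r:]
                # variant 1: A C B D (transposition)
                idx = 0
                for i in range(p):
                    tmp[idx] = x[i]; idx += 1
                for i in range(q, r):
                    tmp[idx] = x[i]; idx += 1
                for i in range(p, q):
                    tmp[idx] = x[i]; idx += 1
                for i in range(r, n):
                    tmp[idx] = x[i]; idx += 1
                cnt, found = _consider(tmp, succ, gray, n, k_rem, ch, sc, cnt, black, visited)
                if found:
                    return cnt, True
                # variant 2: A -C B D
                idx = p
                for i in range(r - q):
                    tmp[idx] = -x[r - 1 - i]; idx += 1
                cnt, found = _consider(tmp, succ, gray, n, k_rem, ch, sc, cnt, black, visited)
                if found:
                    return cnt, True
                # variant 3: A C -B D
                idx = p
                for i in range(q, r):
                    tmp[idx] = x[i]; idx += 1
                for i in range(q - p):
                    tmp[idx] = -x[q - 1 - i]; idx += 1
                cnt, found = _consider(tmp, succ, gray, n, k_rem, ch, sc, cnt, black, visited)
                if found:
                    return cnt, True
                # variant 4: B -A -D C (the wrapping block D+A moves inverted)
                idx = 0
                for i in range(p, q):
                    tmp[idx] = x[i]; idx += 1
                for i in range(p):
                    tmp[idx] = -x[p - 1 - i]; idx += 1
                for i in range(n - r):
                    tmp[idx] = -x[n - 1 - i]; idx += 1
                for i in range(q, r):
                    tmp[idx] = x[i]; idx += 1
                cnt, found = _consider(tmp, succ, gray, n, k_rem, ch, sc, cnt, black, visited)
                if found:
                    return cnt, True
    return cnt, False


@njit(cache=True)
def _exists_k_path(x0, succ, gray, k, n):
    maxc = n * (n - 1) // 2 + 4 * (n * (n - 1) * (n - 2) // 6)
    ch = np.empty((k, maxc, n), dtype=np.int64)
    sc = np.empty((k, maxc), dtype=np.int64)
    order = np.empty((k, maxc), dtype=np.int64)
    cnt = np.zeros(k, dtype=np.int64)
    ptr = np.zeros(k, dtype=np.int64)
    cur = np.empty((k + 1, n), dtype=np.int64)
    tmp = np.empty(n, dtype=np.int64)
    black = np.empty(2 * n, dtype=np.int64)
    visited = np.empty(2 * n, dtype=np.bool_)

    for i in range(n):
        cur[0, i] = x0[i]
    c, found = _children(cur[0], succ, gray, n, k, ch[0], sc[0], tmp, black, visited)
    if found:
        return True
    if c == 0:
        return False
    order[0, :c] = np.argsort(sc[0, :c])
    cnt[0] = c
    ptr[0] = 0
    depth = 0
    while True:
        if ptr[depth] >= cnt[depth]:
            depth -= 1
            if depth < 0:
                return False
            continue
        j = order[depth, ptr[depth]]
        ptr[depth] += 1
        for i in range(n):
            cur[depth + 1, i] = ch[depth, j, i]
        c, found = _children(
            cur[depth + 1], succ, gray, n, k - depth - 1,
            ch[depth + 1], sc[depth + 1], tmp, black, visited,
        )
        if found:
            return True
        if c > 0:
            order[depth + 1, :c] = np.argsort(sc[depth + 1, :c])
            cnt[depth + 1] = c
            ptr[depth + 1] = 0
            depth += 1


@njit(cache=True)
def _distance(x0, succ, gray, n, kmax):
    black = np.empty(2 * n, dtype=np.int64)
    visited = np.empty(2 * n, dtype=np.bool_)
    bp, lb = _lower_bound(x0, succ, gray, n, black, visited, n)
    if bp == 0:
        return 0
    for k in range(lb, kmax + 1):
        if k == 0:
            continue
        if _exists_k_path(x0, succ, gray, k, n):
            return k
    return -1


def target_tables(target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Successor table and breakpoint-graph gray edges of a circular target."""
    n = len(target)
    succ = np.zeros(2 * n + 1, dtype=np.int64)
    gray = np.empty(2 * n, dtype=np.int64)
    for i in range(n):
        a = int(target[i])
        b = int(target[(i + 1) % n])
        succ[a + n] = b
        succ[-b + n] = -a
        e1 = 2 * (a - 1) + 1 if a > 0 else 2 * (-a - 1)
        e2 = 2 * (b - 1) if b > 0 else 2 * (-b - 1) + 1
        gray[e1] = e2
        gray[e2] = e1
    return succ, gray


def kernel_distance(source: np.ndarray, target: np.ndarray, k_max: int = 8) -> int:
    """Exact circular rearrangement distance, or -1 when it exceeds k_max.

    Both genomes must be signed permutations of 1..n (same gene set).
    """
    n = len(source)
    if n != len(target) or n < 3:
        raise ValueError("need two signed permutations of the same n >= 3 genes")
    succ, gray = target_tables(np.asarray(target, dtype=np.int64))
    return int(_distance(np.asarray(source, dtype=np.int64), succ, gray, n, k_max))


def warmup() -> None:
    """Trigger JIT compilation on a trivial instance."""
    kernel_distance(np.array([1, 2, 3]), np.array([1, 3, 2]), 2)
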