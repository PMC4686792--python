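"""Greedy heuristics for sorting by length- and symmetry-weighted inversions.

Four sorters are provided:

``lr_sort``
    *Left or Right*: fills slices outward-in, placing whichever of the two
    elements destined for the current slice is cheaper to move.
``smp_sort``
    Greedy on the slice-misplaced-pair count, with a two-inversion
    symmetric detour for the stuck configurations and a cost-1 symmetric
    endgame once every element sits in its identity slice.
``nb_sort``
    Greedy on the breakpoint count with a selectable contingency strategy
    for permutations without a benefit-positive inversion; the default
    *Best Strip* strategy reverses whole increasing strips at minimum cost.
``nbsmp_sort``
    Greedy on the combined metric (breakpoint change dominant,
    slice-misplaced-pair change as tie-refinement), Best Strip contingency;
    signed inputs are driven through their unsigned copy and finished with
    unitary sign fixes.

Benefit of an inversion = metric decrease divided by inversion cost,
compared in exact rational arithmetic.  Ties are broken deterministically:
lowest cost, then smallest left endpoint, then smallest right endpoint.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Callable, Iterable, Optional

from .permutation import (
    Inversion,
    Permutation,
    SortingScenario,
    identity,
    identity_slice,
    inversion_cost,
    nb_count,
    smp_count,
    strips,
    _smp_from_tuple,
)

METHOD_ORDER = ("LR", "SMP", "NB", "NB+SMP")

NB_STRATEGIES = ("lr", "strip-lr", "revert", "best-strip")


# ---------------------------------------------------------------------------
# shared greedy machinery


def delta_nb_fast(perm: Permutation, inv: Inversion) -> int:
    """Breakpoint change of ``rho(i, j)`` from the two affected adjacencies only."""
    i, j = inv
    e = perm.elements
    n = perm.n
    left = e[i - 2] if i > 1 else 0
    right = e[j] if j < n else n + 1
    a, b = e[i - 1], e[j - 1]
    if perm.signed:
        before = (a - left != 1) + (right - b != 1)
        after = (-b - left != 1) + (right + a != 1)
    else:
        before = (abs(a - left) != 1) + (abs(right - b) != 1)
        after = (abs(b - left) != 1) + (abs(right - a) != 1)
    return after - before


def _smp_after(mags: tuple[int, ...], inv: Inversion) -> int:
    lst = list(mags)
    lst[inv.i - 1 : inv.j] = lst[inv.i - 1 : inv.j][::-1]
    return _smp_from_tuple(lst)


def _best_by_benefit(
    perm: Permutation, delta_fn: Callable[[Permutation, Inversion], "int | Fraction"]
) -> Optional[tuple[Inversion, Fraction, int]]:
    """Maximal-benefit inversion; ties to lowest cost, then smallest (i, j)."""
    n = perm.n
    best_key = None
    best = None
    for inv in perm.inversions():
        c = inversion_cost(n, inv)
        ben = -Fraction(delta_fn(perm, inv)) / c
        key = (ben, -c, -inv.i, -inv.j)
        if best_key is None or key > best_key:
            best_key, best = key, (inv, ben, c)
    return best


# ---------------------------------------------------------------------------
# Left or Right


def _slice_sorted(perm: Permutation, s: int) -> bool:
    n = perm.n
    for mag in {s, n - s + 1}:
        if perm.position(mag) != mag:
            return False
        if perm.signed and perm.sign_of(mag) < 0:
            return False
    return True


def _smallest_unsorted_slice(perm: Permutation) -> Optional[int]:
    for s in range(1, (perm.n + 1) // 2 + 1):
        if not _slice_sorted(perm, s):
            return s
    return None


def lr_step(perm: Permutation) -> Inversion:
    """Single Left-or-Right move for a non-identity permutation.

    The smallest unsorted slice ``s`` has a left target (position ``s``,
    element of magnitude ``s``) and a right target (position ``n - s + 1``,
    element of magnitude ``n - s + 1``).  Whichever candidate is cheaper to
    place -- one inversion between its current and final position, plus a
    unitary sign fix if the placement leaves it negative -- is moved; ties
    move the right candidate.  Placement inversions stay inside the unsorted
    region, so previously sorted slices are never disturbed.
    """
    n = perm.n
    s = _smallest_unsorted_slice(perm)
    if s is None:
        raise ValueError("permutation is already sorted")
    # right candidate listed first so that strict improvement keeps it on ties
    cands = [(n - s + 1, n - s + 1)] if s == n - s + 1 else [(n - s + 1, n - s + 1), (s, s)]
    misplaced = [(mag, t) for mag, t in cands if perm.position(mag) != t]
    if not misplaced:
        for mag, t in cands:  # positions correct, a sign must be wrong
            if perm.sign_of(mag) < 0:
                return Inversion(t, t)
        raise AssertionError("slice reported unsorted but no defect found")
    if len(misplaced) == 1:
        mag, t = misplaced[0]
        p = perm.position(mag)
        return Inversion(min(p, t), max(p, t))
    best: Optional[tuple[int, Inversion]] = None
    for mag, t in misplaced:
        p = perm.position(mag)
        inv = Inversion(min(p, t), max(p, t))
        c = inversion_cost(n, inv)
        if perm.signed and -perm.sign_of(mag) < 0:
            c += 1  # the placement flips the sign; a unitary fix will follow
        if best is None or c < best[0]:
            best = (c, inv)
    return best[1]


def lr_sort(perm: Permutation) -> SortingScenario:
    """Sort by repeated Left-or-Right placements."""
    sc = SortingScenario(perm, method="LR")
    cur = perm
    n = perm.n
    while not cur.is_identity():
        inv = lr_step(cur)
        sc.steps.append((inv, inversion_cost(n, inv)))
        cur = cur.apply(inv)
    return sc


# ---------------------------------------------------------------------------
# Slice-misplaced pairs


def symmetric_endgame(perm: Permutation) -> list[Inversion]:
    """Finish a permutation whose elements all sit in their identity slices.

    Every element is then at its final position or at the mirror of it, so
    perfectly symmetric inversions (cost 1 each, at most ``n // 2``) restore
    all magnitudes; for signed permutations remaining negatives are flipped
    with unitary inversions (cost 1 each).
    """
    if smp_count(perm) != 0:
        raise ValueError("symmetric endgame requires a slice-misplaced-pair count of 0")
    n = perm.n
    out: list[Inversion] = []
    cur = perm
    for i in range(1, n // 2 + 1):
        j = n - i + 1
        if abs(cur.elements[i - 1]) == j:
            inv = Inversion(i, j)
            out.append(inv)
            cur = cur.apply(inv)
    if cur.signed:
        for i in range(1, n + 1):
            if cur.elements[i - 1] < 0:
                out.append(Inversion(i, i))
    return out


def smp_fallback_step(perm: Permutation) -> tuple[Inversion, Inversion]:
    """Two-inversion detour when no single inversion lowers the SMP count.

    A stuck permutation with slice-misplaced pairs left carries two
    neighbouring elements sharing a below-maximum identity slice; mirroring
    the member with the larger position slice through a perfectly symmetric
    inversion (SMP-neutral, cost 1) re-pairs the slices so that a strictly
    SMP-decreasing inversion becomes available.  Candidate pairs are tried
    from the highest position slice down, smallest start position first; as
    a safety net every perfectly symmetric inversion is then tried.
    """
    n = perm.n
    top = (n + 1) // 2
    mags = tuple(abs(e) for e in perm.elements)
    cand = []
    for i in range(1, n):
        m1, m2 = mags[i - 1], mags[i]
        s_id = min(m1, n - m1 + 1)
        if s_id == min(m2, n - m2 + 1) and s_id != top:
            key = max(identity_slice(n, i), identity_slice(n, i + 1))
            cand.append((key, i))
    first_candidates = []
    for _, i in sorted(cand, key=lambda t: (-t[0], t[1])):
        q = i if identity_slice(n, i) > identity_slice(n, i + 1) else i + 1
        first_candidates.append(Inversion(min(q, n - q + 1), max(q, n - q + 1)))
    first_candidates.extend(Inversion(i, n - i + 1) for i in range(1, n // 2 + 1))
    for r1 in first_candidates:
        if not perm.signed and r1.i == r1.j:
            continue
        after = perm.apply(r1)
        pick = _best_by_benefit(after, lambda p, inv: _smp_after(tuple(abs(e) for e in p.elements), inv) - smp_count(p))
        if pick is not None and pick[1] > 0:
            return r1, pick[0]
    raise RuntimeError("no SMP-decreasing two-inversion detour exists")


def smp_sort(perm: Permutation) -> SortingScenario:
    """Greedy sort on the slice-misplaced-pair count."""
    sc = SortingScenario(perm, method="SMP")
    cur = perm
    n = perm.n
    while not cur.is_identity():
        mags = tuple(abs(e) for e in cur.elements)
        before = _smp_from_tuple(mags)
        if before == 0:
            for inv in symmetric_endgame(cur):
                sc.steps.append((inv, inversion_cost(n, inv)))
                cur = cur.apply(inv)
            break
        pick = _best_by_benefit(cur, lambda p, inv: _smp_after(mags, inv) - before)
        if pick is not None and pick[1] > 0:
            chosen: Iterable[Inversion] = (pick[0],)
        else:
            chosen = smp_fallback_step(cur)
        for inv in chosen:
            sc.steps.append((inv, inversion_cost(n, inv)))
            cur = cur.apply(inv)
    return sc


# ---------------------------------------------------------------------------
# Number of breakpoints


def strip_inversion_candidates(perm: Permutation) -> list[Inversion]:
    """Inversions aligned with strip boundaries, cheapest first.

    Each candidate reverses one or more whole strips (never splitting one);
    spans must cover at least one increasing strip when any exists.  Ordered
    by cost, then by endpoints, for deterministic selection.
    """
    st = strips(perm)
    n = perm.n
    any_inc = any(s.direction == "increasing" for s in st)
    out = []
    for a in range(len(st)):
        covers_inc = False
        for b in range(a, len(st)):
            covers_inc = covers_inc or st[b].direction == "increasing"
            if any_inc and not covers_inc:
                continue
            i, j = st[a].start, st[b].end
            if not perm.signed and i == j:
                continue
            out.append(Inversion(i, j))
    out.sort(key=lambda inv: (inversion_cost(n, inv), inv.i, inv.j))
    return out


def best_strip_inversion(perm: Permutation) -> Optional[Inversion]:
    """Least costly whole-strip inversion (the *Best Strip* contingency)."""
    cands = strip_inversion_candidates(perm)
    return cands[0] if cands else None


def _revert_inversion(perm: Permutation) -> Optional[Inversion]:
    """One inversion reverting the entire unsorted region."""
    s = _smallest_unsorted_slice(perm)
    if s is None:
        return None
    t = perm.n - s + 1
    if s == t:
        return Inversion(s, s) if perm.signed else None
    return Inversion(s, t)


def _strip_lr_inversion(perm: Permutation) -> Optional[Inversion]:
    """Whole-strip variant of the Left-or-Right contingency.

    Costs pushing the strip holding the right candidate to the right edge of
    the unsorted region against pushing the strip holding the left candidate
    to the left edge, and applies the cheaper (ties to the right).
    """
    n = perm.n
    s = _smallest_unsorted_slice(perm)
    if s is None:
        return None
    t_l, t_r = s, n - s + 1
    st = strips(perm)

    def strip_of(pos: int) -> tuple[int, int]:
        for sp in st:
            if sp.start <= pos <= sp.end:
                return sp.start, sp.end
        raise AssertionError("position outside all strips")

    options = []
    a, _ = strip_of(perm.position(n - s + 1))
    inv = Inversion(max(a, t_l), t_r)
    if inv.i < inv.j or (perm.signed and inv.i == inv.j):
        options.append(inv)
    _, b = strip_of(perm.position(s))
    inv = Inversion(t_l, min(b, t_r))
    if inv.i < inv.j or (perm.signed and inv.i == inv.j):
        options.append(inv)
    if not options:
        return None
    best = None
    for inv in options:  # right option first: strict < keeps it on ties
        c = inversion_cost(n, inv)
        if best is None or c < best[0]:
            best = (c, inv)
    return best[1]


def _contingency_candidates(perm: Permutation, strategy: str) -> list[Inversion]:
    if strategy == "best-strip":
        return strip_inversion_candidates(perm)
    if strategy == "lr":
        return [lr_step(perm)]
    if strategy == "revert":
        inv = _revert_inversion(perm)
        return [] if inv is None else [inv]
    if strategy == "strip-lr":
        inv = _strip_lr_inversion(perm)
        return [] if inv is None else [inv]
    raise ValueError(f"unknown NB contingency strategy {strategy!r}; choose from {NB_STRATEGIES}")


def nb_sort(perm: Permutation, strategy: str = "best-strip") -> SortingScenario:
    """Greedy sort on the breakpoint count with a contingency strategy.

    The maximal-benefit inversion is applied while its benefit is strictly
    positive (guaranteed whenever a decreasing strip exists); otherwise the
    contingency strategy supplies a move.  Contingency moves that would
    revisit an earlier state are skipped; if none remains the permutation is
    finished deterministically with Left-or-Right placements.
    """
    if strategy not in NB_STRATEGIES:
        raise ValueError(f"unknown NB contingency strategy {strategy!r}; choose from {NB_STRATEGIES}")
    sc = SortingScenario(perm, method="NB")
    cur = perm
    n = perm.n
    seen = {cur.elements}
    while not cur.is_identity():
        pick = _best_by_benefit(cur, delta_nb_fast)
        if pick is not None and pick[1] > 0:
            inv: Optional[Inversion] = pick[0]
        else:
            inv = next(
                (iv for iv in _contingency_candidates(cur, strategy) if cur.apply(iv).elements not in seen),
                None,
            )
        if inv is None:
            tail = lr_sort(cur)
            sc.steps.extend(tail.steps)
            cur = identity(n, perm.signed)
            break
        sc.steps.append((inv, inversion_cost(n, inv)))
        cur = cur.apply(inv)
        seen.add(cur.elements)
    return sc


# ---------------------------------------------------------------------------
# Combined metric


def _nbsmp_inversion_stream(start: Permutation):
    """Yield the inversions the combined greedy applies to an unsigned permutation.

    The combined metric change is the breakpoint change plus the
    slice-misplaced-pair change divided by ``C(n, 2) + 1``, which keeps the
    breakpoint term strictly dominant while using the pair term to refine
    ties; comparisons are exact rationals.  When no inversion has positive
    benefit the Best Strip contingency is used (state-revisit guarded, with
    a Left-or-Right completion as last resort).
    """
    cur = start
    n = start.n
    norm = n * (n - 1) // 2 + 1
    seen = {cur.elements}
    while not cur.is_identity():
        mags = cur.elements
        before = _smp_from_tuple(mags)

        def combined(p: Permutation, inv: Inversion) -> Fraction:
            return Fraction(delta_nb_fast(p, inv)) + Fraction(_smp_after(mags, inv) - before, norm)

        pick = _best_by_benefit(cur, combined)
        if pick is not None and pick[1] > 0:
            inv: Optional[Inversion] = pick[0]
        else:
            inv = next(
                (iv for iv in strip_inversion_candidates(cur) if cur.apply(iv).elements not in seen),
                None,
            )
        if inv is None:
            for inv2, _ in lr_sort(cur).steps:
                yield inv2
            return
        yield inv
        cur = cur.apply(inv)
        seen.add(cur.elements)


def nbsmp_sort(perm: Permutation) -> SortingScenario:
    """Greedy sort on breakpoints refined by slice-misplaced pairs.

    Signed permutations are driven by their unsigned copy: each inversion the
    unsigned procedure selects is applied to the signed permutation as well,
    and once the unsigned copy is sorted the remaining negative elements are
    flipped with unitary inversions.
    """
    sc = SortingScenario(perm, method="NB+SMP")
    n = perm.n
    if not perm.signed:
        cur = perm
        for inv in _nbsmp_inversion_stream(perm):
            sc.steps.append((inv, inversion_cost(n, inv)))
            cur = cur.apply(inv)
        return sc
    cur = perm
    for inv in _nbsmp_inversion_stream(perm.dropped_signs()):
        sc.steps.append((inv, inversion_cost(n, inv)))
        cur = cur.apply(inv)
    for i in range(1, n + 1):
        if cur.elements[i - 1] < 0:
            inv = Inversion(i, i)
            sc.steps.append((inv, inversion_cost(n, inv)))
            cur = cur.apply(inv)
    return sc


# ---------------------------------------------------------------------------
# best-of selector


SORTERS: dict[str, Callable[[Permutation], SortingScenario]] = {
    "LR": lr_sort,
    "SMP": smp_sort,
    "NB": nb_sort,
    "NB+SMP": nbsmp_sort,
}


def sort_all(perm: Permutation) -> tuple[dict[str, SortingScenario], str]:
    """Run all four heuristics; return the scenarios and the cheapest method.

    Ties are broken by the fixed order LR < SMP < NB < NB+SMP.
    """
    scenarios = {name: SORTERS[name](perm) for name in METHOD_ORDER}
    best = min(METHOD_ORDER, key=lambda m: (scenarios[m].total_cost, METHOD_ORDER.index(m)))
    return scenarios, best
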