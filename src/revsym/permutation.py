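"""Permutation primitives for length- and symmetry-weighted inversion sorting.

A bacterial chromosome with no duplicated genes is modelled as a permutation
``pi = (pi_1 ... pi_n)`` of ``1..n``; position 1 holds the first gene after
the origin of replication.  When gene orientation is known the permutation is
*signed* (each element carries a strand sign), otherwise it is *unsigned*.

An inversion ``rho(i, j)`` reverses the segment between positions ``i`` and
``j`` (1-based, inclusive), additionally flipping signs in the signed case.
Its cost is ``|slice(i) - slice(j)| + 1`` where ``slice(k) = min(k, n-k+1)``
is the distance of position ``k`` from the nearer end of the chromosome:
inversions whose endpoints lie on the same side of the middle pay for their
length, while inversions symmetric about the origin (``j = n - i + 1``) cost
exactly 1 regardless of length.

The module also provides the two progress metrics driving the greedy
sorters: the number of breakpoints (NB) of the extended permutation, and the
number of slice-misplaced pairs (SMP) -- element pairs whose slice order in
the current permutation contradicts their slice order in the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence


class Inversion(NamedTuple):
    """Segment reversal identified by its 1-based inclusive endpoints."""

    i: int
    j: int

    def is_unitary(self) -> bool:
        return self.i == self.j

    def is_perfectly_symmetric(self, n: int) -> bool:
        return self.j == n - self.i + 1


class Strip(NamedTuple):
    """Maximal breakpoint-free interval of positions, with its orientation."""

    start: int
    end: int
    direction: str  # "increasing" or "decreasing"


def identity_slice(n: int, k: int) -> int:
    """Slice of position ``k`` in a chromosome of length ``n``.

    ``min(k, n - k + 1)`` pairs positions equidistant from the two ends;
    its range is ``1 .. ceil(n / 2)``.
    """
    if not 1 <= k <= n:
        raise ValueError(f"position {k} outside 1..{n}")
    return min(k, n - k + 1)


def inversion_cost(n: int, inv: Inversion) -> int:
    """Cost of ``rho(i, j)`` on a chromosome of length ``n``.

    ``|slice(i) - slice(j)| + 1``: proportional to segment length when both
    endpoints are on the same side of the middle, and penalising asymmetry
    otherwise; perfectly symmetric inversions cost 1.
    """
    i, j = inv
    if not 1 <= i <= j <= n:
        raise ValueError(f"invalid inversion endpoints {inv} for n={n}")
    return abs(identity_slice(n, i) - identity_slice(n, j)) + 1


@dataclass(frozen=True)
class Permutation:
    """A signed or unsigned permutation of the magnitudes ``1..n``."""

    elements: tuple[int, ...]
    signed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        n = len(self.elements)
        if n == 0:
            raise ValueError("empty permutation")
        if sorted(abs(e) for e in self.elements) != list(range(1, n + 1)):
            raise ValueError(f"magnitudes must be a bijection on 1..{n}: {self.elements}")
        if not self.signed and any(e < 0 for e in self.elements):
            raise ValueError("unsigned permutation with negative element")

    # -- basic accessors ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.elements)

    def is_identity(self) -> bool:
        return all(e == k for k, e in enumerate(self.elements, start=1))

    def position(self, element: int) -> int:
        """Index ``k`` (1-based) with ``|pi_k| = element``."""
        self._check_magnitude(element)
        for k, e in enumerate(self.elements, start=1):
            if abs(e) == element:
                return k
        raise AssertionError("unreachable: magnitudes are a bijection")

    def sign_of(self, element: int) -> int:
        """-1 iff the element carrying this magnitude is on the reverse strand."""
        self._check_magnitude(element)
        return -1 if self.elements[self.position(element) - 1] < 0 else 1

    def slice_of(self, element: int) -> int:
        """Slice of the element's current position (sign-independent)."""
        return identity_slice(self.n, self.position(element))

    def _check_magnitude(self, element: int) -> None:
        if not 1 <= element <= self.n:
            raise ValueError(f"element magnitude {element} outside 1..{self.n}")

    # -- operations -----------------------------------------------------

    def apply(self, inv: Inversion) -> "Permutation":
        """Apply ``rho(i, j)``: reverse the segment, flipping signs if signed."""
        i, j = inv
        n = self.n
        if not 1 <= i <= j <= n:
            raise ValueError(f"invalid inversion endpoints {inv} for n={n}")
        if not self.signed and i == j:
            raise ValueError("unitary inversions are no-ops on unsigned permutations")
        e = list(self.elements)
        seg = e[i - 1 : j]
        seg.reverse()
        if self.signed:
            seg = [-x for x in seg]
        e[i - 1 : j] = seg
        return Permutation(tuple(e), self.signed)

    def compose(self, other: "Permutation") -> "Permutation":
        """Function composition ``pi . sigma = (pi_sigma(1) ... pi_sigma(n))``.

        Extends to signed permutations via ``pi(-i) = -pi(i)``.
        """
        if self.n != other.n:
            raise ValueError("length mismatch in composition")
        out = []
        for s in other.elements:
            v = self.elements[abs(s) - 1]
            out.append(v if s > 0 else -v)
        return Permutation(tuple(out), self.signed or other.signed)

    def inverse(self) -> "Permutation":
        """Functional inverse: ``pi . pi^-1 = identity``."""
        out = [0] * self.n
        for k, e in enumerate(self.elements, start=1):
            out[abs(e) - 1] = k if e > 0 else -k
        return Permutation(tuple(out), self.signed)

    def dropped_signs(self) -> "Permutation":
        """Unsigned copy obtained by removing the signs."""
        return Permutation(tuple(abs(e) for e in self.elements), False)

    def inversions(self) -> Iterator[Inversion]:
        """All legal inversions: ``i <= j`` signed, ``i < j`` unsigned."""
        n = self.n
        for i in range(1, n + 1):
            for j in range(i if self.signed else i + 1, n + 1):
                yield Inversion(i, j)

    def __str__(self) -> str:
        if self.signed:
            return "(" + " ".join(f"{e:+d}" for e in self.elements) + ")"
        return "(" + " ".join(str(e) for e in self.elements) + ")"


def identity(n: int, signed: bool = False) -> Permutation:
    return Permutation(tuple(range(1, n + 1)), signed)


# -- breakpoints and strips ---------------------------------------------


def nb_count(perm: Permutation) -> int:
    """Number of breakpoints of the extended permutation.

    The extension adds sentinels ``pi_0 = 0`` and ``pi_{n+1} = n + 1``.  A
    signed adjacency ``(pi_i, pi_{i+1})`` is a breakpoint when
    ``pi_{i+1} - pi_i != 1``; the unsigned condition is ``|pi_{i+1} - pi_i| != 1``.
    The identity is the only permutation with no breakpoints.
    """
    ext = (0,) + perm.elements + (perm.n + 1,)
    if perm.signed:
        return sum(1 for a, b in zip(ext, ext[1:]) if b - a != 1)
    return sum(1 for a, b in zip(ext, ext[1:]) if abs(b - a) != 1)


def strips(perm: Permutation) -> list[Strip]:
    """Partition positions ``1..n`` into maximal breakpoint-free intervals.

    Each strip is labelled increasing or decreasing by the order of its
    elements; single-element strips count as decreasing.
    """
    ext = (0,) + perm.elements + (perm.n + 1,)
    if perm.signed:
        bp = [b - a != 1 for a, b in zip(ext, ext[1:])]
    else:
        bp = [abs(b - a) != 1 for a, b in zip(ext, ext[1:])]
    out: list[Strip] = []
    start = 1
    for k in range(1, perm.n):
        # bp[k] is the adjacency between permutation positions k and k+1
        if bp[k]:
            out.append(_make_strip(perm, start, k))
            start = k + 1
    out.append(_make_strip(perm, start, perm.n))
    return out


def _make_strip(perm: Permutation, start: int, end: int) -> Strip:
    if start == end:
        return Strip(start, end, "decreasing")
    inc = perm.elements[start - 1] < perm.elements[start]
    return Strip(start, end, "increasing" if inc else "decreasing")


# -- slice-misplaced pairs ----------------------------------------------


def smp_count(perm: Permutation) -> int:
    """Number of slice-misplaced pairs.

    A pair of elements is slice-misplaced when their slice order in the
    current permutation is the strict reverse of their slice order in the
    identity.  Signs are irrelevant since the slice is sign-independent.
    Computed over unordered pairs; the identity scores 0.
    """
    return _smp_from_tuple(tuple(abs(e) for e in perm.elements))


def _smp_from_tuple(mags: Sequence[int]) -> int:
    n = len(mags)
    cur = [0] * (n + 1)  # slice of each magnitude in the current arrangement
    for k, m in enumerate(mags, start=1):
        cur[m] = k if k <= n - k + 1 else n - k + 1
    count = 0
    for a in range(1, n + 1):
        sa_cur = cur[a]
        sa_id = a if a <= n - a + 1 else n - a + 1
        for b in range(a + 1, n + 1):
            sb_id = b if b <= n - b + 1 else n - b + 1
            if (sa_cur - cur[b]) * (sa_id - sb_id) < 0:
                count += 1
    return count


def delta_nb(perm: Permutation, inv: Inversion) -> int:
    """Breakpoint change ``NB(pi . rho) - NB(pi)``; always in ``-2..2``."""
    return nb_count(perm.apply(inv)) - nb_count(perm)


def delta_smp(perm: Permutation, inv: Inversion) -> int:
    """Slice-misplaced-pair change ``SMP(pi . rho) - SMP(pi)``.

    Zero for every perfectly symmetric inversion, which permutes elements
    between mirror positions and therefore changes no slice.
    """
    return smp_count(perm.apply(inv)) - smp_count(perm)


def delta(metric: str, perm: Permutation, inv: Inversion) -> int:
    """Dispatch on ``metric`` in {"NB", "SMP"}."""
    if metric == "NB":
        return delta_nb(perm, inv)
    if metric == "SMP":
        return delta_smp(perm, inv)
    raise ValueError(f"unknown metric {metric!r}")


# -- sorting scenarios --------------------------------------------------


@dataclass
class SortingScenario:
    """An ordered sequence of inversions transforming ``start`` into the identity."""

    start: Permutation
    steps: list[tuple[Inversion, int]] = field(default_factory=list)
    method: str = ""

    @property
    def total_cost(self) -> int:
        return sum(c for _, c in self.steps)

    def replay(self) -> Permutation:
        cur = self.start
        for inv, _ in self.steps:
            cur = cur.apply(inv)
        return cur

    def validate(self) -> None:
        """Raise unless the scenario replays to the identity with correct costs."""
        n = self.start.n
        for inv, c in self.steps:
            if c != inversion_cost(n, inv):
                raise ValueError(f"step {inv} recorded cost {c}, expected {inversion_cost(n, inv)}")
        if not self.replay().is_identity():
            raise ValueError("scenario does not sort the permutation")
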