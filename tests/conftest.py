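"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import pytest

from revsym import Permutation, identity, inversion_cost


def all_permutations(n: int, signed: bool):
    """Exhaustive enumeration built directly on itertools (oracle-side)."""
    for mags in itertools.permutations(range(1, n + 1)):
        if not signed:
            yield Permutation(mags, False)
        else:
            for mask in range(2**n):
                yield Permutation(
                    tuple(-m if mask >> k & 1 else m for k, m in enumerate(mags)), True
                )


def brute_force_costs(n: int, signed: bool) -> dict[tuple[int, ...], int]:
    """Optimal sorting costs by fixpoint relaxation over the whole state space.

    Deliberately naive: a dictionary keyed by element tuples, relaxed until
    no edge improves -- no priority queue, no state ranking -- serving as an
    implementation-independent oracle for the shortest-path solver.
    """
    ident = identity(n, signed)
    edges = [(inv, inversion_cost(n, inv)) for inv in ident.inversions()]
    best: dict[tuple[int, ...], float] = {p.elements: math.inf for p in all_permutations(n, signed)}
    best[ident.elements] = 0
    changed = True
    while changed:
        changed = False
        for elems, d in list(best.items()):
            if d == math.inf:
                continue
            perm = Permutation(elems, signed)
            for inv, c in edges:
                ne = perm.apply(inv).elements
                if d + c < best[ne]:
                    best[ne] = d + c
                    changed = True
    return {k: int(v) for k, v in best.items()}


@pytest.fixture(scope="session")
def exhaustive_summary():
    """Exhaustive evaluation (unsigned n<=7, signed n<=5), computed once."""
    from revsym import evaluate_exhaustive

    records, summary = evaluate_exhaustive(max_n_unsigned=7, max_n_signed=5)
    return records, summary
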