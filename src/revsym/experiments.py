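"""Evaluation harness: exhaustive small-permutation and random benchmarks.

Two experimental designs are supported.  *Exhaustive* mode enumerates every
permutation of each size, sorts it with every selected heuristic, compares
against the exact shortest-path cost and summarises per size: the fraction
of instances sorted optimally, the mean and maximum approximation ratio
(heuristic cost / optimal cost), and how often each method gives the best
answer among the methods run (ties counted for every tying method, so these
fractions may sum past 1).  *Random* mode draws uniform permutations of
configurable sizes; there the optimum is out of reach, so mean cost replaces
the ratio.

The virtual method ``All`` takes, per instance, the cheapest of the
individual heuristics.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exact import exact_all
from .heuristics import METHOD_ORDER, SORTERS
from .permutation import Permutation

ALL = "All"


def space_size(n: int, signed: bool) -> int:
    """Number of permutations of length ``n``: ``n!`` or ``2^n * n!``."""
    return math.factorial(n) * (2**n if signed else 1)


def dataset_cardinality(n_min: int, n_max: int, signed: bool) -> int:
    """Total instances in an exhaustive dataset over sizes ``n_min..n_max``."""
    return sum(space_size(n, signed) for n in range(n_min, n_max + 1))


def enumerate_permutations(n: int, signed: bool) -> Iterator[Permutation]:
    """Every permutation of length ``n`` exactly once, in state-space rank order."""
    for mags in itertools.permutations(range(1, n + 1)):
        if not signed:
            yield Permutation(mags, False)
            continue
        for mask in range(2**n):
            yield Permutation(
                tuple(-m if mask >> k & 1 else m for k, m in enumerate(mags)), True
            )


def random_permutation(n: int, signed: bool, rng: "np.random.Generator | int") -> Permutation:
    """Uniform draw: random shuffle, i.i.d. fair-coin signs when signed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mags = rng.permutation(n) + 1
    if signed:
        signs = rng.integers(0, 2, size=n) * 2 - 1
        mags = mags * signs
    return Permutation(tuple(int(x) for x in mags), signed)


def _method_costs(perm: Permutation, methods: Sequence[str]) -> dict[str, int]:
    costs = {m: SORTERS[m](perm).total_cost for m in methods}
    costs[ALL] = min(costs[m] for m in methods)
    return costs


def evaluate_exhaustive(
    max_n_unsigned: int = 7,
    max_n_signed: int = 5,
    methods: Sequence[str] = METHOD_ORDER,
    n_min: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exhaustive comparison against the exact solver.

    Returns ``(records, summary)``: one record per permutation with each
    method's cost, the optimal cost and the approximation ratios; and one
    summary row per (signedness, size, method).  Sizes run from ``n_min`` to
    the per-variant maxima, which must stay within the exact-solver bounds.
    """
    from .exact import MAX_N_SIGNED, MAX_N_UNSIGNED

    if max_n_unsigned > MAX_N_UNSIGNED or max_n_signed > MAX_N_SIGNED:
        raise ValueError(
            f"exhaustive evaluation refused beyond the exact-solver bounds "
            f"(unsigned n<={MAX_N_UNSIGNED}, signed n<={MAX_N_SIGNED})"
        )
    rows = []
    jobs = [(n, False) for n in range(n_min, max_n_unsigned + 1)] + [
        (n, True) for n in range(n_min, max_n_signed + 1)
    ]
    for n, signed in jobs:
        index, dist, _ = exact_all(n, signed)
        count = 0
        for rank, perm in enumerate(enumerate_permutations(n, signed)):
            count += 1
            opt = dist[rank]
            row = {"signed": signed, "n": n, "rank": rank, "opt_cost": opt}
            costs = _method_costs(perm, methods)
            for m, c in costs.items():
                row[f"cost_{m}"] = c
                row[f"ratio_{m}"] = c / opt if opt > 0 else 1.0
            rows.append(row)
        if count != space_size(n, signed):
            raise AssertionError("enumeration does not cover the state space")
    records = pd.DataFrame(rows)
    summary = summarize(records, list(methods) + [ALL])
    return records, summary


def evaluate_random(
    sizes: Sequence[int],
    reps_per_size: int,
    seed: int,
    signed: bool = False,
    methods: Sequence[str] = METHOD_ORDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random benchmark without an exact reference (mean cost, not ratio)."""
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        for rep in range(reps_per_size):
            perm = random_permutation(n, signed, rng)
            row = {"signed": signed, "n": n, "rank": rep}
            for m, c in _method_costs(perm, methods).items():
                row[f"cost_{m}"] = c
            rows.append(row)
    records = pd.DataFrame(rows)
    summary = summarize(records, list(methods) + [ALL])
    return records, summary


def summarize(records: pd.DataFrame, methods: Iterable[str]) -> pd.DataFrame:
    """Per (signedness, size, method) aggregates, recomputable from the records."""
    methods = [m for m in methods if f"cost_{m}" in records.columns]
    out = []
    for (signed, n), grp in records.groupby(["signed", "n"], sort=True):
        best = grp[[f"cost_{m}" for m in methods if m != ALL]].min(axis=1)
        for m in methods:
            cost = grp[f"cost_{m}"]
            row = {
                "signed": signed,
                "n": n,
                "method": m,
                "mean_cost": cost.mean(),
                "best_answer_fraction": (cost == best).mean(),
            }
            if "opt_cost" in grp.columns:
                ratio = grp[f"ratio_{m}"]
                row["fraction_optimal"] = (cost == grp["opt_cost"]).mean()
                row["mean_ratio"] = ratio.mean()
                row["max_ratio"] = ratio.max()
            out.append(row)
    return pd.DataFrame(out)
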