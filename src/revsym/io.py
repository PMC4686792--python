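"""Plain-text formats for permutations and sorting scenarios.

Permutation files hold one permutation per line as whitespace-separated
integers; ``#`` starts a comment line.  A line containing any explicit
``+``/``-`` sign is parsed as signed; files may not mix the two variants
(the legal inversion sets differ).  The writer emits signed permutations
with explicit ``+`` on positive elements.

Scenario files carry a header line ``n <n> signed <0|1> method <label>
total_cost <c>`` followed by one line per step, ``i j cost`` with 1-based
inclusive endpoints.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Union

from .permutation import Inversion, Permutation, SortingScenario

PathLike = Union[str, Path]

_SIGN_RE = re.compile(r"[+-]")


def parse_permutation_line(line: str, signed: "bool | None" = None) -> Permutation:
    """Parse a single permutation; signedness inferred from explicit signs."""
    tokens = line.split()
    if signed is None:
        signed = any(_SIGN_RE.match(t) for t in tokens)
    return Permutation(tuple(int(t) for t in tokens), signed)


def read_permutations(path: PathLike, signed: "bool | None" = None) -> list[Permutation]:
    """Read a permutation file; blank and ``#`` lines are skipped.

    Raises ``ValueError`` (naming the line) on malformed lines or when the
    file mixes signed and unsigned permutations.
    """
    perms: list[Permutation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                perm = parse_permutation_line(line, signed)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if perms and perm.signed != perms[0].signed:
                raise ValueError(f"{path}:{lineno}: mixed signed and unsigned permutations")
            perms.append(perm)
    return perms


def format_permutation(perm: Permutation) -> str:
    if perm.signed:
        return " ".join(f"{e:+d}" for e in perm.elements)
    return " ".join(str(e) for e in perm.elements)


def write_permutations(path: PathLike, perms: Iterable[Permutation]) -> None:
    with open(path, "w") as fh:
        for perm in perms:
            fh.write(format_permutation(perm) + "\n")


def write_scenario(path: PathLike, scenario: SortingScenario) -> None:
    """Write a scenario after verifying that it replays to the identity."""
    scenario.validate()
    with open(path, "w") as fh:
        fh.write(
            f"n {scenario.start.n} signed {int(scenario.start.signed)} "
            f"method {scenario.method} total_cost {scenario.total_cost}\n"
        )
        for inv, cost in scenario.steps:
            fh.write(f"{inv.i} {inv.j} {cost}\n")


def read_scenario(path: PathLike, start: Permutation) -> SortingScenario:
    """Read a scenario for ``start`` and validate it."""
    with open(path) as fh:
        header = fh.readline().split()
        fields = dict(zip(header[::2], header[1::2]))
        sc = SortingScenario(start, method=fields.get("method", ""))
        for raw in fh:
            if not raw.strip():
                continue
            i, j, cost = (int(x) for x in raw.split())
            sc.steps.append((Inversion(i, j), cost))
    if sc.start.n != int(fields["n"]) or sc.start.signed != bool(int(fields["signed"])):
        raise ValueError(f"{path}: scenario header does not match the permutation")
    if sc.total_cost != int(fields["total_cost"]):
        raise ValueError(f"{path}: total_cost header disagrees with the steps")
    sc.validate()
    return sc
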