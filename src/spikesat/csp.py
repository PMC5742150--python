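"""Binary constraint satisfaction problems: data model, checking, enumeration.

A CSP is the triple ⟨X, D, C⟩: variables, per-variable value domains, and
binary constraints.  Constraints carry a sign: a *negative* constraint forbids
the two variables from taking equal values (graph coloring, Latin squares,
antiferromagnetic bonds), a *positive* constraint requires them to be equal
(ferromagnetic bonds).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "UNDECIDED",
    "Constraint",
    "CSP",
    "Assignment",
    "CheckResult",
    "check_assignment",
    "brute_force_solve",
]

#: Marker for a variable with no decided value (e.g. a silent network variable).
UNDECIDED = -1


@dataclass(frozen=True)
class Constraint:
    """A signed binary constraint over two variables.

    ``sign=-1`` forbids equal values; ``sign=+1`` requires equal values.
    ``strength_tag`` optionally selects a non-default weight range in the
    network compiler.
    """

    u: int
    v: int
    sign: int = -1
    strength_tag: str | None = None

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"constraint scope must reference two distinct variables, got ({self.u}, {self.v})")
        if self.sign not in (-1, 1):
            raise ValueError(f"constraint sign must be -1 or +1, got {self.sign}")

    @property
    def scope(self) -> tuple[int, int]:
        return (self.u, self.v)


@dataclass
class CSP:
    """A binary CSP ⟨X, D, C⟩.

    Parameters
    ----------
    domains
        One ordered list of value labels per variable; ``domains[i][j]`` is the
        label of value ``j`` of variable ``i``.  Labels are arbitrary hashables
        (colors, digits, spins); internally values are domain indices.
    constraints
        Signed binary constraints.  Duplicate (scope, sign) pairs are rejected.
    metadata
        Free-form instance annotations (clues, lattice shape, ...).
    """

    domains: list[list]
    constraints: list[Constraint] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.domains:
            # an empty CSP (zero variables) is legal and trivially satisfied
            pass
        for i, dom in enumerate(self.domains):
            if len(dom) == 0:
                raise ValueError(f"domain of variable {i} is empty")
        seen: set[tuple[tuple[int, int], int]] = set()
        n = self.n_variables
        for c in self.constraints:
            if not (0 <= c.u < n and 0 <= c.v < n):
                raise ValueError(f"constraint scope ({c.u}, {c.v}) outside variable range 0..{n - 1}")
            key = (tuple(sorted(c.scope)), c.sign)
            if key in seen:
                raise ValueError(f"duplicate constraint on scope {c.scope} with sign {c.sign}")
            seen.add(key)

    @property
    def n_variables(self) -> int:
        return len(self.domains)

    @property
    def domain_sizes(self) -> list[int]:
        return [len(d) for d in self.domains]

    def search_space_size(self) -> int:
        """Number of complete assignments, Π_i |D_i|."""
        size = 1
        for d in self.domains:
            size *= len(d)
        return size


@dataclass(frozen=True)
class Assignment:
    """Per-variable chosen domain indices; ``UNDECIDED`` marks no choice."""

    values: tuple[int, ...]

    @classmethod
    def from_values(cls, values: Iterable[int]) -> "Assignment":
        return cls(tuple(int(v) for v in values))

    def is_complete(self) -> bool:
        return all(v != UNDECIDED for v in self.values)

    def labels(self, csp: CSP) -> list:
        """Map decided indices to their domain labels (``None`` if undecided)."""
        return [csp.domains[i][v] if v != UNDECIDED else None for i, v in enumerate(self.values)]

    def __len__(self) -> int:
        return len(self.values)


def _validate(csp: CSP, a: Assignment) -> None:
    if len(a) != csp.n_variables:
        raise ValueError(f"assignment has {len(a)} values for a CSP of {csp.n_variables} variables")
    for i, v in enumerate(a.values):
        if v != UNDECIDED and not (0 <= v < len(csp.domains[i])):
            raise ValueError(f"value index {v} outside domain of variable {i}")


@dataclass
class CheckResult:
    """Outcome of checking an assignment against a CSP.

    ``violated`` holds constraints broken by decided value pairs;
    ``undetermined`` holds constraints with at least one undecided endpoint.
    Satisfaction requires a complete assignment, no violations and no
    undetermined constraints.
    """

    satisfied: bool
    violated: list[Constraint]
    undetermined: list[Constraint]

    def __iter__(self) -> Iterator:
        # unpacks as (satisfied, violated) per the two-value contract
        return iter((self.satisfied, self.violated + self.undetermined))


def check_assignment(csp: CSP, a: Assignment) -> CheckResult:
    """Check consistency and completeness of an assignment.

    A negative constraint is violated when both endpoints share a value, a
    positive one when the (decided) values differ.  Undecided endpoints make
    the incident constraints undetermined and satisfaction false.
    """
    _validate(csp, a)
    violated: list[Constraint] = []
    undetermined: list[Constraint] = []
    for c in csp.constraints:
        vu, vv = a.values[c.u], a.values[c.v]
        if vu == UNDECIDED or vv == UNDECIDED:
            undetermined.append(c)
        elif c.sign < 0 and vu == vv:
            violated.append(c)
        elif c.sign > 0 and vu != vv:
            violated.append(c)
    satisfied = a.is_complete() and not violated and not undetermined
    return CheckResult(satisfied, violated, undetermined)


def brute_force_solve(csp: CSP, cap: int = 1_000_000) -> list[Assignment]:
    """Exhaustively enumerate all satisfying assignments, in lexicographic order.

    Exact oracle for small instances.  Refuses outright (``ValueError``) if the
    search space exceeds ``cap`` — never silently truncates.
    """
    size = csp.search_space_size()
    if size > cap:
        raise ValueError(f"search space of {size} assignments exceeds cap {cap}; refusing to enumerate")
    solutions: list[Assignment] = []
    ranges: Sequence[range] = [range(len(d)) for d in csp.domains]
    for combo in itertools.product(*ranges):
        a = Assignment(combo)
        if check_assignment(csp, a).satisfied:
            solutions.append(a)
    return solutions
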