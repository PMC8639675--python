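"""Arithmetic stimulus set: problem parsing, size classification, validation.

The experiment uses 80 unique problems (40 subtractions, 40 multiplications)
split into four blocks A-D.  Problem size proxies strategy use: *small*
problems (both operands <= 10) are typically solved by fact retrieval,
*large* problems (one operand > 10) by a procedure.  Large subtractions
additionally require borrowing (the subtrahend exceeds the ones digit of
the minuend), which rules out shortcut strategies.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "Operation",
    "SizeClass",
    "ArithmeticProblem",
    "ProblemParseError",
    "ValidationReport",
    "parse_problem",
    "classify_size",
    "validate_problem_set",
    "load_problem_set",
]

BLOCKS = ("A", "B", "C", "D")


class Operation(str, Enum):
    SUBTRACTION = "subtraction"
    MULTIPLICATION = "multiplication"

    @property
    def symbol(self) -> str:
        return "-" if self is Operation.SUBTRACTION else "x"


class SizeClass(str, Enum):
    SMALL = "small"
    LARGE = "large"


class ProblemParseError(ValueError):
    """Raised when a problem string cannot be turned into a valid stimulus."""


# accepted operator glyphs, normalized to a canonical internal operation
_SUB_GLYPHS = {"−", "-", "–"}
_MUL_GLYPHS = {"×", "x", "X", "*", "·"}
_PROBLEM_RE = re.compile(r"^\s*(\d+)\s*([^\d\s])\s*(\d+)\s*$")


@dataclass(frozen=True)
class ArithmeticProblem:
    """One stimulus: two positive operands, an operation, and a block label."""

    operand1: int
    operand2: int
    operation: Operation
    block: str

    def __post_init__(self) -> None:
        if self.operand1 <= 0 or self.operand2 <= 0:
            raise ProblemParseError(
                f"operands must be positive, got {self.operand1}, {self.operand2}"
            )
        if self.block not in BLOCKS:
            raise ProblemParseError(f"unknown block {self.block!r}")
        if self.operation is Operation.SUBTRACTION and self.solution <= 0:
            raise ProblemParseError(
                f"subtraction {self.text!r} has non-positive solution"
            )

    @property
    def solution(self) -> int:
        if self.operation is Operation.SUBTRACTION:
            return self.operand1 - self.operand2
        return self.operand1 * self.operand2

    @property
    def size(self) -> SizeClass:
        return classify_size(self)

    @property
    def text(self) -> str:
        return f"{self.operand1} {self.operation.symbol} {self.operand2}"


def parse_problem(text: str, block: str) -> ArithmeticProblem:
    """Parse a problem string like ``"36 − 8"`` or ``"16 x 6"``.

    ASCII and typographic operator glyphs are both accepted and normalized.
    Raises :class:`ProblemParseError` naming the offending text for malformed
    strings, non-positive operands, or non-positive subtraction results.
    """
    m = _PROBLEM_RE.match(text)
    if m is None:
        raise ProblemParseError(f"malformed problem string: {text!r}")
    op1, glyph, op2 = m.group(1), m.group(2), m.group(3)
    if glyph in _SUB_GLYPHS:
        operation = Operation.SUBTRACTION
    elif glyph in _MUL_GLYPHS:
        operation = Operation.MULTIPLICATION
    else:
        raise ProblemParseError(f"unknown operator {glyph!r} in {text!r}")
    try:
        return ArithmeticProblem(int(op1), int(op2), operation, block)
    except ProblemParseError as err:
        raise ProblemParseError(f"{err} (while parsing {text!r})") from None


def classify_size(problem: ArithmeticProblem) -> SizeClass:
    """Small iff both operands are <= 10; large otherwise."""
    if problem.operand1 <= 10 and problem.operand2 <= 10:
        return SizeClass.SMALL
    return SizeClass.LARGE


@dataclass
class ValidationReport:
    """Design-constraint report for a candidate stimulus set.

    ``counts`` maps (block, operation, size) -> number of problems.
    ``violations`` lists human-readable constraint breaches.
    """

    n_problems: int
    n_unique: int
    counts: dict[tuple[str, Operation, SizeClass], int]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def count(self, block: str, operation: Operation, size: SizeClass) -> int:
        return self.counts.get((block, operation, size), 0)


def validate_problem_set(
    problems: Sequence[ArithmeticProblem],
) -> ValidationReport:
    """Check a problem set against the design constraints of the task.

    Flags duplicate problems and large subtractions that do not require
    borrowing (subtrahend <= ones digit of the minuend).  The counts table
    lets callers verify the 5-per-cell block structure.
    """
    if not problems:
        raise ValueError("empty problem set")

    counts: Counter = Counter()
    violations: list[str] = []
    seen: Counter = Counter()
    for p in problems:
        counts[(p.block, p.operation, p.size)] += 1
        seen[(p.operand1, p.operand2, p.operation)] += 1
        if (
            p.operation is Operation.SUBTRACTION
            and p.size is SizeClass.LARGE
            and p.operand2 <= p.operand1 % 10
        ):
            violations.append(
                f"large subtraction {p.text} does not require borrowing "
                f"(subtrahend {p.operand2} <= ones digit {p.operand1 % 10})"
            )
    for key, n in seen.items():
        if n > 1:
            o1, o2, op = key
            violations.append(f"duplicate problem {o1} {op.symbol} {o2} (x{n})")

    return ValidationReport(
        n_problems=len(problems),
        n_unique=len(seen),
        counts=dict(counts),
        violations=violations,
    )


def load_problem_set() -> list[ArithmeticProblem]:
    """Load the packaged 80-problem stimulus set (TSV fixture).

    The fixture is a transcription of the experiment's problem table and is
    validated by :func:`validate_problem_set` in the test suite rather than
    trusted blindly.
    """
    text = (
        resources.files("arithmeeg").joinpath("data/problems.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["block", "operand1", "operation", "operand2"]
    if header != expected:
        raise ValueError(f"stimulus TSV header {header} != {expected}")
    problems = []
    for ln in lines[1:]:
        block, o1, op, o2 = ln.split("\t")
        problems.append(parse_problem(f"{o1} {op} {o2}", block))
    return problems


def problems_by_block(
    problems: Iterable[ArithmeticProblem],
) -> dict[str, list[ArithmeticProblem]]:
    out: dict[str, list[ArithmeticProblem]] = {b: [] for b in BLOCKS}
    for p in problems:
        out[p.block].append(p)
    return out
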