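"""Shared test helpers: building trial lists from count tables."""

from arithmeeg.stimuli import ArithmeticProblem, Operation
from arithmeeg.synthdata import TrialEvent

SMALL = ArithmeticProblem(6, 2, Operation.SUBTRACTION, "A")
LARGE = ArithmeticProblem(36, 8, Operation.SUBTRACTION, "B")


def make_trial(problem, report, participant="p01", rt=2.0, correct=True, onset=10.0):
    return TrialEvent(participant, problem, onset, rt, correct, report)


def trials_from_crosstab(counts):
    """Expand a size-by-report count table (rows: large, small; columns:
    procedure, retrieve, unknown) into individual trials."""
    trials = []
    for row, problem in zip(counts, (LARGE, SMALL)):
        for n, report in zip(row, ("procedure", "retrieve", "unknown")):
            trials.extend(make_trial(problem, report) for _ in range(n))
    return trials
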