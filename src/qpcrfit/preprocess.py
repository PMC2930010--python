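"""Raw-curve preprocessing: finite differences, truncation, baseline.

MAK2 is valid only before primer depletion and enzyme saturation; the
working rule is to truncate each curve at the cycle with the maximum slope
increase (maximum second difference), which empirically falls just before
the curve's inflection.  Differences are plain subtractions on the raw
fluorescence — no smoothing, no statistical outlier classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "AmplificationCurve",
    "TruncationResult",
    "finite_differences",
    "find_truncation_cycle",
    "estimate_baseline",
    "truncate_curve",
]


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's ordered (cycle, fluorescence) series.

    Cycles are 1-based, strictly increasing integers (gaps permitted in the
    in-memory type; file ingestion is stricter).  Fluorescence values must be
    finite.  ``known_copies`` carries the known template amount for
    dilution-series members; ``None`` otherwise.
    """

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    known_copies: float | None = None

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=int)
        fluo = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluo)
        if cycles.ndim != 1 or fluo.ndim != 1 or len(cycles) != len(fluo):
            raise InvalidInputError(
                f"well {self.well_id!r}: cycles and fluorescence must be equal-length 1-D arrays"
            )
        if len(cycles) < 3:
            raise InsufficientDataError(
                f"well {self.well_id!r}: at least 3 cycles required, got {len(cycles)}"
            )
        if np.any(np.diff(cycles) <= 0):
            raise InvalidInputError(f"well {self.well_id!r}: cycles must be strictly increasing")
        if cycles[0] < 1:
            raise InvalidInputError(f"well {self.well_id!r}: cycles are 1-based")
        if not np.all(np.isfinite(fluo)):
            bad = int(cycles[np.flatnonzero(~np.isfinite(fluo))[0]])
            raise InvalidInputError(
                f"well {self.well_id!r}: non-finite fluorescence at cycle {bad}"
            )
        if self.known_copies is not None and not (self.known_copies > 0):
            raise InvalidInputError(
                f"well {self.well_id!r}: known_copies must be > 0, got {self.known_copies!r}"
            )

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class TruncationResult:
    """Outcome of the maximum-slope-increase truncation rule.

    ``cutoff_cycle`` is the 1-based cycle label of the last cycle retained
    for MAK2 fitting (inclusive).  ``first_diff`` is defined for cycles
    2..N and ``second_diff`` for cycles 3..N.  ``flagged_degenerate`` is set
    when the maximum second difference is <= 0, i.e. no growth detected;
    degenerate curves are flagged, never rejected here.
    """

    cutoff_cycle: int
    first_diff: np.ndarray = field(repr=False)
    second_diff: np.ndarray = field(repr=False)
    flagged_degenerate: bool = False


def finite_differences(curve: AmplificationCurve) -> tuple[np.ndarray, np.ndarray]:
    """First and second differences of raw fluorescence.

    ``first_diff[i] = F[i+1] - F[i]`` (slope, cycles 2..N);
    ``second_diff[i] = first_diff[i+1] - first_diff[i]`` (slope increase,
    cycles 3..N).  Plain subtraction, no smoothing.
    """
    first = np.diff(curve.fluorescence)
    second = np.diff(first)
    return first, second


def find_truncation_cycle(curve: AmplificationCurve) -> TruncationResult:
    """Locate the cycle with the maximum slope increase.

    Data retained for MAK2 fitting are cycles 1..cutoff_cycle inclusive.
    Ties are broken toward the earliest cycle (conservative: keeps fitting
    inside the model's validity region).
    """
    first, second = finite_differences(curve)
    idx = int(np.argmax(second))  # argmax takes the earliest maximum
    cutoff_cycle = int(curve.cycles[idx + 2])
    degenerate = bool(second[idx] <= 0)
    return TruncationResult(
        cutoff_cycle=cutoff_cycle,
        first_diff=first,
        second_diff=second,
        flagged_degenerate=degenerate,
    )


def estimate_baseline(
    curve: AmplificationCurve, n_baseline_cycles: int | None = None
) -> float:
    """Mean fluorescence over the early, pre-amplification cycles.

    With ``n_baseline_cycles=None`` the window runs up to two cycles before
    the truncation cutoff (to keep early signal out of the baseline), with a
    minimum of 3 cycles.  An explicit window must satisfy
    ``2 <= n_baseline_cycles <= len(curve)``.
    """
    if n_baseline_cycles is None:
        cutoff = find_truncation_cycle(curve).cutoff_cycle
        cutoff_pos = int(np.searchsorted(curve.cycles, cutoff)) + 1
        n = max(3, cutoff_pos - 2)
        n = min(n, len(curve))
    else:
        n = int(n_baseline_cycles)
        if n < 2:
            raise InsufficientDataError("baseline window must cover at least 2 cycles")
        if n > len(curve):
            raise InsufficientDataError(
                f"baseline window of {n} cycles exceeds curve length {len(curve)}"
            )
    return float(np.mean(curve.fluorescence[:n]))


def truncate_curve(curve: AmplificationCurve, cutoff_cycle: int) -> AmplificationCurve:
    """Return the sub-curve of cycles 1..cutoff_cycle inclusive."""
    mask = curve.cycles <= cutoff_cycle
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"well {curve.well_id!r}: fewer than 3 cycles at or before cycle {cutoff_cycle}"
        )
    return replace(
        curve, cycles=curve.cycles[mask], fluorescence=curve.fluorescence[mask]
    )
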