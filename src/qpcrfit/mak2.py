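"""The MAK2 mass-action kinetic model of PCR.

MAK2 describes the accumulation of double-stranded product during the
exponential growth phase of PCR with a single per-cycle recursion,

    D_n = D_{n-1} + k * ln(1 + D_{n-1} / k),

where ``D_n`` is the amount of product (or, equivalently, the fluorescence
associated with it) after cycle ``n``, ``D_0`` is the initial template
amount, and ``k`` — the ratio of the primer-binding and strand-reannealing
rate constants — sets how fast the per-cycle amplification efficiency
declines as product accumulates.  Observed fluorescence is modelled as the
product signal plus a constant background, ``F_n = Fb + D_n``.

The recursion follows from competing first-order priming and second-order
reannealing kinetics run to completion within each cycle; see
:mod:`qpcrfit.kinetics` for the mechanistic derivation used as a numerical
cross-check.  The model applies only before primer depletion and polymerase
saturation matter, i.e. up to (not through) the plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError

__all__ = [
    "MAK2Params",
    "Trajectory",
    "mak2_step",
    "simulate_trajectory",
    "efficiency_profile",
]

# Beyond this ratio ln(1 + D/k) is evaluated asymptotically as ln(D/k);
# dilution series span many orders of magnitude and 1 + D/k would overflow
# or lose all precision.
_ASYMPTOTIC_RATIO = 1e15


def _check_k(k: float) -> None:
    if not (math.isfinite(k) and k > 0):
        raise InvalidParameterError(f"k must be finite and > 0, got {k!r}")


@dataclass(frozen=True)
class MAK2Params:
    """The MAK2 parameter triple.

    Parameters
    ----------
    d0 : float
        Initial target amount in (arbitrary) fluorescence units; >= 0.
        Zero is allowed for degenerate (no-template) simulation.
    k : float
        Characteristic PCR constant, same units as ``d0``; strictly > 0.
    fb : float
        Constant background fluorescence; unconstrained sign.
    """

    d0: float
    k: float
    fb: float = 0.0

    def __post_init__(self) -> None:
        _check_k(self.k)
        if not (math.isfinite(self.d0) and self.d0 >= 0):
            raise InvalidParameterError(f"d0 must be finite and >= 0, got {self.d0!r}")
        if not math.isfinite(self.fb):
            raise InvalidParameterError(f"fb must be finite, got {self.fb!r}")


@dataclass(frozen=True)
class Trajectory:
    """A simulated MAK2 trajectory over cycles 1..n.

    ``d`` is the model DNA amount after each cycle (non-decreasing; strictly
    increasing when ``params.d0 > 0``) and ``f = fb + d`` is the predicted
    background-adjusted fluorescence.  Cycle indices are 1-based; ``d0`` is
    the amount *before* cycle 1.
    """

    params: MAK2Params
    cycles: np.ndarray
    d: np.ndarray
    f: np.ndarray

    def __len__(self) -> int:
        return len(self.cycles)


def mak2_step(d_prev: float, k: float) -> float:
    """Advance the MAK2 recursion by one cycle.

    Returns ``d_prev + k * ln(1 + d_prev / k)``, the product amount after one
    further cycle of amplification.  The per-cycle gain is bounded:
    ``d_prev <= result <= 2 * d_prev``, with doubling reached only in the
    ``k -> inf`` limit.
    """
    _check_k(k)
    if not math.isfinite(d_prev) or d_prev < 0:
        raise InvalidInputError(f"d_prev must be finite and >= 0, got {d_prev!r}")
    if d_prev == 0.0:
        return 0.0
    ratio = d_prev / k
    if ratio > _ASYMPTOTIC_RATIO:
        return d_prev + k * math.log(ratio)
    return d_prev + k * math.log1p(ratio)


def simulate_trajectory(params: MAK2Params, n_cycles: int) -> Trajectory:
    """Iterate the MAK2 recursion for ``n_cycles`` cycles.

    ``d[0]`` is the amount after cycle 1 (one step from ``params.d0``);
    ``f[n] = params.fb + d[n]``.  Deterministic.
    """
    if int(n_cycles) != n_cycles or n_cycles < 1:
        raise InvalidInputError(f"n_cycles must be a positive integer, got {n_cycles!r}")
    n_cycles = int(n_cycles)
    d = np.empty(n_cycles, dtype=float)
    current = params.d0
    for i in range(n_cycles):
        current = mak2_step(current, params.k)
        d[i] = current
    cycles = np.arange(1, n_cycles + 1)
    return Trajectory(params=params, cycles=cycles, d=d, f=params.fb + d)


def efficiency_profile(trajectory: Trajectory, k: float | None = None) -> np.ndarray:
    """Per-cycle amplification efficiency along a trajectory.

    Efficiency at cycle n is the fractional gain
    ``E_n = (D_n - D_{n-1}) / D_{n-1} = (k / D_{n-1}) * ln(1 + D_{n-1} / k)``.
    All values lie in (0, 1), decrease strictly with cycle, and approach 1
    (perfect doubling) as ``D / k -> 0``.
    """
    if k is None:
        k = trajectory.params.k
    _check_k(k)
    if trajectory.params.d0 <= 0:
        raise DegenerateInputError("efficiency is undefined for d0 = 0")
    prev = np.concatenate(([trajectory.params.d0], trajectory.d[:-1]))
    return (k / prev) * np.log1p(prev / k)
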