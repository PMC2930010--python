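"""Synthetic qPCR curve and dilution-series generator.

Curves are built from the MAK2 recursion (the exponential phase), a smooth
saturating hand-off toward a plateau ceiling (emulating primer depletion and
polymerase saturation, which MAK2 itself does not model), a constant
background, and additive homoscedastic Gaussian detector noise:

    F_n = Fb + saturate(D_n) + eps_n,   eps_n ~ N(0, noise_sd)

The saturation is the identity up to 0.3*plateau_fmax and a tanh hand-off
above it (slope-continuous; the 0.3 hand-off point is a generator
convention, not a scientific claim).  Dilution series are ten-fold by
default, spanning six orders of magnitude with replicates, and the
generator truth (true D0, k, Fb per curve) is always returned alongside the
curves for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mak2 import MAK2Params, simulate_trajectory
from .preprocess import AmplificationCurve
from .quantify import DilutionSeries

__all__ = [
    "GeneratorConfig",
    "SyntheticSeries",
    "generate_curve",
    "generate_flat_curve",
    "generate_dilution_series",
    "DEFAULT_D0_LEVELS",
]

# Six ten-fold levels, arbitrary fluorescence units (copies factor 1).
DEFAULT_D0_LEVELS = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3)

_HANDOFF_FRACTION = 0.3


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for synthetic curves.

    Defaults emulate a dye-based instrument run: 40 cycles, background 1.0,
    plateau 1.0 above background, detector noise 1% of plateau, six ten-fold
    dilution levels with duplicate wells.  ``k = 0.5`` (in plateau units)
    keeps per-cycle efficiency above ~0.9 until the signal nears the
    saturation hand-off, giving the 10-to-90% rise over roughly 3-4 cycles
    seen in high-efficiency dye-based assays.  ``k_drift`` adds a
    linear-in-log10(D0) trend to k (per decade, relative to the first
    level) for diagnostic studies; 0 keeps k constant as the mechanism
    predicts.  ``copy_signal_factor`` converts known copies to signal units
    (``known_copies = d0 / copy_signal_factor``; default 1, units are
    arbitrary).
    """

    d0_levels: tuple[float, ...] = DEFAULT_D0_LEVELS
    k: float = 0.5
    fb: float = 1.0
    n_cycles: int = 40
    noise_sd: float = 0.01
    plateau_fmax: float = 1.0
    replicates: int = 2
    seed: int = 0
    k_drift: float = 0.0
    copy_signal_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.d0_levels) == 0 or any(d <= 0 for d in self.d0_levels):
            raise ConfigError("d0_levels must be non-empty and strictly positive")
        for name in ("k", "plateau_fmax", "copy_signal_factor"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_cycles < 3:
            raise ConfigError("n_cycles must be >= 3")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if max(self.d0_levels) >= _HANDOFF_FRACTION * self.plateau_fmax:
            raise ConfigError(
                "plateau_fmax is below the expected exponential-phase signal: "
                "the largest d0 level already reaches the saturation hand-off"
            )

    def k_at_level(self, level_index: int) -> float:
        d0 = self.d0_levels[level_index]
        k = self.k + self.k_drift * (
            math.log10(d0) - math.log10(self.d0_levels[0])
        )
        if k <= 0:
            raise ConfigError(f"k_drift drives k non-positive at level {level_index}")
        return k


@dataclass(frozen=True)
class SyntheticSeries:
    """A generated dilution series plus its generator truth table."""

    series: DilutionSeries
    truth: pd.DataFrame


def _saturate(d: np.ndarray, fmax: float) -> np.ndarray:
    """Smooth saturating hand-off from the identity toward ``fmax``.

    Identity up to 0.3*fmax; above it, ``theta + span*tanh(u + u**3/3)``
    with ``u = (d - theta)/span``.  Slope-continuous at the hand-off and,
    because the cubic term cancels the tanh expansion, the deviation from
    the identity grows only as u**5 — the curve stays on the kinetic model
    until saturation sets in decisively, mirroring the fairly abrupt onset
    of primer depletion in real reactions.
    """
    theta = _HANDOFF_FRACTION * fmax
    span = fmax - theta
    u = np.maximum(d - theta, 0.0) / span
    return np.where(d <= theta, d, theta + span * np.tanh(u + u**3 / 3.0))


def _noise(config: GeneratorConfig, level_index: int, replicate: int, n: int) -> np.ndarray:
    if config.noise_sd == 0:
        return np.zeros(n)
    # per-curve stream keyed on (seed, level, replicate): determinism does
    # not depend on generation order
    rng = np.random.default_rng([config.seed, level_index, replicate])
    return rng.normal(0.0, config.noise_sd, n)


def generate_curve(
    config: GeneratorConfig, level_index: int, replicate: int = 0
) -> tuple[AmplificationCurve, dict]:
    """One synthetic well at the given dilution level.

    Returns the curve and its truth record (true d0, k, fb, known copies).
    Deterministic for a fixed config.
    """
    d0 = config.d0_levels[level_index]
    k = config.k_at_level(level_index)
    traj = simulate_trajectory(MAK2Params(d0=d0, k=k, fb=0.0), config.n_cycles)
    signal = _saturate(traj.d, config.plateau_fmax)
    fluo = config.fb + signal + _noise(config, level_index, replicate, config.n_cycles)
    known = d0 / config.copy_signal_factor
    well_id = f"L{level_index}R{replicate}"
    curve = AmplificationCurve(
        well_id=well_id, cycles=traj.cycles, fluorescence=fluo, known_copies=known
    )
    truth = {
        "well_id": well_id,
        "level_index": level_index,
        "replicate": replicate,
        "d0": d0,
        "k": k,
        "fb": config.fb,
        "known_copies": known,
    }
    return curve, truth


def generate_flat_curve(
    config: GeneratorConfig, replicate: int = 0, well_id: str = "NTC"
) -> AmplificationCurve:
    """A no-template (negative control) well: flat noisy baseline."""
    # stream key 1000 + n_levels keeps negative-control noise disjoint from
    # every dilution level's stream
    fluo = config.fb + _noise(config, 1000 + len(config.d0_levels), replicate, config.n_cycles)
    return AmplificationCurve(
        well_id=f"{well_id}R{replicate}",
        cycles=np.arange(1, config.n_cycles + 1),
        fluorescence=fluo,
        known_copies=None,
    )


def generate_dilution_series(config: GeneratorConfig) -> SyntheticSeries:
    """All levels x replicates, with independent noise per well."""
    if len(config.d0_levels) < 2:
        raise ConfigError("a dilution series needs at least 2 levels")
    curves, truths = [], []
    for level in range(len(config.d0_levels)):
        for rep in range(config.replicates):
            curve, truth = generate_curve(config, level, rep)
            curves.append(curve)
            truths.append(truth)
    return SyntheticSeries(
        series=DilutionSeries(curves=curves), truth=pd.DataFrame(truths)
    )
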