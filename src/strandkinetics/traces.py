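"""Containers for plate-reader fluorescence time traces.

A strand-displacement experiment produces four kinds of wells read on the
same schedule: the reaction itself, a pre-activated control (reporter
fully triggered with excess input, defining maximal fluorescence), a
negative control (no input, quenched reporter baseline) and an empty-well
background. Normalization divides out instrument gain using the two
controls, so traces are kept raw here and only normalized downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLES = ("reaction", "pre_activated", "negative", "background")

MIN_TRACE_POINTS = 4


@dataclass(frozen=True)
class FluorescenceTrace:
    """One well's raw fluorescence versus time.

    Parameters
    ----------
    times : array of float
        Seconds, strictly increasing, at least 4 points.
    values : array of float
        Fluorescence in arbitrary instrument units, same length as times.
    role : str
        One of ``reaction``, ``pre_activated``, ``negative``, ``background``.
    label : str
        Free-text well / condition identifier.
    """

    times: np.ndarray
    values: np.ndarray
    role: str
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if times.size != values.size:
            raise ValueError(
                f"times ({times.size}) and values ({values.size}) differ in length"
            )
        if times.size < MIN_TRACE_POINTS:
            raise ValueError(f"need at least {MIN_TRACE_POINTS} points, got {times.size}")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ReactionConditions:
    """Initial concentrations (molar) and temperature for one reaction well.

    ``in0`` is the invading input strand, ``ai0`` the PNA-DNA heteroduplex
    gate (the limiting species), ``r0`` the downstream fluorescent
    reporter duplex. The standard designs use a 1.5:1 input:gate and 3:1
    reporter:gate ratio.
    """

    in0: float
    ai0: float
    r0: float
    temperature: float = 37.0

    def __post_init__(self):
        if self.ai0 <= 0:
            raise ValueError(f"ai0 must be > 0, got {self.ai0}")
        if self.in0 < 0:
            raise ValueError(f"in0 must be >= 0, got {self.in0}")
        if self.r0 < 0:
            raise ValueError(f"r0 must be >= 0, got {self.r0}")


@dataclass(frozen=True)
class NormalizedTrace:
    """Fluorescence normalized to [0, 1] by the pre-activated/negative controls.

    ``fn`` is dimensionless; ``out_conc`` is the displaced-incumbent
    concentration fn * ai0 (molar), attached when conditions are known.
    ``mask`` marks points excluded because the control difference
    Fc - F0 fell below the floor.
    """

    times: np.ndarray
    fn: np.ndarray
    conditions: ReactionConditions | None = None
    label: str = ""
    mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        fn = np.asarray(self.fn, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fn", fn)
        if times.size != fn.size:
            raise ValueError("times and fn must have the same length")
        mask = self.mask
        if mask is None:
            mask = np.ones(times.size, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.size != times.size:
                raise ValueError("mask must match trace length")
        object.__setattr__(self, "mask", mask)

    @property
    def out_conc(self) -> np.ndarray | None:
        """Displaced incumbent concentration, fn * ai0 (molar)."""
        if self.conditions is None:
            return None
        return np.clip(self.fn, 0.0, None) * self.conditions.ai0
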