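"""Generative dose -> relative-hazard scenario curves.

A scenario curve encodes a hypothesis about how graft CD34+ cell dose maps
to the instantaneous rate of granulocyte recovery, relative to some
reference level.  Two hypotheses are of central interest:

* ``threshold`` -- recovery is impossible (hazard exactly zero) below a
  minimum dose ``d0`` and possible above it;
* ``plateau``  -- the hazard is positive at every nonzero dose, rises with
  dose, and saturates at a ceiling (no threshold).

``linear`` (log-linear in dose) and ``flat`` (dose carries no signal) are
provided for parameter-recovery and null checks.  At dose exactly zero the
hazard is zero for every kind: with no graft cells there is nothing to
engraft.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScenarioCurve", "scenario_relative_hazard"]

_KINDS = ("threshold", "plateau", "linear", "flat")


@dataclass(frozen=True)
class ScenarioCurve:
    """Dose -> relative-hazard function used by the cohort simulator.

    Parameters
    ----------
    kind:
        One of ``threshold``, ``plateau``, ``linear``, ``flat``.
    d0:
        Dose breakpoint, in the units of the dose metric the curve is
        applied to.  For ``threshold`` it is the threshold dose; for
        ``plateau`` the dose at which the ceiling is reached; for
        ``linear`` the reference dose at which the relative hazard is 1.
    low_level:
        Relative hazard at the low-dose end (``plateau`` only).
    high_level:
        Ceiling relative hazard (``plateau``), or the hazard at and above
        the threshold (``threshold``).
    slope:
        Log2-hazard change per doubling of dose (``linear`` only).
    """

    kind: str
    d0: float | None = None
    low_level: float = 0.5
    high_level: float = 1.5
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind in ("threshold", "plateau"):
            if self.d0 is None or self.d0 <= 0:
                raise ValueError(f"kind={self.kind} requires d0 > 0")
        if self.high_level <= 0:
            raise ValueError("high_level must be > 0")
        if self.low_level < 0:
            raise ValueError("low_level must be >= 0")
        if self.kind == "plateau":
            if self.low_level <= 0:
                raise ValueError("plateau requires low_level > 0")
            if self.high_level < self.low_level:
                raise ValueError("plateau requires high_level >= low_level")


def scenario_relative_hazard(curve: ScenarioCurve, dose):
    """Evaluate the generative relative-hazard curve at ``dose``.

    Accepts a scalar or array of doses (>= 0).  Returns values >= 0, with
    r(0) = 0 for every kind.  Continuous in dose for every kind except
    ``threshold``.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)

    if curve.kind == "flat":
        r = np.ones_like(d)
    elif curve.kind == "threshold":
        r = np.where(d < curve.d0, 0.0, curve.high_level)
    elif curve.kind == "plateau":
        ramp = np.clip(d / curve.d0, 0.0, 1.0)
        r = curve.low_level + (curve.high_level - curve.low_level) * ramp
    else:  # linear in log2 dose
        ref = curve.d0 if curve.d0 is not None else 1.0
        r = np.zeros_like(d)
        pos = d > 0
        r[pos] = np.power(d[pos] / ref, curve.slope)

    r = np.where(d == 0, 0.0, r)
    return float(r[0]) if scalar else r
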