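"""Core in-memory containers for dynamic first-pass perfusion data.

A :class:`DynamicCurve` is one time-resolved trace — either the arterial
input function (AIF) sampled in the left-ventricular blood pool, or the
tissue response of a single AHA myocardial segment — in signal-intensity
or gadolinium-concentration units.  :class:`SequenceParams` carries the
acquisition constants needed to convert between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Union

import numpy as np

Kind = Literal["signal", "concentration"]
Role = Literal["aif", "tissue"]
Phase = Literal["stress", "rest"]


class CurveError(ValueError):
    """Raised when a curve violates its structural invariants."""


@dataclass
class DynamicCurve:
    """Time-stamped samples for one segment or the arterial input.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    values
        Signal intensity (a.u.) or gadolinium concentration (mM),
        matching ``kind``.
    kind
        ``"signal"`` or ``"concentration"``.
    role
        ``"aif"`` or ``"tissue"``.
    segment
        AHA segment number 1–16 for tissue curves; ``None`` for the AIF.
    phase
        ``"stress"`` or ``"rest"`` (optional for free-standing curves).
    """

    times: np.ndarray
    values: np.ndarray
    kind: Kind = "concentration"
    role: Role = "tissue"
    segment: Optional[int] = None
    phase: Optional[Phase] = None
    subject: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise CurveError("times and values must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise CurveError("curve must contain at least one sample")
        if np.any(np.diff(self.times) <= 0):
            raise CurveError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise CurveError("times and values must be finite")
        if self.kind not in ("signal", "concentration"):
            raise CurveError(f"unknown kind {self.kind!r}")
        if self.role not in ("aif", "tissue"):
            raise CurveError(f"unknown role {self.role!r}")
        if self.role == "tissue" and self.segment is not None:
            if not 1 <= int(self.segment) <= 16:
                raise CurveError(f"segment id {self.segment} outside 1..16")

    # -- grid helpers -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.times.size

    def grid_spacing(self, rtol: float = 1e-6) -> float:
        """Return the uniform sample spacing dt, or raise if non-uniform."""
        dts = np.diff(self.times)
        dt = float(dts[0]) if dts.size else 0.0
        if dts.size and not np.allclose(dts, dt, rtol=rtol, atol=1e-12):
            raise CurveError("curve is not on a uniform time grid")
        return dt

    def with_values(self, values: np.ndarray, kind: Union[Kind, None] = None) -> "DynamicCurve":
        """Copy of this curve with new values (and optionally a new kind)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass
class SequenceParams:
    """Acquisition constants of the saturation-recovery perfusion sequence.

    Parameters
    ----------
    td
        Preparation-pulse delay to the central k-space line, seconds.
    relaxivity
        Longitudinal relaxivity r1 of the contrast agent, L·mmol⁻¹·s⁻¹.
    baseline_t1
        Pre-contrast T1 of the tissue (or blood) in seconds, from a
        MOLLI map.
    n_baseline_frames
        Number of pre-contrast frames averaged for the baseline signal.
    readout
        ``"sr"`` — pure saturation-recovery exponential (default);
        ``"spgr"`` — spoiled gradient-echo readout including flip angle
        and repetition time.
    flip_angle_deg, tr
        Readout flip angle (degrees) and repetition time (seconds);
        only used by the ``"spgr"`` model.
    """

    td: float = 0.1
    relaxivity: float = 5.0
    baseline_t1: float = 1.2
    n_baseline_frames: int = 5
    readout: Literal["sr", "spgr"] = "sr"
    flip_angle_deg: float = 12.0
    tr: float = 0.0022

    def __post_init__(self) -> None:
        if self.td <= 0:
            raise ValueError("TD must be positive")
        if self.relaxivity <= 0:
            raise ValueError("relaxivity must be positive")
        if self.baseline_t1 <= 0:
            raise ValueError("baseline T1 must be positive")
        if self.n_baseline_frames < 1:
            raise ValueError("need at least one baseline frame")
        if self.readout not in ("sr", "spgr"):
            raise ValueError(f"unknown readout model {self.readout!r}")

    @property
    def r1_0(self) -> float:
        """Pre-contrast longitudinal relaxation rate R1(0) = 1/T1, s⁻¹."""
        return 1.0 / self.baseline_t1
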