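"""Signal-intensity to gadolinium-concentration conversion.

First-pass perfusion images are acquired with a saturation-recovery
prepared readout, so the signal of each frame depends on the momentary
longitudinal relaxation rate R1(t).  With the pre-contrast baseline
signal as reference, the conversion proceeds in two steps:

1. invert the signal model to R1(t);
2. apply the linear relaxivity model ``C(t) = (R1(t) - R1(0)) / r1``.

Two signal models are available.  The default (``"sr"``) is the pure
saturation-recovery exponential

    S(t) ∝ 1 - exp(-TD * R1(t)),

neglecting the perturbation of the readout pulses.  A spoiled
gradient-echo steady-state model (``"spgr"``) that includes flip angle
and TR is available behind :class:`~myoflow.curves.SequenceParams`'
``readout`` switch; both are exactly invertible, so either choice
round-trips losslessly with its forward counterpart.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .curves import DynamicCurve, SequenceParams

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Signal exceeds the dynamic range of the signal model.

    Carries the index of the first offending frame in ``frame``.
    """

    def __init__(self, frame: int, message: str) -> None:
        super().__init__(message)
        self.frame = frame


class BaselineError(ValueError):
    """Too few frames to form the pre-contrast baseline."""


def baseline_signal(curve: DynamicCurve, n_baseline_frames: int) -> float:
    """Mean signal of the first ``n_baseline_frames`` (pre-contrast) frames."""
    if n_baseline_frames < 1:
        raise BaselineError("need at least one baseline frame")
    if curve.n < n_baseline_frames:
        raise BaselineError(
            f"curve has {curve.n} frames, fewer than the {n_baseline_frames} requested"
        )
    return float(np.mean(curve.values[:n_baseline_frames]))


def detect_contrast_arrival(curve: DynamicCurve, n_baseline_frames: int,
                            n_sd: float = 5.0) -> int:
    """First frame whose signal exceeds baseline mean + ``n_sd``·SD.

    Guards against bolus frames leaking into the baseline window.
    Returns ``curve.n`` if no frame ever crosses the threshold.
    """
    base = curve.values[:n_baseline_frames]
    thresh = float(np.mean(base)) + n_sd * float(np.std(base))
    above = np.nonzero(curve.values > thresh)[0]
    return int(above[0]) if above.size else curve.n


def _spgr_ratio(e1: np.ndarray, cos_a: float) -> np.ndarray:
    return (1.0 - e1) / (1.0 - cos_a * e1)


def signal_to_r1(curve: DynamicCurve, s_pre: float, seq: SequenceParams) -> np.ndarray:
    """Invert the signal model to the per-frame relaxation rate R1(t), s⁻¹.

    For the saturation-recovery model::

        R1(t) = -(1/TD) * ln(1 - (S(t)/S_pre) * (1 - exp(-TD * R1_0)))

    Raises
    ------
    SaturationError
        If any frame's signal lies beyond the model's dynamic range
        (log argument <= 0); the error names the first offending frame.
    """
    if curve.kind != "signal":
        raise ValueError("curve.kind must be 'signal'")
    if s_pre <= 0:
        raise ValueError("baseline signal must be positive")
    ratio = curve.values / s_pre
    if seq.readout == "sr":
        sat0 = 1.0 - math.exp(-seq.td * seq.r1_0)
        arg = 1.0 - ratio * sat0
        bad = np.nonzero(arg <= 0)[0]
        if bad.size:
            raise SaturationError(
                int(bad[0]),
                f"frame {int(bad[0])}: signal beyond the saturation-recovery "
                f"dynamic range (S/S_pre = {ratio[bad[0]]:.3g})",
            )
        return -np.log(arg) / seq.td
    # Spoiled gradient-echo: S ∝ sin(a) (1 - E1) / (1 - cos(a) E1) with
    # E1 = exp(-TD * R1); solved for E1 in closed form.
    cos_a = math.cos(math.radians(seq.flip_angle_deg))
    e1_0 = math.exp(-seq.td * seq.r1_0)
    r = ratio * _spgr_ratio(np.array(e1_0), cos_a)
    denom = 1.0 - r * cos_a
    e1 = (1.0 - r) / denom
    bad = np.nonzero((e1 <= 0) | (denom <= 0))[0]
    if bad.size:
        raise SaturationError(
            int(bad[0]),
            f"frame {int(bad[0])}: signal beyond the SPGR dynamic range",
        )
    return -np.log(e1) / seq.td


def r1_to_concentration(
    r1_t: np.ndarray,
    r1_0: float,
    relaxivity: float,
    *,
    like: DynamicCurve | None = None,
    times: np.ndarray | None = None,
) -> DynamicCurve:
    """Linear relaxivity model ``C(t) = (R1(t) - R1_0) / r1`` in mM.

    Negative concentrations (baseline noise) are retained; their count
    and extreme value are reported at WARNING level for the QC log.
    Provide ``like`` (a source curve donating times and metadata) or an
    explicit ``times`` array.
    """
    if relaxivity <= 0:
        raise ValueError("relaxivity must be positive")
    conc = (np.asarray(r1_t, dtype=float) - r1_0) / relaxivity
    n_neg = int(np.sum(conc < 0))
    if n_neg:
        logger.debug("conversion produced %d negative concentration samples "
                     "(min %.4g mM)", n_neg, float(conc.min()))
    if like is not None:
        return like.with_values(conc, kind="concentration")
    if times is None:
        raise ValueError("provide either `like` or `times`")
    return DynamicCurve(times=times, values=conc, kind="concentration")


def convert_curve(curve: DynamicCurve, seq: SequenceParams) -> DynamicCurve:
    """Full signal → concentration conversion for one curve."""
    s_pre = baseline_signal(curve, seq.n_baseline_frames)
    r1_t = signal_to_r1(curve, s_pre, seq)
    return r1_to_concentration(r1_t, seq.r1_0, seq.relaxivity, like=curve)
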