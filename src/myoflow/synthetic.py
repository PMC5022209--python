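"""Synthetic first-pass perfusion cohorts with known ground truth.

No public first-pass perfusion dataset accompanies the study design
this package targets, so every downstream stage is exercised against
simulated data: a gamma-variate surrogate for the arterial input
function, tissue curves generated by the distributed-parameter forward
model, and whole stress/rest cohorts whose group-wise haemodynamics
follow configurable normal distributions (defaults: the per-patient
DP-model summary statistics of the target study — Group 1 stress MBF
2.53 ± 0.37, Group 2 1.41 ± 0.46 mL/min/mL, with perfusion reserve
2.26 ± 0.61 and 1.21 ± 0.39).

Vessels of obstructive-CAD patients receive angiographic labels that
satisfy the Group-2 rule (stenosis ≥ 70 %, or ≥ 50 % with FFR ≤ 0.80);
all other vessels fail it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .aha import DEFAULT_TERRITORIES, AngioLabel, validate_mapping
from .curves import DynamicCurve, SequenceParams
from .kinetics import DPParams, model_tissue_curve


class SimulationError(ValueError):
    """Raised for impossible simulation specifications."""


# ---------------------------------------------------------------------------
# Arterial input function
# ---------------------------------------------------------------------------

@dataclass
class AIFParams:
    """Gamma-variate arterial input surrogate.

    ``peak_amplitude`` (mM) is the first-pass peak; the curve is the
    peak-normalised gamma variate

        C_a(t) = peak · x^alpha · exp(alpha (1 - x)),  x = (t - t0)/t_p

    for ``t > t0`` and zero before.  ``recirculation_fraction`` adds a
    delayed, broadened copy scaled by that fraction.
    """

    peak_amplitude: float = 4.0
    t0: float = 10.0
    t_p: float = 6.0
    alpha: float = 3.0
    recirculation_fraction: float = 0.0
    recirculation_delay: float = 20.0

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0:
            raise SimulationError("peak amplitude must be positive")
        if self.t_p <= 0 or self.alpha <= 0:
            raise SimulationError("t_p and alpha must be positive")
        if not 0 <= self.recirculation_fraction < 1:
            raise SimulationError("recirculation fraction must lie in [0, 1)")


def gamma_variate_aif(params: AIFParams, times: np.ndarray) -> DynamicCurve:
    """Evaluate the gamma-variate AIF on a time grid (seconds)."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise SimulationError("times must be non-decreasing")

    def first_pass(tt: np.ndarray, width: float) -> np.ndarray:
        x = (tt - params.t0) / width
        pos = x > 0
        out = np.zeros_like(tt)
        out[pos] = np.power(x[pos], params.alpha) * np.exp(params.alpha * (1.0 - x[pos]))
        return out

    vals = params.peak_amplitude * first_pass(t, params.t_p)
    if params.recirculation_fraction > 0:
        # Recirculated bolus: delayed and dispersed (doubled width).
        vals = vals + params.recirculation_fraction * params.peak_amplitude * \
            first_pass(t - params.recirculation_delay, 2.0 * params.t_p)
    return DynamicCurve(times=t, values=vals, kind="concentration", role="aif")


def saturate_aif(curve: DynamicCurve, cap: float) -> DynamicCurve:
    """Soft-clip an AIF above ``cap`` mM, emulating signal saturation.

    Applies ``cap * tanh(C / cap)``: linear for small concentrations and
    asymptotically flat at ``cap``, mimicking the compression of the
    measured blood-pool signal at high gadolinium concentration.
    """
    if cap <= 0:
        raise SimulationError("saturation cap must be positive")
    return curve.with_values(cap * np.tanh(curve.values / cap))


# ---------------------------------------------------------------------------
# Forward tissue simulation
# ---------------------------------------------------------------------------

def simulate_tissue_curve(
    aif: DynamicCurve,
    truth: DPParams,
    dt: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> DynamicCurve:
    """Tissue curve ``F · (R_DP ⊛ C_a)`` plus additive Gaussian noise.

    The AIF must already live on a uniform grid of spacing ``dt``;
    resample first if it does not.
    """
    step = aif.grid_spacing()
    if abs(step - dt) > 1e-9:
        raise SimulationError(
            f"AIF grid spacing {step:.4g} s does not match dt={dt:.4g} s; resample first"
        )
    clean = model_tissue_curve(aif, "dp", truth, delay=truth.tau_d)
    if noise_sd < 0:
        raise SimulationError("noise SD must be non-negative")
    if noise_sd == 0:
        return clean
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return clean.with_values(clean.values + rng.normal(0.0, noise_sd, clean.n))


def concentration_to_signal(
    conc: DynamicCurve,
    seq: SequenceParams,
    s_pre: float = 100.0,
) -> DynamicCurve:
    """Forward signal model: concentration → saturation-recovery signal.

    Exact inverse of :func:`myoflow.concentration.signal_to_r1` followed
    by the relaxivity step, for either readout model.  With zero
    concentration the output equals the baseline signal ``s_pre``.
    """
    r1_t = seq.r1_0 + seq.relaxivity * conc.values
    if seq.readout == "sr":
        sat0 = 1.0 - math.exp(-seq.td * seq.r1_0)
        vals = s_pre * (1.0 - np.exp(-seq.td * r1_t)) / sat0
    else:
        cos_a = math.cos(math.radians(seq.flip_angle_deg))
        e1 = np.exp(-seq.td * r1_t)
        e1_0 = math.exp(-seq.td * seq.r1_0)
        vals = s_pre * ((1.0 - e1) / (1.0 - cos_a * e1)) / \
            ((1.0 - e1_0) / (1.0 - cos_a * e1_0))
    return conc.with_values(vals, kind="signal")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Distribution parameters driving a synthetic stress/rest cohort.

    Group-wise means and SDs are per *territory* ground truth: stress
    MBF is drawn from a normal truncated below at ``truncation_floor``;
    rest MBF follows as stress divided by a likewise-drawn perfusion
    reserve, so the simulated MPR distributions match the requested
    ones by construction.
    """

    n_group1_patients: int = 8
    n_group2_patients: int = 16
    mbf_stress_mean: Dict[int, float] = field(default_factory=lambda: {1: 2.53, 2: 1.41})
    mbf_stress_sd: Dict[int, float] = field(default_factory=lambda: {1: 0.37, 2: 0.46})
    mpr_mean: Dict[int, float] = field(default_factory=lambda: {1: 2.26, 2: 1.21})
    mpr_sd: Dict[int, float] = field(default_factory=lambda: {1: 0.61, 2: 0.39})
    vessels_per_patient: int = 3
    territories: Dict[str, Tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TERRITORIES))
    #: probabilities of 1-, 2- and 3-vessel disease for Group-2 patients
    disease_extent_probs: Tuple[float, float, float] = (10 / 16, 2 / 16, 4 / 16)
    segment_jitter_sd: float = 0.05
    noise_sd: float = 0.03
    n_frames: int = 50
    dt: float = 1.0
    aif_stress: AIFParams = field(default_factory=AIFParams)
    aif_rest: AIFParams = field(default_factory=AIFParams)
    aif_saturation_cap: Optional[float] = None
    v_p: float = 0.08
    v_e: float = 0.25
    ps: float = 1.0
    max_delay_frames: int = 2
    truncation_floor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1_patients < 0 or self.n_group2_patients < 0:
            raise SimulationError("patient counts must be non-negative")
        if self.n_group1_patients + self.n_group2_patients < 1:
            raise SimulationError("cohort must contain at least one patient")
        for d in (self.mbf_stress_sd, self.mpr_sd):
            if any(v < 0 for v in d.values()):
                raise SimulationError("SDs must be non-negative")
        if self.vessels_per_patient != len(self.territories):
            raise SimulationError("vessels_per_patient must match the territory map")
        validate_mapping(self.territories)
        if self.noise_sd < 0 or self.segment_jitter_sd < 0:
            raise SimulationError("noise and jitter SDs must be non-negative")
        if self.n_frames < 2 or self.dt <= 0:
            raise SimulationError("need at least two frames with positive spacing")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class SyntheticSubject:
    """One simulated patient: curves, ground truth and angiography."""

    subject_id: str
    group: int
    aif: Dict[str, DynamicCurve]
    tissue: Dict[Tuple[str, int], DynamicCurve]
    truth: Dict[Tuple[str, int], DPParams]
    territory_truth: Dict[str, Dict[str, float]]
    labels: List[AngioLabel]

    def __post_init__(self) -> None:
        phases = {p for p, _ in self.tissue}
        if self.tissue and phases != {"stress", "rest"}:
            raise SimulationError("both stress and rest phases are required")
        for phase in phases:
            segs = sorted(s for p, s in self.tissue if p == phase)
            if segs != list(range(1, 17)):
                raise SimulationError(f"{phase}: expected exactly segments 1..16")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float) -> float:
    """Redraw until above the floor (degenerate specs fall back to the floor)."""
    if sd == 0:
        return max(mean, floor)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    return floor + abs(rng.normal(0, sd))  # pragma: no cover - pathological spec


def _draw_label(rng: np.random.Generator, vessel: str, diseased: bool) -> AngioLabel:
    if diseased:
        if rng.random() < 0.5:
            # Severe stenosis alone is sufficient.
            return AngioLabel(vessel=vessel, stenosis_pct=float(rng.uniform(70, 95)),
                              ffr=float(rng.uniform(0.4, 0.9)) if rng.random() < 0.5 else None)
        return AngioLabel(vessel=vessel, stenosis_pct=float(rng.uniform(50, 69)),
                          ffr=float(rng.uniform(0.5, 0.80)))
    if rng.random() < 0.8:
        return AngioLabel(vessel=vessel, stenosis_pct=float(rng.uniform(0, 49)), ffr=None)
    # Intermediate stenosis rescued by a normal FFR.
    return AngioLabel(vessel=vessel, stenosis_pct=float(rng.uniform(50, 69)),
                      ffr=float(rng.uniform(0.81, 1.0)))


def simulate_cohort(spec: CohortSpec, with_curves: bool = True) -> List[SyntheticSubject]:
    """Simulate a full stress/rest cohort with known ground truth.

    Group-2 patients receive 1–3 diseased vessels (extent drawn from
    ``disease_extent_probs``); diseased territories draw their
    haemodynamics from the Group-2 distributions, all other territories
    from Group 1.  Per-segment multiplicative jitter perturbs the
    territory flow, curves are generated by the DP forward model with a
    random bolus-arrival delay of 0–``max_delay_frames`` frames, and
    additive Gaussian concentration noise is applied.  Deterministic
    for a fixed ``spec.seed``.

    Set ``with_curves=False`` to draw ground truth and labels only
    (fast path for distribution-level checks).
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times
    subjects: List[SyntheticSubject] = []
    group_of_patient = [1] * spec.n_group1_patients + [2] * spec.n_group2_patients
    vessels = list(spec.territories)

    for i_pat, group in enumerate(group_of_patient):
        subject_id = f"S{i_pat + 1:03d}"
        if group == 2:
            n_dis = int(rng.choice([1, 2, 3], p=spec.disease_extent_probs))
            diseased = set(rng.choice(vessels, size=n_dis, replace=False))
        else:
            diseased = set()

        aif = {
            "stress": gamma_variate_aif(spec.aif_stress, times),
            "rest": gamma_variate_aif(spec.aif_rest, times),
        }
        tissue: Dict[Tuple[str, int], DynamicCurve] = {}
        truth: Dict[Tuple[str, int], DPParams] = {}
        territory_truth: Dict[str, Dict[str, float]] = {}
        labels: List[AngioLabel] = []

        for vessel in vessels:
            v_group = 2 if vessel in diseased else 1
            stress_mbf = _truncated_normal(
                rng, spec.mbf_stress_mean[v_group], spec.mbf_stress_sd[v_group],
                spec.truncation_floor)
            mpr_true = _truncated_normal(
                rng, spec.mpr_mean[v_group], spec.mpr_sd[v_group],
                spec.truncation_floor)
            rest_mbf = stress_mbf / mpr_true
            territory_truth[vessel] = {
                "group": float(v_group), "mbf_stress": stress_mbf,
                "mbf_rest": rest_mbf, "mpr": mpr_true,
            }
            labels.append(_draw_label(rng, vessel, vessel in diseased))

            for seg in spec.territories[vessel]:
                jitter = max(0.05, 1.0 + rng.normal(0.0, spec.segment_jitter_sd))
                delay = float(rng.integers(0, spec.max_delay_frames + 1)) * spec.dt
                for phase, f in (("stress", stress_mbf), ("rest", rest_mbf)):
                    p = DPParams(flow=max(f * jitter, 0.02), v_p=spec.v_p,
                                 v_e=spec.v_e, ps=spec.ps, tau_d=delay)
                    truth[(phase, seg)] = p
                    if with_curves:
                        tissue[(phase, seg)] = simulate_tissue_curve(
                            aif[phase], p, spec.dt, spec.noise_sd, rng)
                        tissue[(phase, seg)] = replace(
                            tissue[(phase, seg)], role="tissue", segment=seg,
                            phase=phase, subject=subject_id)

        if spec.aif_saturation_cap is not None and with_curves:
            aif = {ph: saturate_aif(c, spec.aif_saturation_cap) for ph, c in aif.items()}
        for ph in aif:
            aif[ph] = replace(aif[ph], phase=ph, subject=subject_id)

        subjects.append(SyntheticSubject(
            subject_id=subject_id, group=2 if diseased else 1, aif=aif,
            tissue=tissue if with_curves else {}, truth=truth,
            territory_truth=territory_truth, labels=[
                replace(l, subject=subject_id) for l in labels],
        ))
    return subjects
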