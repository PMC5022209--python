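"""AHA 16-segment aggregation and angiographic classification.

Segment-level MBF estimates are rolled up to the three epicardial
coronary territories (LAD, LCX, RCA) and to patient-level scores, and
vessels/patients are classified into Group 1 (no, minor or
non-obstructive CAD) versus Group 2 (obstructive CAD) from invasive
angiography: Group 2 means luminal stenosis ≥ 70 %, or stenosis ≥ 50 %
with fractional flow reserve ≤ 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Default segment → territory assignment of the 16-segment model
#: (apical four-segment ring; no apex segment 17).
DEFAULT_TERRITORIES: dict[str, tuple[int, ...]] = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "RCA": (3, 4, 9, 10, 15),
    "LCX": (5, 6, 11, 12, 16),
}

VESSELS = tuple(DEFAULT_TERRITORIES)


class MappingError(ValueError):
    """Raised for invalid segment→territory mappings or missing segments."""


class IndeterminateVesselError(ValueError):
    """Stenosis in [50, 70) % without an FFR measurement cannot be classified."""


class DegenerateRestError(ValueError):
    """Rest MBF below the floor makes the perfusion-reserve ratio meaningless."""


def validate_mapping(mapping: Mapping[str, Sequence[int]]) -> None:
    """Assert the mapping partitions segments 1..16 (no overlaps, no gaps)."""
    seen: list[int] = []
    for vessel, segs in mapping.items():
        seen.extend(int(s) for s in segs)
    if sorted(seen) != list(range(1, 17)):
        raise MappingError(
            "segment mapping must partition {1..16}; got " + repr(sorted(seen))
        )


validate_mapping(DEFAULT_TERRITORIES)


@dataclass
class AngioLabel:
    """Invasive angiography result for one vessel.

    ``stenosis_pct`` in [0, 100]; ``ffr`` is the distal-to-aortic
    pressure ratio in (0, 1], or ``None`` when not measured.
    """

    vessel: str
    stenosis_pct: float
    ffr: Optional[float] = None
    subject: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.stenosis_pct <= 100:
            raise ValueError("stenosis must lie in [0, 100] %")
        if self.ffr is not None and not 0 < self.ffr <= 1:
            raise ValueError("FFR must lie in (0, 1]")


def _segments_for(vessel: str, mapping: Mapping[str, Sequence[int]] | None) -> tuple[int, ...]:
    mapping = DEFAULT_TERRITORIES if mapping is None else mapping
    if mapping is not DEFAULT_TERRITORIES:
        validate_mapping(mapping)
    if vessel not in mapping:
        raise MappingError(f"unknown vessel {vessel!r}; expected one of {sorted(mapping)}")
    return tuple(int(s) for s in mapping[vessel])


def territory_mean(
    segment_values: Mapping[int, float],
    vessel: str,
    mapping: Mapping[str, Sequence[int]] | None = None,
) -> float:
    """Arithmetic mean of a per-segment quantity over one vessel territory."""
    segs = _segments_for(vessel, mapping)
    missing = [s for s in segs if s not in segment_values]
    if missing:
        raise MappingError(f"missing segments {missing} for vessel {vessel}")
    return float(np.mean([segment_values[s] for s in segs]))


def mpr(stress_mbf: float, rest_mbf: float, floor: float = 0.05) -> float:
    """Myocardial perfusion reserve: hyperaemic over resting MBF."""
    if rest_mbf < floor:
        raise DegenerateRestError(
            f"rest MBF {rest_mbf:.3g} below floor {floor:.3g} mL/min/mL"
        )
    return stress_mbf / rest_mbf


def mpr2(
    segment_mprs: Mapping[int, float],
    vessel: str,
    mapping: Mapping[str, Sequence[int]] | None = None,
) -> float:
    """Mean MPR of the two lowest-scoring segments in a territory."""
    segs = _segments_for(vessel, mapping)
    missing = [s for s in segs if s not in segment_mprs]
    if missing:
        raise MappingError(f"missing segments {missing} for vessel {vessel}")
    if len(segs) < 2:
        raise MappingError(f"vessel {vessel} maps fewer than 2 segments")
    vals = sorted(segment_mprs[s] for s in segs)
    return float(np.mean(vals[:2]))


def classify_vessel(label: AngioLabel) -> int:
    """Group 2 iff stenosis ≥ 70 %, or stenosis ≥ 50 % with FFR ≤ 0.80.

    Raises
    ------
    IndeterminateVesselError
        For stenosis in [50, 70) % without an FFR value — the rule
        cannot be evaluated there.
    """
    if label.stenosis_pct >= 70:
        return 2
    if label.stenosis_pct >= 50:
        if label.ffr is None:
            raise IndeterminateVesselError(
                f"vessel {label.vessel}: stenosis {label.stenosis_pct:.0f} % in "
                "[50, 70) requires an FFR measurement"
            )
        return 2 if label.ffr <= 0.80 else 1
    return 1


def classify_patient(vessel_groups: Iterable[int]) -> int:
    """Group 2 iff at least one vessel is Group 2."""
    groups = list(vessel_groups)
    if not groups:
        raise ValueError("patient has no classified vessels")
    if any(g not in (1, 2) for g in groups):
        raise ValueError("vessel groups must be 1 or 2")
    return max(groups)


def patient_score(
    territory_values: Mapping[str, float],
    method: str = "min",
    territory_groups: Mapping[str, int] | None = None,
) -> float:
    """Roll three territory values up to one patient-level score.

    ``method``:

    * ``"min"`` (default) — the most-ischaemic territory; a prospective
      score that needs no knowledge of angiography.
    * ``"mean"`` — mean of the three territories.
    * ``"mean_diseased"`` — mean over Group-2 territories (evaluation
      only; requires ``territory_groups``; falls back to the overall
      mean for patients without diseased territories).
    """
    vals = dict(territory_values)
    if not vals:
        raise ValueError("no territory values supplied")
    if method == "min":
        return float(min(vals.values()))
    if method == "mean":
        return float(np.mean(list(vals.values())))
    if method == "mean_diseased":
        if territory_groups is None:
            raise ValueError("mean_diseased requires territory_groups")
        diseased = [v for k, v in vals.items() if territory_groups.get(k) == 2]
        return float(np.mean(diseased if diseased else list(vals.values())))
    raise ValueError(f"unknown patient aggregation method {method!r}")
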