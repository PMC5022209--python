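"""Stable on-disk formats: curve CSV, angiography CSV, report JSON.

Curve schema (one row per sampled frame)::

    subject, phase, segment, frame, time_s, value, kind

``segment`` is ``1``–``16`` for myocardium or ``AIF`` for the arterial
input; ``kind`` is ``signal`` or ``concentration``.  Angiography
labels::

    subject, vessel, stenosis_pct, ffr

with an empty ``ffr`` field meaning "not measured".
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .aha import AngioLabel
from .curves import DynamicCurve
from .synthetic import SyntheticSubject

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["subject", "phase", "segment", "frame", "time_s", "value", "kind"]
LABEL_COLUMNS = ["subject", "vessel", "stenosis_pct", "ffr"]


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


def _require_columns(df: pd.DataFrame, required: List[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_curves(path: str | Path) -> Dict[Tuple[str, str, str], DynamicCurve]:
    """Read a curve CSV into ``{(subject, phase, segment_key): DynamicCurve}``.

    ``segment_key`` is ``"AIF"`` or the segment number as a string.
    Rows out of time order are re-sorted with a warning; duplicate
    ``(subject, phase, segment, frame)`` keys or non-increasing times
    after sorting raise :class:`SchemaError` naming the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"curve file {path} does not exist")
    df = pd.read_csv(path)
    _require_columns(df, CURVE_COLUMNS, path)

    dup = df.duplicated(subset=["subject", "phase", "segment", "frame"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]  # +2: header + 1-based
        raise SchemaError(f"{path}: duplicate (subject, phase, segment, frame) "
                          f"keys at rows {rows}")

    curves: Dict[Tuple[str, str, str], DynamicCurve] = {}
    for (subject, phase, segment), g in df.groupby(
            ["subject", "phase", "segment"], sort=True):
        g_frame = g.sort_values("frame")
        times = g_frame["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            g_time = g.sort_values("time_s")
            t_sorted = g_time["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t_sorted) <= 0):
                rows = (g.index[:5] + 2).tolist()
                raise SchemaError(
                    f"{path}: non-increasing times for {subject}/{phase}/{segment} "
                    f"(rows near {rows})")
            logger.warning("curves %s/%s/%s out of frame order; re-sorted by time",
                           subject, phase, segment)
            g_frame = g_time
            times = t_sorted
        kinds = g_frame["kind"].unique()
        if len(kinds) != 1 or kinds[0] not in ("signal", "concentration"):
            raise SchemaError(f"{path}: inconsistent kind for {subject}/{phase}/{segment}")
        seg_key = str(segment).upper() if str(segment).upper() == "AIF" else str(int(segment))
        curves[(str(subject), str(phase), seg_key)] = DynamicCurve(
            times=times,
            values=g_frame["value"].to_numpy(dtype=float),
            kind=str(kinds[0]),
            role="aif" if seg_key == "AIF" else "tissue",
            segment=None if seg_key == "AIF" else int(seg_key),
            phase=str(phase),
            subject=str(subject),
        )
    return curves


def curves_to_frame(subjects: List[SyntheticSubject]) -> pd.DataFrame:
    """Flatten simulated subjects into the curve CSV schema."""
    rows = []
    for s in subjects:
        for phase, curve in sorted(s.aif.items()):
            for i, (t, v) in enumerate(zip(curve.times, curve.values)):
                rows.append((s.subject_id, phase, "AIF", i, t, v, curve.kind))
        for (phase, seg), curve in sorted(s.tissue.items()):
            for i, (t, v) in enumerate(zip(curve.times, curve.values)):
                rows.append((s.subject_id, phase, str(seg), i, t, v, curve.kind))
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def write_curves(subjects: List[SyntheticSubject], path: str | Path) -> None:
    curves_to_frame(subjects).to_csv(path, index=False)


def read_labels(path: str | Path) -> List[AngioLabel]:
    """Read the angiography label CSV; empty FFR means "not measured"."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"label file {path} does not exist")
    df = pd.read_csv(path)
    _require_columns(df, LABEL_COLUMNS, path)
    dup = df.duplicated(subset=["subject", "vessel"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicate (subject, vessel) keys at rows {rows}")
    labels = []
    for i, row in df.iterrows():
        try:
            labels.append(AngioLabel(
                vessel=str(row["vessel"]),
                stenosis_pct=float(row["stenosis_pct"]),
                ffr=None if pd.isna(row["ffr"]) else float(row["ffr"]),
                subject=str(row["subject"]),
            ))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return labels


def write_labels(labels: List[AngioLabel], path: str | Path) -> None:
    pd.DataFrame(
        [(l.subject, l.vessel, l.stenosis_pct, l.ffr) for l in labels],
        columns=LABEL_COLUMNS,
    ).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Write an evaluation report as deterministic, sorted JSON."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=1, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
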