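"""Reading, validation and preprocessing of long-format isokinetic trials.

The working container is a pandas DataFrame with the canonical columns
``athlete_id, action, mode, repetition, angle_deg, velocity_dps, torque_nm``
(one row per dynamometer sample).  Angles follow the anatomical convention:
0 deg = full knee extension, 90 deg = deep flexion (the start of an extension
effort).  Preprocessing reduces raw trials to one model-ready series per
(athlete, action, mode): only "truly" isokinetic samples — those recorded
while the limb actually moved at the target angular velocity — are kept, and
a single best repetition (greatest peak torque) represents each group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = (
    "athlete_id", "action", "mode", "repetition",
    "angle_deg", "velocity_dps", "torque_nm",
)
ACTIONS = ("extension", "flexion")
MODES = ("concentric", "eccentric")
GROUP_KEYS = ["athlete_id", "action", "mode"]

ANGLE_MIN = 0.0
ANGLE_MAX = 90.0

#: default velocity tolerance: 10% of the 60 deg/s target
DEFAULT_TARGET_VELOCITY = 60.0
DEFAULT_TOLERANCE = 6.0


@dataclass(frozen=True)
class TorqueSample:
    """One dynamometer reading."""

    athlete_id: str
    action: str
    mode: str
    repetition: int
    angle_deg: float
    velocity_dps: float
    torque_nm: float


@dataclass
class ActionSeries:
    """The selected best repetition of one (athlete, action, mode) group."""

    athlete_id: str
    action: str
    mode: str
    repetition: int
    angle_deg: np.ndarray
    torque_nm: np.ndarray
    axis: str = "flexion_angle"  # or "extension_progress"

    def __len__(self) -> int:
        return len(self.angle_deg)


@dataclass
class RejectionReport:
    """Counts of rows dropped during validation, by reason."""

    n_input: int = 0
    n_valid: int = 0
    by_reason: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.by_reason.values())


def _reject(report: RejectionReport, mask: pd.Series, reason: str) -> pd.Series:
    n = int(mask.sum())
    if n:
        report.by_reason[reason] = report.by_reason.get(reason, 0) + n
        logger.warning("rejected %d rows: %s", n, reason)
    return ~mask


def validate_trials(df: pd.DataFrame) -> tuple[pd.DataFrame, RejectionReport]:
    """Validate canonical-column trial data; return (clean frame, report).

    Rows with out-of-range angles, non-finite torques, unknown action/mode
    labels, non-positive repetition numbers or unparseable numeric cells are
    dropped and counted; a missing column is a hard error.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    report = RejectionReport(n_input=len(df))
    df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    for col in ("repetition", "angle_deg", "velocity_dps", "torque_nm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    keep = pd.Series(True, index=df.index)
    numeric_bad = df[["repetition", "angle_deg", "velocity_dps"]].isna().any(axis=1)
    keep &= _reject(report, numeric_bad, "unparseable numeric cell")
    keep &= _reject(report, keep & ~df["torque_nm"].apply(np.isfinite), "non-finite torque")
    keep &= _reject(report, keep & ~df["action"].isin(ACTIONS), "unknown action label")
    keep &= _reject(report, keep & ~df["mode"].isin(MODES), "unknown mode label")
    keep &= _reject(report, keep & (df["repetition"] < 1), "repetition < 1")
    out_of_range = keep & ((df["angle_deg"] < ANGLE_MIN) | (df["angle_deg"] > ANGLE_MAX))
    keep &= _reject(report, out_of_range, "angle outside [0, 90]")

    clean = df.loc[keep].copy()
    clean["repetition"] = clean["repetition"].astype(int)
    report.n_valid = len(clean)
    return clean, report


def read_trials(path, column_map: Mapping[str, str] | None = None
                ) -> tuple[pd.DataFrame, RejectionReport]:
    """Read a trial CSV, remap columns if needed, and validate.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"torque_nm": "moment"}``.
    """
    raw = pd.read_csv(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    return validate_trials(raw)


def filter_isokinetic(df: pd.DataFrame,
                      target_velocity_dps: float = DEFAULT_TARGET_VELOCITY,
                      tolerance_dps: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Keep only truly isokinetic samples: | |velocity| - target | <= tolerance.

    Flexion and extension phases carry opposite velocity signs in raw exports,
    so the criterion compares speeds.  Row order is preserved.  Groups emptied
    by the filter are warned about.
    """
    if not tolerance_dps > 0:
        raise ValueError("tolerance_dps must be positive")
    mask = (df["velocity_dps"].abs() - target_velocity_dps).abs() <= tolerance_dps
    out = df.loc[mask]
    if len(out) < len(df):
        emptied = set(map(tuple, df[GROUP_KEYS].drop_duplicates().itertuples(index=False))) \
            - set(map(tuple, out[GROUP_KEYS].drop_duplicates().itertuples(index=False)))
        for grp in sorted(emptied, key=str):
            logger.warning("group %s has no truly isokinetic samples left", grp)
    return out


def peak_torque_by_repetition(df: pd.DataFrame) -> pd.DataFrame:
    """Peak torque per (athlete, action, mode, repetition)."""
    return (df.groupby(GROUP_KEYS + ["repetition"], sort=True)["torque_nm"]
            .max().rename("peak_torque_nm").reset_index())


def select_best_repetition(df: pd.DataFrame) -> list[ActionSeries]:
    """Reduce each (athlete, action, mode) group to its best repetition.

    "Best" is the repetition with the greatest peak torque; ties go to the
    lowest repetition number.  Empty groups are omitted with a warning.
    """
    series: list[ActionSeries] = []
    if df.empty:
        return series
    peaks = peak_torque_by_repetition(df)
    # idxmax on a frame sorted by repetition implements the tie-break
    best = peaks.loc[peaks.groupby(GROUP_KEYS, sort=True)["peak_torque_nm"].idxmax()]
    for row in best.itertuples(index=False):
        grp = df[(df["athlete_id"] == row.athlete_id)
                 & (df["action"] == row.action)
                 & (df["mode"] == row.mode)
                 & (df["repetition"] == row.repetition)]
        series.append(ActionSeries(
            athlete_id=row.athlete_id, action=row.action, mode=row.mode,
            repetition=int(row.repetition),
            angle_deg=grp["angle_deg"].to_numpy(dtype=float),
            torque_nm=grp["torque_nm"].to_numpy(dtype=float),
        ))
    return series


def rescale_extension_angle(angle_deg):
    """Map anatomical knee-flexion angle to extension progress: 90 - angle.

    Extension starts at 90 deg of knee flexion; on the rescaled axis 0 deg is
    the start of the action.  The map is an involution.
    """
    a = np.asarray(angle_deg, dtype=float)
    if a.size and (a.min() < ANGLE_MIN or a.max() > ANGLE_MAX):
        raise ValueError("angle outside [0, 90]")
    out = ANGLE_MAX - a
    return float(out) if np.isscalar(angle_deg) else out


def series_to_frame(series: list[ActionSeries]) -> pd.DataFrame:
    """Stack ActionSeries into a long frame (athlete, action, mode, angle, torque)."""
    frames = [pd.DataFrame({
        "athlete_id": s.athlete_id, "action": s.action, "mode": s.mode,
        "repetition": s.repetition, "angle_deg": s.angle_deg,
        "torque_nm": s.torque_nm, "axis": s.axis,
    }) for s in series]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["athlete_id", "action", "mode", "repetition",
                 "angle_deg", "torque_nm", "axis"])


def preprocess(df: pd.DataFrame,
               target_velocity_dps: float = DEFAULT_TARGET_VELOCITY,
               tolerance_dps: float = DEFAULT_TOLERANCE) -> dict[tuple[str, str], list[ActionSeries]]:
    """Full preprocessing: isokinetic filter then best-repetition selection.

    Returns the series grouped per (action, mode) — the four datasets the
    hierarchical model fits independently.
    """
    filtered = filter_isokinetic(df, target_velocity_dps, tolerance_dps)
    out: dict[tuple[str, str], list[ActionSeries]] = {}
    for s in select_best_repetition(filtered):
        out.setdefault((s.action, s.mode), []).append(s)
    return out
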