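"""Quality control: motion exclusion, behavioral exclusion, node harmonization.

Motion is summarized from the six rigid-body realignment parameters
(3 rotations in radians, then 3 translations in mm per volume) as the
volume-to-volume relative root-mean-squared displacement over an 80 mm
sphere (the rigid-body RMS formula used throughout the FSL motion
literature). Subjects are excluded when mean relative RMS > 0.2 mm or when
more than 20 transitions exceed 0.25 mm. Behavioral exclusion drops
subjects >= 2 SD from the candidate-pool mean on any listed outcome, with
more than 21 days between scan and task, or with missing task data. All
thresholds are configurable; defaults are the published rules.

Node harmonization drops, per subject, parcellation nodes with fewer than
four signal-containing voxels and returns the order-preserving intersection
across subjects — the common node set on which all connectomes are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "QCReport",
    "framewise_rms",
    "mean_relative_rms",
    "apply_motion_exclusion",
    "behavioral_exclusion",
    "combine_reports",
    "harmonize_nodes",
    "exclusion_flow",
]

SPHERE_RADIUS_MM = 80.0

REASONS = ("motion_mean", "motion_spikes", "behavior_outlier", "interval", "missing_tol")


@dataclass
class QCThresholds:
    mean_rms_mm: float = 0.2          # exclude if mean relative RMS exceeds this
    spike_rms_mm: float = 0.25        # a transition above this is a spike
    max_spike_volumes: int = 20       # exclude if spikes exceed this count
    behavior_z: float = 2.0           # |z| >= this (inclusive) is an outlier
    max_interval_days: int = 21       # > this (exclusive) is excluded


@dataclass
class QCReport:
    subject_id: str
    kept: bool
    reasons: list[str] = field(default_factory=list)
    mean_rel_rms_mm: float = float("nan")
    n_spike_volumes: int = 0

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept flag inconsistent with reasons list")
        bad = [r for r in self.reasons if r not in REASONS]
        if bad:
            raise ValueError(f"unknown QC reasons: {bad}")


def _rigid_matrix(params: np.ndarray) -> np.ndarray:
    """4x4 homogeneous transform from (rx, ry, rz [rad], tx, ty, tz [mm])."""
    return _rigid_matrices(np.asarray(params, float)[None, :])[0]


def _rigid_matrices(params: np.ndarray) -> np.ndarray:
    """Batched (T, 4, 4) homogeneous transforms from (T, 6) parameter rows."""
    rx, ry, rz = params[:, 0], params[:, 1], params[:, 2]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    T = len(params)
    z = np.zeros(T)
    o = np.ones(T)
    mx = np.stack([o, z, z, z, cx, sx, z, -sx, cx], -1).reshape(T, 3, 3)
    my = np.stack([cy, z, -sy, z, o, z, sy, z, cy], -1).reshape(T, 3, 3)
    mz = np.stack([cz, sz, z, -sz, cz, z, z, z, o], -1).reshape(T, 3, 3)
    m = np.broadcast_to(np.eye(4), (T, 4, 4)).copy()
    m[:, :3, :3] = mx @ my @ mz
    m[:, :3, 3] = params[:, 3:]
    return m


def _rms_of_transform(m: np.ndarray, radius: float = SPHERE_RADIUS_MM) -> float:
    """RMS displacement of a solid sphere (radius mm, centered at origin)
    under the rigid transform m, relative to identity."""
    a = m[:3, :3] - np.eye(3)
    t = m[:3, 3]
    return float(np.sqrt(radius**2 / 5.0 * np.trace(a.T @ a) + t @ t))


def framewise_rms(motion_params: np.ndarray) -> np.ndarray:
    """Relative (volume-to-volume) RMS displacement in mm, length T-1."""
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError(f"expected (T, 6) motion parameters, got {p.shape}")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 volumes for relative displacement")
    bad = np.nonzero(~np.isfinite(p).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"malformed motion parameters at row {int(bad[0])}")
    mats = _rigid_matrices(p)
    rel = mats[1:] @ np.linalg.inv(mats[:-1])
    a = rel[:, :3, :3] - np.eye(3)
    t = rel[:, :3, 3]
    return np.sqrt(
        SPHERE_RADIUS_MM**2 / 5.0 * np.einsum("tij,tij->t", a, a)
        + np.einsum("ti,ti->t", t, t)
    )


def mean_relative_rms(motion_params: np.ndarray) -> float:
    return float(framewise_rms(motion_params).mean())


def apply_motion_exclusion(
    motion_by_subject: Mapping[str, np.ndarray],
    thresholds: QCThresholds | None = None,
) -> list[QCReport]:
    """Flag subjects whose head motion exceeds the published cut-offs."""
    th = thresholds or QCThresholds()
    reports = []
    for sid, params in motion_by_subject.items():
        rms = framewise_rms(params)
        mean_rms = float(rms.mean())
        n_spikes = int((rms > th.spike_rms_mm).sum())
        reasons = []
        if mean_rms > th.mean_rms_mm:
            reasons.append("motion_mean")
        if n_spikes > th.max_spike_volumes:
            reasons.append("motion_spikes")
        reports.append(
            QCReport(sid, not reasons, reasons, mean_rms, n_spikes)
        )
    return reports


def behavioral_exclusion(
    behavior: pd.DataFrame,
    outcome_columns: Sequence[str] = ("tol_accuracy_pct", "tol_rt_s"),
    thresholds: QCThresholds | None = None,
) -> list[QCReport]:
    """Flag extreme scores, long scan-to-task intervals, and missing task data.

    ``behavior`` needs columns ``subject_id``, ``interval_days`` and the
    outcome columns. Z-scores are computed once on the full candidate pool
    (single pass; no iterative re-exclusion).
    """
    th = thresholds or QCThresholds()
    if len(behavior) < 3:
        raise ValueError("need >= 3 subjects to estimate behavioral SD")
    z = {}
    for col in outcome_columns:
        vals = behavior[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        sd = finite.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in outcome column {col!r}")
        z[col] = (vals - finite.mean()) / sd
    reports = []
    for i, row in behavior.reset_index(drop=True).iterrows():
        reasons = []
        missing = any(not np.isfinite(float(row[c])) for c in outcome_columns)
        if missing:
            reasons.append("missing_tol")
        elif any(abs(z[c][i]) >= th.behavior_z for c in outcome_columns):
            reasons.append("behavior_outlier")
        if float(row["interval_days"]) > th.max_interval_days:
            reasons.append("interval")
        reports.append(QCReport(str(row["subject_id"]), not reasons, reasons))
    return reports


def combine_reports(*report_lists: list[QCReport]) -> list[QCReport]:
    """Merge per-rule reports into one report per subject (union of reasons)."""
    merged: dict[str, QCReport] = {}
    for reports in report_lists:
        for r in reports:
            if r.subject_id not in merged:
                merged[r.subject_id] = QCReport(
                    r.subject_id, r.kept, list(r.reasons), r.mean_rel_rms_mm, r.n_spike_volumes
                )
            else:
                m = merged[r.subject_id]
                reasons = sorted(set(m.reasons) | set(r.reasons))
                rms = m.mean_rel_rms_mm if np.isfinite(m.mean_rel_rms_mm) else r.mean_rel_rms_mm
                merged[r.subject_id] = QCReport(
                    r.subject_id, not reasons, reasons, rms,
                    max(m.n_spike_volumes, r.n_spike_volumes),
                )
    return list(merged.values())


def harmonize_nodes(
    voxel_counts: Mapping[str, np.ndarray],
    node_ids: Sequence[str],
    min_voxels: int = 4,
) -> list[str]:
    """Common node set: drop nodes with < min_voxels in any subject, keep order."""
    node_ids = list(node_ids)
    keep = np.ones(len(node_ids), dtype=bool)
    for sid, counts in voxel_counts.items():
        counts = np.asarray(counts)
        if counts.shape != (len(node_ids),):
            raise ValueError(f"subject {sid}: voxel counts do not match node universe")
        keep &= counts >= min_voxels
    common = [n for n, k in zip(node_ids, keep) if k]
    if not common:
        raise ValueError("harmonization left no common nodes")
    return common


def exclusion_flow(reports: list[QCReport]) -> dict:
    """Flow-chart style summary: totals and per-reason counts (a subject may
    carry several reasons; per-reason counts therefore reconcile as a union)."""
    n_total = len(reports)
    excluded = [r for r in reports if not r.kept]
    per_reason = {reason: sum(reason in r.reasons for r in excluded) for reason in REASONS}
    return {
        "n_candidates": n_total,
        "n_excluded": len(excluded),
        "n_included": n_total - len(excluded),
        "excluded_per_reason": per_reason,
        "excluded_subjects": sorted(r.subject_id for r in excluded),
    }


def reports_table(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in reports],
            "kept": [r.kept for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
            "mean_rel_rms_mm": [r.mean_rel_rms_mm for r in reports],
            "n_spike_volumes": [r.n_spike_volumes for r in reports],
        }
    )
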