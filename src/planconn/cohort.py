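"""Synthetic cohort generator with planted age and network-integration effects.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised without any scanner data:

* regional BOLD-like series — each resting-state network (DMN, FPN, DAN,
  VAN) has a shared band-limited (0.06-0.12 Hz) Gaussian component; a node
  mixes its network's shared signal (weight = the subject's coupling c) with
  private broadband noise (weight sqrt(1 - c^2)); cross-network leakage
  comes from a global component mixed into every network signal;
* motion — a six-parameter rigid-body random walk whose mean relative RMS
  displacement is calibrated to a per-subject severity drawn from a
  lognormal matched to published cohort statistics (0.07 +/- 0.03 mm);
* demographics — age 21-74 (mean/SD 48.1/13.9), sex, Verhage education,
  handedness, scan-to-task interval;
* Tower of London behavior — trial-level responses across difficulty
  levels 1-5; reaction time follows a linear model in age and in the
  subject's (standardized) network coupling, so the planted
  "integration -> slower planning" effect is recoverable by the regression
  stage; accuracy carries a weak negative age effect concentrated at the
  demanding 4- and 5-move levels (floor/ceiling structure at easy levels).

Behavioral noise uses a truncated normal (+/- 1.8 residual SD) so that
spontaneous |z| >= 2 outliers are essentially absent and the planted QC
violators are exactly the subjects a correct QC stage excludes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sps

from planconn import tol
from planconn.graph_metrics import NetworkPartition, RSN_NAMES, OTHER_LABEL

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "simulate_timeseries",
    "simulate_motion",
    "generate_cohort",
]

_VIOLATOR_KINDS = ("motion_mean", "motion_spikes", "behavior", "interval")


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the published cohort: 62 subjects, 192 retained
    volumes at TR = 1.8 s, 225 parcellation nodes of which 31 contain too
    few signal voxels in some subject (leaving 194 common nodes).
    """

    n_subjects: int = 62
    n_volumes: int = 192
    tr_s: float = 1.8
    network_sizes: dict[str, int] = field(
        default_factory=lambda: {"DMN": 40, "FPN": 30, "DAN": 25, "VAN": 20, OTHER_LABEL: 110}
    )
    n_low_voxel_nodes: int = 31
    band_hz: tuple[float, float] = (0.06, 0.12)
    coupling_between: float = 0.3          # weight^2 of the global component in each network signal
    coupling_beta: tuple[float, float] = (2.0, 2.0)  # subject coupling ~ Beta(a, b)
    # demographics (means/SDs follow the published sample characteristics)
    age_mean: float = 48.1
    age_sd: float = 13.9
    age_range: tuple[float, float] = (21.0, 74.0)
    female_fraction: float = 0.468
    education_probs: dict[int, float] = field(
        default_factory=lambda: {3: 0.016, 4: 0.080, 5: 0.290, 6: 0.435, 7: 0.179}
    )
    left_handed_fraction: float = 7 / 61
    interval_mean_days: float = 6.2
    interval_sd_days: float = 4.6
    # behavioral generating model
    rt_mean_s: float = 10.1
    rt_sd_target_s: float = 2.1
    b_age: float = 0.09                    # s per year of age
    b_integration: float = 0.22            # standardized effect of coupling on RT
    sigma_rt: float = 1.65                 # residual RT SD (s), truncated at 1.8 SD
    acc_mean_pct: float = 87.7
    b_age_acc: float = -0.131              # accuracy %-points per year
    sigma_acc: float = 7.0
    trials_per_level: int = 10
    # motion severity ~ lognormal matched to mean 0.07, SD 0.03 mm
    motion_rms_mean_mm: float = 0.07
    motion_rms_sd_mm: float = 0.03
    motion_rms_range_mm: tuple[float, float] = (0.025, 0.17)
    # planted QC violators (disjoint subjects per kind)
    violator_fractions: dict[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in _VIOLATOR_KINDS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_between < 0 or self.coupling_between >= 1:
            raise ValueError("coupling_between must be in [0, 1)")
        if min(self.sigma_rt, self.sigma_acc, self.age_sd) <= 0:
            raise ValueError("variance parameters must be positive")
        bad = set(self.violator_fractions) - set(_VIOLATOR_KINDS)
        if bad:
            raise ValueError(f"unknown violator kinds: {sorted(bad)}")
        if sum(self.violator_fractions.values()) > 1:
            raise ValueError("planted violator fractions sum to more than 1")
        if self.n_low_voxel_nodes > self.n_nodes:
            raise ValueError("more low-voxel nodes than nodes")

    @property
    def n_nodes(self) -> int:
        return sum(self.network_sizes.values())

    @property
    def node_ids(self) -> list[str]:
        return [f"n{i:03d}" for i in range(self.n_nodes)]

    def partition(self) -> NetworkPartition:
        labels = {}
        i = 0
        for name, size in self.network_sizes.items():
            for _ in range(size):
                labels[f"n{i:03d}"] = name
                i += 1
        return NetworkPartition(labels)

    @classmethod
    def emulation_60(cls, **overrides) -> "CohortConfig":
        """Scaled-down 60-node variant used for fast end-to-end emulation."""
        defaults = dict(
            network_sizes={"DMN": 14, "FPN": 12, "DAN": 10, "VAN": 10, OTHER_LABEL: 14},
            n_low_voxel_nodes=0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["education_probs"] = {str(k): v for k, v in self.education_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["education_probs"] = {int(k): v for k, v in d["education_probs"].items()}
        d["band_hz"] = tuple(d["band_hz"])
        d["age_range"] = tuple(d["age_range"])
        d["motion_rms_range_mm"] = tuple(d["motion_rms_range_mm"])
        d["coupling_beta"] = tuple(d["coupling_beta"])
        return cls(**d)


@dataclass
class SubjectRecord:
    """One participant: demographics, motion, time series, behavior."""

    subject_id: str
    age_years: float
    sex: str
    education_verhage: int
    handedness: str
    interval_days: int
    motion_params: np.ndarray              # (n_volumes, 6): rotations rad, translations mm
    voxel_counts: np.ndarray               # per node, full (pre-harmonization) universe
    tol_accuracy_pct: float
    tol_rt_s: float
    tol_accuracy_45_pct: float
    tol_rt_45_s: float
    timeseries: np.ndarray | None = None   # (n_volumes, n_nodes)
    trials: list[tol.TrialResponse] | None = None


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectRecord]
    ground_truth: pd.DataFrame             # coupling, severity, planted_* flags

    @property
    def node_ids(self) -> list[str]:
        return self.config.node_ids

    def partition(self) -> NetworkPartition:
        return self.config.partition()

    def behavior_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "age": s.age_years,
                    "sex": s.sex,
                    "education": s.education_verhage,
                    "handedness": s.handedness,
                    "interval_days": s.interval_days,
                    "tol_accuracy_pct": s.tol_accuracy_pct,
                    "tol_rt_s": s.tol_rt_s,
                    "tol_accuracy_45_pct": s.tol_accuracy_45_pct,
                    "tol_rt_45_s": s.tol_rt_45_s,
                }
            )
        return pd.DataFrame(rows)

    def to_dir(self, path: str | Path) -> Path:
        """Write the cohort as plain-text files (manifest, TSVs, motion .par)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.config.to_dict(),
            "ground_truth": self.ground_truth.to_dict(orient="list"),
            "node_ids": self.node_ids,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        self.behavior_frame().to_csv(path / "demographics.tsv", sep="\t", index=False)
        voxels = pd.DataFrame(
            {s.subject_id: s.voxel_counts for s in self.subjects}, index=self.node_ids
        )
        voxels.rename_axis("node_id").to_csv(path / "voxel_counts.tsv", sep="\t")
        self.partition().to_frame().to_csv(path / "partition.tsv", sep="\t", index=False)
        for s in self.subjects:
            np.savetxt(path / f"{s.subject_id}_motion.par", s.motion_params, fmt="%.10g")
            if s.timeseries is not None:
                pd.DataFrame(s.timeseries, columns=self.node_ids).to_csv(
                    path / f"{s.subject_id}_timeseries.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        config = CohortConfig.from_dict(manifest["config"])
        gt = pd.DataFrame(manifest["ground_truth"])
        demo = pd.read_csv(path / "demographics.tsv", sep="\t")
        voxels = pd.read_csv(path / "voxel_counts.tsv", sep="\t", index_col="node_id")
        subjects = []
        for _, row in demo.iterrows():
            sid = str(row["subject_id"])
            ts_file = path / f"{sid}_timeseries.tsv"
            ts = pd.read_csv(ts_file, sep="\t").to_numpy() if ts_file.exists() else None
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    age_years=float(row["age"]),
                    sex=str(row["sex"]),
                    education_verhage=int(row["education"]),
                    handedness=str(row["handedness"]),
                    interval_days=int(row["interval_days"]),
                    motion_params=np.loadtxt(path / f"{sid}_motion.par").reshape(-1, 6),
                    voxel_counts=voxels[sid].to_numpy(),
                    tol_accuracy_pct=float(row["tol_accuracy_pct"]),
                    tol_rt_s=float(row["tol_rt_s"]),
                    tol_accuracy_45_pct=float(row["tol_accuracy_45_pct"]),
                    tol_rt_45_s=float(row["tol_rt_45_s"]),
                    timeseries=ts,
                )
            )
        return cls(config, subjects, gt)


def _bandlimited_noise(rng: np.random.Generator, n: int, tr_s: float, band) -> np.ndarray:
    """Unit-variance Gaussian noise band-pass filtered into the analysis band."""
    fs = 1.0 / tr_s
    sos = spsig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = spsig.sosfiltfilt(sos, rng.standard_normal(n + 2 * n))[n : 2 * n]
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise RuntimeError("degenerate band-limited signal")
    return x / sd


def simulate_timeseries(
    config: CohortConfig,
    subject_coupling: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """(volumes x nodes) matrix with the cohort's modular band-limited structure.

    Nodes of each named RSN share a band-limited network signal (weight =
    ``subject_coupling``); unassigned ("other") nodes are private noise only.
    Columns are standardized to zero mean, unit variance.
    """
    if not 0 <= subject_coupling < 1:
        raise ValueError("subject coupling must be in [0, 1)")
    if config.n_volumes * config.tr_s < 3.0 / config.band_hz[0]:
        raise ValueError(
            f"{config.n_volumes} volumes at TR={config.tr_s}s cannot resolve "
            f"{config.band_hz[0]} Hz (need >= 3 cycles)"
        )
    rng = np.random.default_rng(rng)
    T = config.n_volumes
    shared_global = _bandlimited_noise(rng, T, config.tr_s, config.band_hz)
    b = config.coupling_between
    net_signal = {}
    for name in RSN_NAMES:
        own = _bandlimited_noise(rng, T, config.tr_s, config.band_hz)
        s = np.sqrt(b) * shared_global + np.sqrt(1.0 - b) * own
        net_signal[name] = (s - s.mean()) / s.std()
    c = subject_coupling
    partition = config.partition()
    labels = [partition.labels[node] for node in config.node_ids]
    noise = rng.standard_normal((T, config.n_nodes))
    shared = np.column_stack(
        [net_signal.get(lab, np.zeros(T)) for lab in labels]
    )
    weights = np.array([c if lab in net_signal else 0.0 for lab in labels])
    x = weights * shared + np.sqrt(1.0 - weights**2) * noise
    x = x - x.mean(axis=0)
    return x / x.std(axis=0)


def simulate_motion(
    config: CohortConfig,
    severity: float,
    rng: np.random.Generator | int | None = None,
    n_spikes: int = 0,
    spike_amplitude_mm: float = 0.3,
) -> np.ndarray:
    """Rigid-body random-walk motion trace calibrated to a target severity.

    ``severity`` is the target mean relative RMS displacement in mm (the
    trace is rescaled so the realized mean matches it closely); zero
    severity returns an identically zero trace. ``n_spikes`` single-volume
    displacements of ``spike_amplitude_mm`` can be injected to plant
    spike-rule violations.
    """
    from planconn.qc import mean_relative_rms

    if severity < 0:
        raise ValueError("severity must be nonnegative")
    rng = np.random.default_rng(rng)
    T = config.n_volumes
    params = np.zeros((T, 6))
    if severity > 0:
        sig_rot = severity / np.sqrt(15360.0)   # (2R^2/5)*3*sig^2 = severity^2/2, R=80
        sig_tr = severity / np.sqrt(6.0)        # 3*sig^2 = severity^2/2
        steps = np.column_stack(
            [rng.normal(0, sig_rot, (T, 3)), rng.normal(0, sig_tr, (T, 3))]
        )
        steps[0] = 0.0
        params = np.cumsum(steps, axis=0)
        for _ in range(3):  # rescale to hit the target mean RMS (near-linear)
            measured = mean_relative_rms(params)
            params *= severity / measured
    if n_spikes > 0:
        vols = rng.choice(np.arange(2, T - 2), size=n_spikes, replace=False)
        params[vols, 3] += spike_amplitude_mm
    return params


def _simulate_trials(
    rng: np.random.Generator,
    trials_per_level: int,
    target_acc_pct: float,
    target_rt_s: float,
) -> list[tol.TrialResponse]:
    """Trial-level ToL responses consistent with subject-level targets.

    Per-level correctness probabilities place easy levels near ceiling and
    concentrate the accuracy deficit at levels 4-5; correct counts are
    rounded deterministically and correct-trial RTs are rescaled so their
    pooled mean equals the target exactly.
    """
    problems = tol.generate_problem_set(trials_per_level, seed=int(rng.integers(2**31)))
    a = target_acc_pct / 100.0
    offsets = {1: 0.10, 2: 0.07, 3: 0.02, 4: -0.07, 5: -0.12}
    trials: list[tol.TrialResponse] = []
    rts = []
    for level in (1, 2, 3, 4, 5):
        level_problems = [p for p in problems if p.min_moves == level]
        p_correct = float(np.clip(a + offsets[level], 0.15, 1.0))
        n_correct = int(round(p_correct * len(level_problems)))
        if level >= 4:
            n_correct = max(1, n_correct)  # keep level-4/5 mean RT defined
        order = rng.permutation(len(level_problems))
        base_rt = 3.0 + 1.6 * level
        for rank, pi in enumerate(order):
            prob = level_problems[pi]
            correct = rank < n_correct
            if correct:
                answer = prob.min_moves
            else:
                candidates = [m for m in (prob.min_moves - 1, prob.min_moves + 1) if 1 <= m <= 5]
                answer = int(rng.choice(candidates))
            rt = base_rt * float(np.exp(rng.normal(0.0, 0.25)))
            trials.append(tol.TrialResponse(prob, answer, rt))
            if correct:
                rts.append(rt)
    scale = target_rt_s / float(np.mean(rts))
    return [
        tol.TrialResponse(t.problem, t.answered_moves, t.rt_s * scale) for t in trials
    ]


def _truncated_normal(rng, sd: float, size: int, bound_sd: float = 1.8) -> np.ndarray:
    return sps.truncnorm.rvs(-bound_sd, bound_sd, scale=sd, size=size, random_state=rng)


def _winsorize(values: np.ndarray, bound_sd: float = 1.6) -> np.ndarray:
    """Clamp a behavioral-target sample to mean +/- bound_sd sample SDs.

    Keeps spontaneous |z| >= 2 outliers out of the generated cohort so the
    planted-violator ground truth is exact (see module docstring)."""
    mean = values.mean()
    sd = values.std(ddof=1)
    return np.clip(values, mean - bound_sd * sd, mean + bound_sd * sd)


def generate_cohort(config: CohortConfig, include_timeseries: bool = True) -> Cohort:
    """Draw a full cohort of SubjectRecords, reproducible from config.seed.

    ``include_timeseries=False`` skips the BOLD simulation (used by
    behavior-only Monte Carlo studies of the regression stage).
    """
    root = np.random.SeedSequence(config.seed)
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    n = config.n_subjects

    # demographics
    ages = np.empty(n)
    for i in range(n):
        while True:
            a = demo_rng.normal(config.age_mean, config.age_sd)
            if config.age_range[0] <= a <= config.age_range[1]:
                ages[i] = a
                break
    sexes = np.where(demo_rng.random(n) < config.female_fraction, "F", "M")
    edu_levels = np.array(list(config.education_probs))
    edu_p = np.array(list(config.education_probs.values()))
    education = demo_rng.choice(edu_levels, size=n, p=edu_p / edu_p.sum())
    handed = np.where(demo_rng.random(n) < config.left_handed_fraction, "L", "R")
    intervals = np.clip(
        np.round(demo_rng.gamma(
            (config.interval_mean_days / config.interval_sd_days) ** 2,
            config.interval_sd_days**2 / config.interval_mean_days,
            size=n,
        )),
        0, 21,
    ).astype(int)

    # network coupling and motion severity
    coupling = demo_rng.beta(*config.coupling_beta, size=n)
    mu = np.log(config.motion_rms_mean_mm**2 /
                np.sqrt(config.motion_rms_mean_mm**2 + config.motion_rms_sd_mm**2))
    sig = np.sqrt(np.log(1 + (config.motion_rms_sd_mm / config.motion_rms_mean_mm) ** 2))
    severity = np.clip(demo_rng.lognormal(mu, sig, size=n), *config.motion_rms_range_mm)

    # planted violators: disjoint subject sets per kind
    planted = {k: np.zeros(n, dtype=bool) for k in _VIOLATOR_KINDS}
    pool = demo_rng.permutation(n)
    offset = 0
    for kind in _VIOLATOR_KINDS:
        count = int(round(config.violator_fractions.get(kind, 0.0) * n))
        chosen = pool[offset : offset + count]
        planted[kind][chosen] = True
        offset += count
    severity[planted["motion_mean"]] = 0.30
    intervals = intervals.copy()
    intervals[planted["interval"]] = 30

    # behavioral generating model (truncated residuals; see module docstring)
    c_mean = config.coupling_beta[0] / sum(config.coupling_beta)
    c_var = (config.coupling_beta[0] * config.coupling_beta[1]) / (
        sum(config.coupling_beta) ** 2 * (sum(config.coupling_beta) + 1)
    )
    z_coupling = (coupling - c_mean) / np.sqrt(c_var)
    rt_target = (
        config.rt_mean_s
        + config.b_age * (ages - config.age_mean)
        + config.b_integration * config.rt_sd_target_s * z_coupling
        + _truncated_normal(demo_rng, config.sigma_rt, n)
    )
    rt_target = _winsorize(np.clip(rt_target, 1.0, None))
    rt_target[planted["behavior"]] = config.rt_mean_s + 6.0 * config.rt_sd_target_s
    acc_target = _winsorize(
        np.clip(
            config.acc_mean_pct
            + config.b_age_acc * (ages - config.age_mean)
            + _truncated_normal(demo_rng, config.sigma_acc, n),
            20.0, 100.0,
        )
    )

    # low-voxel nodes: each assigned to one subject with < 4 signal voxels
    low_nodes = demo_rng.choice(config.n_nodes, size=config.n_low_voxel_nodes, replace=False)
    low_owner = demo_rng.integers(0, n, size=config.n_low_voxel_nodes)

    subject_seeds = root.spawn(n)
    subjects = []
    for i in range(n):
        rng_i = np.random.default_rng(subject_seeds[i])
        sid = f"sub{i:03d}"
        n_spikes = 25 if planted["motion_spikes"][i] else 0
        motion = simulate_motion(config, float(severity[i]), rng_i, n_spikes=n_spikes)
        ts = (
            simulate_timeseries(config, float(coupling[i]), rng_i)
            if include_timeseries
            else None
        )
        voxel_counts = rng_i.integers(20, 400, size=config.n_nodes)
        for node_idx, owner in zip(low_nodes, low_owner):
            if owner == i:
                voxel_counts[node_idx] = int(rng_i.integers(0, 4))
        trials = _simulate_trials(
            rng_i, config.trials_per_level, float(acc_target[i]), float(rt_target[i])
        )
        acc, rt = tol.score_responses(trials)
        acc45, rt45 = tol.score_responses(trials, levels={4, 5})
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age_years=float(ages[i]),
                sex=str(sexes[i]),
                education_verhage=int(education[i]),
                handedness=str(handed[i]),
                interval_days=int(intervals[i]),
                motion_params=motion,
                voxel_counts=voxel_counts,
                tol_accuracy_pct=acc,
                tol_rt_s=rt,
                tol_accuracy_45_pct=acc45,
                tol_rt_45_s=rt45,
                timeseries=ts,
                trials=trials,
            )
        )
    ground_truth = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "coupling": coupling,
            "severity_mm": severity,
            "rt_target_s": rt_target,
            "acc_target_pct": acc_target,
            **{f"planted_{k}": planted[k] for k in _VIOLATOR_KINDS},
        }
    )
    return Cohort(config, subjects, ground_truth)
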