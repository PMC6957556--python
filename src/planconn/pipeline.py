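"""End-to-end orchestration: simulate -> QC -> harmonize -> connectivity ->
graph metrics -> bootstrapped regression, with per-stage text outputs and
full provenance (config + derived seeds) so a run is bit-reproducible.

All randomness flows from one root seed: the cohort generator and every
bootstrap get named substreams derived from it, so any stage can be re-run
in isolation with identical results. Outputs carry no timestamps; two runs
from the same config produce identical result trees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from planconn import __version__
from planconn.cohort import Cohort, CohortConfig, generate_cohort
from planconn.connectivity import WaveletSpec, connectivity_matrix
from planconn.graph_metrics import (
    CoherenceMatrix,
    NetworkPartition,
    RSN_NAMES,
    compute_topology_metrics,
    metrics_table,
)
from planconn.qc import (
    QCThresholds,
    apply_motion_exclusion,
    behavioral_exclusion,
    combine_reports,
    exclusion_flow,
    harmonize_nodes,
    mean_relative_rms,
    reports_table,
)
from planconn import stats as pcstats

__all__ = ["PipelineConfig", "run_pipeline", "analysis_table", "run_stats_stage"]

STAGES = ("simulate", "qc", "connect", "metrics", "stats")


@dataclass
class PipelineConfig:
    """One self-contained description of a full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig.emulation_60)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    n_boot: int = 2000
    outcome_set: str = "all_levels"      # all_levels | steps_4_5 | both
    sensitivity: str | None = None       # optional 4th block: "sex" | "education"
    edge_length: str = "inverse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_set not in ("all_levels", "steps_4_5", "both"):
            raise ValueError(f"unknown outcome_set {self.outcome_set!r}")
        if self.sensitivity not in (None, "sex", "education"):
            raise ValueError(f"unknown sensitivity covariate {self.sensitivity!r}")

    def substream(self, name: str) -> int:
        """Named integer substream (< 2**31) derived from the root seed."""
        key = sum(ord(c) * 31**i for i, c in enumerate(name)) % (2**31)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "cohort": self.cohort.to_dict(),
            "wavelet": self.wavelet.to_dict(),
            "qc_thresholds": dataclasses.asdict(self.qc_thresholds),
            "n_boot": self.n_boot,
            "outcome_set": self.outcome_set,
            "sensitivity": self.sensitivity,
            "edge_length": self.edge_length,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        wav = d["wavelet"]
        wav["band_hz"] = tuple(wav["band_hz"])
        return cls(
            cohort=CohortConfig.from_dict(d["cohort"]),
            wavelet=WaveletSpec(**wav),
            qc_thresholds=QCThresholds(**d["qc_thresholds"]),
            n_boot=d["n_boot"],
            outcome_set=d["outcome_set"],
            sensitivity=d.get("sensitivity"),
            edge_length=d.get("edge_length", "inverse"),
            seed=d["seed"],
        )


def _outcomes(config: PipelineConfig) -> list[tuple[str, str]]:
    base = [("rt", "tol_rt_s"), ("acc", "tol_accuracy_pct")]
    post = [("rt45", "tol_rt_45_s"), ("acc45", "tol_accuracy_45_pct")]
    if config.outcome_set == "all_levels":
        return base
    if config.outcome_set == "steps_4_5":
        return post
    return base + post


MEASURE_FAMILIES = {
    "global": ["GE", "Gcc"],
    "subnetwork": [f"eff_{n}" for n in RSN_NAMES] + [f"cc_{n}" for n in RSN_NAMES],
    "between_fc": [
        f"fc_{a}_{b}"
        for i, a in enumerate(RSN_NAMES)
        for b in RSN_NAMES[i + 1 :]
    ],
    "within_dmn": ["fc_within_DMN"],
}


def analysis_table(cohort: Cohort, kept_ids: list[str], metrics: pd.DataFrame) -> pd.DataFrame:
    """Merge demographics, motion summary and topology into one table."""
    demo = cohort.behavior_frame()
    demo = demo[demo.subject_id.isin(kept_ids)].copy()
    motion = {
        s.subject_id: mean_relative_rms(s.motion_params)
        for s in cohort.subjects
        if s.subject_id in set(kept_ids)
    }
    demo["motion_mean_rms"] = demo.subject_id.map(motion)
    demo["sex_code"] = (demo["sex"] == "F").astype(float)
    return demo.merge(metrics, on="subject_id", validate="one_to_one")


def run_stats_stage(
    table: pd.DataFrame, config: PipelineConfig
) -> dict[str, pd.DataFrame | dict]:
    """Regressions for every outcome x measure, with per-family FDR control.

    Blocks: age; the network measure; mean relative RMS motion; optionally
    sex or education. Subnetwork topology (8 tests) and between-network FC
    (6 tests) form separate FDR families per outcome.
    """
    results: dict[str, pd.DataFrame | dict] = {}
    pvalues: dict[str, dict] = {}
    boot_index = 0
    for outcome_name, outcome_col in _outcomes(config):
        frames = {}
        raw_p: dict[str, dict[str, float]] = {fam: {} for fam in MEASURE_FAMILIES}
        for family, measures in MEASURE_FAMILIES.items():
            rows = []
            for measure in measures:
                block_list = [["age"], [measure], ["motion_mean_rms"]]
                if config.sensitivity == "sex":
                    block_list.append(["sex_code"])
                elif config.sensitivity == "education":
                    block_list.append(["education"])
                blocks = pcstats.RegressionBlocks(outcome=outcome_col, blocks=block_list)
                res = pcstats.bootstrap_regression(
                    table,
                    blocks,
                    n_boot=config.n_boot,
                    seed=config.substream(f"boot:{outcome_name}:{measure}:{boot_index}"),
                )
                frame = res.to_frame()
                frame.insert(1, "measure", measure)
                rows.append(frame)
                p_measure = next(
                    c.p_bca for c in res.coefficients if c.name == measure
                )
                raw_p[family][measure] = p_measure
            frames[family] = pd.concat(rows, ignore_index=True)
        adjusted = {}
        for family in ("subnetwork", "between_fc"):
            fdr = pcstats.fdr_bh(raw_p[family], q=0.05)
            adjusted[family] = fdr.adjusted
            frames[family]["P_fdr"] = frames[family].apply(
                lambda r: fdr.adjusted[r["measure"]]
                if r["predictor"] == r["measure"]
                else np.nan,
                axis=1,
            )
        results[outcome_name] = frames
        pvalues[outcome_name] = {"raw": raw_p, "fdr_adjusted": adjusted}
    results["pvalues"] = pvalues
    return results


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, resume: bool = False
) -> dict:
    """Execute every stage and write the documented text outputs.

    Returns a dict with the key in-memory products (qc table, metrics
    table, stats frames) plus the output directory.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    def done(stage: str) -> Path:
        return out / f"stage_{stage}.done"

    # --- simulate -----------------------------------------------------
    cohort_dir = out / "cohort"
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.substream("simulate"))
    if not (resume and done("simulate").exists()):
        cohort = generate_cohort(cohort_cfg)
        cohort.to_dir(cohort_dir)
        done("simulate").write_text("")
    else:
        cohort = Cohort.from_dir(cohort_dir)

    # --- qc -----------------------------------------------------------
    motion = {s.subject_id: s.motion_params for s in cohort.subjects}
    motion_reports = apply_motion_exclusion(motion, config.qc_thresholds)
    behav_reports = behavioral_exclusion(
        cohort.behavior_frame(), thresholds=config.qc_thresholds
    )
    reports = combine_reports(motion_reports, behav_reports)
    reports_table(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    flow = exclusion_flow(reports)
    (out / "exclusion_flow.json").write_text(json.dumps(flow, indent=1, sort_keys=True))
    kept_ids = [r.subject_id for r in reports if r.kept]

    # --- harmonize ----------------------------------------------------
    voxel_counts = {
        s.subject_id: s.voxel_counts for s in cohort.subjects if s.subject_id in set(kept_ids)
    }
    common_nodes = harmonize_nodes(voxel_counts, cohort.node_ids)
    (out / "common_nodes.json").write_text(json.dumps(common_nodes))

    # --- connect ------------------------------------------------------
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    (mat_dir / "wavelet_spec.json").write_text(
        json.dumps(config.wavelet.to_dict(), indent=1, sort_keys=True)
    )
    node_index = [cohort.node_ids.index(n) for n in common_nodes]
    matrices: dict[str, CoherenceMatrix] = {}
    for s in cohort.subjects:
        if s.subject_id not in set(kept_ids):
            continue
        if s.timeseries is None:
            raise RuntimeError(f"subject {s.subject_id} has no time series")
        m = connectivity_matrix(
            s.timeseries[:, node_index],
            cohort.config.tr_s,
            config.wavelet,
            node_ids=common_nodes,
        )
        matrices[s.subject_id] = m
        pd.DataFrame(m.values, index=common_nodes, columns=common_nodes).rename_axis(
            "node_id"
        ).to_csv(mat_dir / f"{s.subject_id}_fc.tsv", sep="\t", float_format="%.10g")

    # --- metrics ------------------------------------------------------
    partition = cohort.partition().restrict(common_nodes)
    per_subject = {
        sid: compute_topology_metrics(m, partition, edge_length=config.edge_length)
        for sid, m in matrices.items()
    }
    metrics = metrics_table(per_subject)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")

    # --- stats --------------------------------------------------------
    table = analysis_table(cohort, kept_ids, metrics)
    table.to_csv(out / "analysis_table.tsv", sep="\t", index=False, float_format="%.10g")
    stats_results = run_stats_stage(table, config)
    for outcome_name in [o for o, _ in _outcomes(config)]:
        frames = stats_results[outcome_name]
        for family, frame in frames.items():
            frame.to_csv(
                out / f"stats_{outcome_name}_{family}.tsv",
                sep="\t", index=False, float_format="%.10g",
            )
    (out / "pvalues.json").write_text(
        json.dumps(stats_results["pvalues"], indent=1, sort_keys=True)
    )

    # demographic/performance correlations (distribution-aware)
    corr_rows = []
    for a, b in [("age", "tol_rt_s"), ("age", "tol_accuracy_pct"),
                 ("age", "motion_mean_rms"), ("motion_mean_rms", "tol_rt_s"),
                 ("motion_mean_rms", "tol_accuracy_pct")]:
        r, p, method = pcstats.correlate(table[a], table[b])
        corr_rows.append({"x": a, "y": b, "r": r, "P": p, "method": method})
    pd.DataFrame(corr_rows).to_csv(
        out / "correlations.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # partial-correlation (plot-ready) table: RT vs GE given age + motion
    ry, rx = pcstats.residualize_pair(
        table["tol_rt_s"], table["GE"], table[["age", "motion_mean_rms"]]
    )
    pd.DataFrame(
        {"subject_id": table.subject_id, "rt_resid": ry, "ge_resid": rx}
    ).to_csv(out / "partial_rt_ge.tsv", sep="\t", index=False, float_format="%.10g")

    log = {
        "planconn_version": __version__,
        "root_seed": config.seed,
        "derived_seeds": {"simulate": cohort_cfg.seed},
        "n_candidates": flow["n_candidates"],
        "n_included": flow["n_included"],
        "common_nodes": len(common_nodes),
        "stages": list(STAGES),
    }
    (out / "log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    for stage in STAGES:
        done(stage).write_text("")
    return {
        "outdir": out,
        "qc": reports_table(reports),
        "flow": flow,
        "common_nodes": common_nodes,
        "metrics": metrics,
        "table": table,
        "stats": stats_results,
    }
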