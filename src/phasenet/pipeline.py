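"""End-to-end orchestration: simulate -> connectivity -> networks -> stats.

Every stage persists its outputs as delimited text under the run
directory, so any intermediate can be inspected, deleted and
regenerated deterministically from the same config and seed.
"""

from __future__ import annotations

import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from phasenet import io as pio
from phasenet.montage import Montage, default_montage
from phasenet.preprocess import (
    DEFAULT_WINDOWS, EpochSet, SubStageWindow, bandpass_beta, segment,
    select_correct,
)
from phasenet.phase_sync import (
    PhaseSegment, analytic_phase, average_by_type, hemispheric_summary,
    psi_matrix,
)
from phasenet.network import compute_metrics, threshold_topk
from phasenet.stats import drop_incomplete_subjects, fdr_bh, posthoc_t, rm_anova
from phasenet.synth import (
    CohortSpec, control_preset, generate_cohort, patient_preset,
)

__all__ = ["RunConfig", "run_pipeline", "report"]

logger = logging.getLogger(__name__)

GLOBAL_MEASURES = ("C", "L", "sigma")
NODAL_MEASURES = ("nodal_clustering", "betweenness")


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    outdir: str = "phasenet_run"
    source: str = "synthetic"        # "synthetic" | path to a cohort directory
    seed: int = 0
    n_per_group: int = 11
    blocks_control: int = 6
    blocks_patient: int = 2
    block_size: int = 96
    band_low: float = 13.0
    band_high: float = 30.0
    windows: tuple[tuple[str, float, float], ...] = tuple(
        (w.name, w.start_ms, w.end_ms) for w in DEFAULT_WINDOWS)
    k: int = 90
    k_sweep: tuple[int, ...] = ()    # e.g. (90, 105, ..., 180)
    ensemble: int = 20
    q: float = 0.05
    with_sigma: bool = True
    with_stats: bool = True
    save_cohort: bool = False

    def __post_init__(self) -> None:
        if self.band_low >= self.band_high:
            raise ValueError("band_low must be below band_high")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.ensemble < 1:
            raise ValueError("ensemble must be >= 1")

    @property
    def window_objs(self) -> tuple[SubStageWindow, ...]:
        return tuple(SubStageWindow(n, s, e) for n, s, e in self.windows)

    @classmethod
    def quick(cls, **kwargs) -> "RunConfig":
        """Small smoke-test configuration (2 subjects/group, 1 block)."""
        defaults = dict(n_per_group=2, blocks_control=1, blocks_patient=1,
                        block_size=16, ensemble=5)
        defaults.update(kwargs)
        return cls(**defaults)

    def to_toml(self, path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, (int, float)):
                lines.append(f"{key} = {value}")
            elif key == "windows":
                inner = ", ".join(f'["{n}", {s}, {e}]' for n, s, e in value)
                lines.append(f"windows = [{inner}]")
            else:
                lines.append(f"{key} = [{', '.join(str(v) for v in value)}]")
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        if "windows" in raw:
            raw["windows"] = tuple((n, float(s), float(e)) for n, s, e in raw["windows"])
        if "k_sweep" in raw:
            raw["k_sweep"] = tuple(int(v) for v in raw["k_sweep"])
        return cls(**raw)


def _matrix_path(outdir: Path, sid: str, stage: str, hand: str, angle: int) -> Path:
    return outdir / "matrices" / f"{sid}_{stage}_{hand}_{angle}.tsv"


def simulate_stage(config: RunConfig) -> list[EpochSet]:
    spec = CohortSpec(
        n_per_group=config.n_per_group,
        blocks_per_subject={"control": config.blocks_control,
                            "patient": config.blocks_patient},
        block_size=config.block_size,
        seed=config.seed,
    )
    cohort = generate_cohort(spec, control_preset(), patient_preset(),
                             windows=config.window_objs)
    if config.save_cohort:
        pio.write_cohort(Path(config.outdir) / "cohort", cohort)
    return cohort


def load_stage(config: RunConfig, montage: Montage) -> list[EpochSet]:
    return pio.read_cohort(config.source, montage)


def connectivity_stage(cohort: list[EpochSet], config: RunConfig) -> pd.DataFrame:
    """Preprocess each subject and write averaged association matrices.

    Returns the tidy hemispheric-PSI table (one row per subject,
    sub-stage, stimulus type and hemisphere class).
    """
    outdir = Path(config.outdir)
    windows = list(config.window_objs)
    include_whole = bool(config.k_sweep)
    psi_rows = []
    for es in cohort:
        t0 = time.perf_counter()
        es = select_correct(es)
        es = bandpass_beta(es, config.band_low, config.band_high)
        # phases over the full trial, sliced per window afterwards
        ph = analytic_phase(es.data)
        stages = list(windows)
        if include_whole:
            stages = stages + [SubStageWindow(
                "Whole", 0, es.n_samples / es.fs * 1000.0)]
        for w in stages:
            sl = w.sample_slice(es.fs)
            per_trial = psi_matrix(PhaseSegment(
                phases=ph.phases[:, :, sl], valid=ph.valid))
            averaged = average_by_type(
                per_trial, es.meta, labels=es.montage.labels,
                context={"subject": es.subject_id, "group": es.group,
                         "stage": w.name})
            for (hand, angle), mat in averaged.items():
                pio.write_matrix(
                    _matrix_path(outdir, es.subject_id, w.name, hand, angle),
                    mat.psi, mat.labels)
                hemi = hemispheric_summary(mat, es.montage)
                for cls, value in (("L", hemi.psi_L), ("R", hemi.psi_R),
                                   ("I", hemi.psi_I)):
                    psi_rows.append((es.subject_id, es.group, w.name, hand,
                                     angle, cls, value))
        logger.info("connectivity %s (%s): %d trials in %.1fs",
                    es.subject_id, es.group, es.n_trials,
                    time.perf_counter() - t0)
    psi_long = pd.DataFrame(psi_rows, columns=[
        "subject", "group", "stage", "hand", "angle", "hemisphere", "value"])
    pio.write_table(outdir / "psi_long.tsv", psi_long)
    return psi_long


def network_stage(config: RunConfig) -> pd.DataFrame:
    """Threshold every stored matrix and compute its graph metrics."""
    outdir = Path(config.outdir)
    files = sorted((outdir / "matrices").glob("*.tsv"))
    if not files:
        raise FileNotFoundError("no association matrices; run connectivity first")
    rows = []
    for idx, path in enumerate(files):
        sid, stage, hand, angle = path.stem.rsplit("_", 3)
        group = "control" if sid.startswith("C") else "patient"
        psi, labels = pio.read_matrix(path)
        ks = (config.k,) if stage != "Whole" else tuple(config.k_sweep) or (config.k,)
        for k in ks:
            net = threshold_topk(psi, k)
            seed = np.random.SeedSequence([config.seed, 7919, idx, k])
            metrics = compute_metrics(net, n_rand=config.ensemble,
                                      seed=np.random.default_rng(seed),
                                      with_sigma=config.with_sigma)
            base = (sid, group, stage, hand, int(angle), k)
            rows.append((*base, "C", "global", metrics.global_clustering))
            rows.append((*base, "L", "global", metrics.char_path_length))
            rows.append((*base, "sigma", "global", metrics.sigma))
            rows.append((*base, "n_unreachable", "global",
                         float(metrics.n_unreachable_pairs)))
            for ci, lab in enumerate(labels):
                rows.append((*base, "nodal_clustering", lab,
                             metrics.nodal_clustering[ci]))
                rows.append((*base, "betweenness", lab,
                             metrics.nodal_betweenness[ci]))
    metrics_long = pd.DataFrame(rows, columns=[
        "subject", "group", "stage", "hand", "angle", "k", "metric",
        "channel", "value"])
    pio.write_table(outdir / "metrics_long.tsv", metrics_long)
    return metrics_long


def _anova_block(table: pd.DataFrame, measure: str, stage: str,
                 within: list[str]) -> pd.DataFrame:
    table = drop_incomplete_subjects(table, within)
    res = rm_anova(table, within=within)
    res.insert(0, "stage", stage)
    res.insert(0, "measure", measure)
    return res


def stats_stage(config: RunConfig, psi_long: pd.DataFrame,
                metrics_long: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Repeated-measures ANOVAs per sub-stage plus the k-sweep post-hocs."""
    outdir = Path(config.outdir)
    stage_names = [w.name for w in config.window_objs]
    anova_parts = []
    for stage in stage_names:
        sub = psi_long[psi_long["stage"] == stage]
        anova_parts.append(_anova_block(
            sub, "psi", stage, ["hemisphere", "angle", "hand"]))
        msub = metrics_long[(metrics_long["stage"] == stage)
                            & (metrics_long["k"] == config.k)]
        for measure in GLOBAL_MEASURES:
            if not config.with_sigma and measure == "sigma":
                continue
            part = msub[msub["metric"] == measure]
            anova_parts.append(_anova_block(
                part, measure, stage, ["angle", "hand"]))
        for measure in NODAL_MEASURES:
            part = msub[msub["metric"] == measure]
            anova_parts.append(_anova_block(
                part, measure, stage, ["angle", "hand", "channel"]))
    anova = pd.concat(anova_parts, ignore_index=True)
    pio.write_table(outdir / "anova.tsv", anova)
    out = {"anova": anova}

    if config.k_sweep:
        whole = metrics_long[(metrics_long["stage"] == "Whole")
                             & (metrics_long["channel"] == "global")]
        ph_parts = []
        for measure in GLOBAL_MEASURES:
            part = whole[whole["metric"] == measure]
            # subject-level mean over the 12 stimulus types
            per_subj = (part.groupby(["subject", "group", "k"], observed=True)
                        ["value"].mean().reset_index())
            tt = posthoc_t(per_subj, by="k")
            tt.insert(0, "measure", measure)
            tt["reject_fdr"] = fdr_bh(tt["p"].to_numpy(), q=config.q).reject
            ph_parts.append(tt)
        posthoc = pd.concat(ph_parts, ignore_index=True)
        pio.write_table(outdir / "posthoc_k.tsv", posthoc)
        out["posthoc_k"] = posthoc
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order; returns the artifact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_toml(outdir / "config.toml")
    t0 = time.perf_counter()
    if config.source == "synthetic":
        cohort = simulate_stage(config)
    else:
        cohort = load_stage(config, default_montage())
    logger.info("stage simulate/load: %d subjects, %.1fs",
                len(cohort), time.perf_counter() - t0)
    psi_long = connectivity_stage(cohort, config)
    del cohort
    metrics_long = network_stage(config)
    if config.with_stats:
        stats_stage(config, psi_long, metrics_long)
    else:
        logger.info("stats stage skipped by config")
    return outdir


def report(outdir) -> str:
    """Human-readable summary of a completed run."""
    outdir = Path(outdir)
    if not (outdir / "psi_long.tsv").exists():
        raise FileNotFoundError(f"{outdir} is not a completed run directory")
    psi = pio.read_table(outdir / "psi_long.tsv")
    lines = [f"phasenet run summary: {outdir}", "=" * 40]
    for stage in psi["stage"].unique():
        sub = psi[psi["stage"] == stage]
        lines.append(f"\n[{stage}] mean PSI by group and hemisphere class")
        pivot = sub.pivot_table(index="group", columns="hemisphere",
                                values="value", observed=True)
        lines.append(pivot.round(4).to_string())
    metrics_path = outdir / "metrics_long.tsv"
    if metrics_path.exists():
        metrics = pio.read_table(metrics_path)
        glob = metrics[metrics["channel"] == "global"]
        lines.append("\nGlobal network metrics (group means per sub-stage):")
        pivot = glob.pivot_table(index=["stage", "metric"], columns="group",
                                 values="value", observed=True)
        lines.append(pivot.round(4).to_string())
    anova_path = outdir / "anova.tsv"
    if anova_path.exists():
        anova = pio.read_table(anova_path)
        lines.append("\nANOVA results:")
        lines.append(anova.round(4).to_string(index=False))
        sig = anova[(anova["measure"] == "psi") & (anova["effect"] == "GROUP")
                    & (anova["p"] < 0.05)]
        for _, row in sig.iterrows():
            lines.append(f"\n* GROUP contrast on PSI significant in "
                         f"{row['stage']} sub-stage "
                         f"(F({row['df1']},{row['df2']}) = {row['F']:.3f}, "
                         f"p = {row['p']:.4f})")
    else:
        lines.append("\nStats stage skipped: no ANOVA table present.")
    return "\n".join(lines)
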