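"""End-to-end four-system analysis: RMSD -> hydrogen bonds -> LIE ddG.

One configuration drives all three stages over the four systems
{AT, GC} x {Complex, DNA}, from either a named synthetic preset or a
dataset directory laid out by :func:`write_dataset`. The report mirrors
the result structure of the underlying study design: pooled RMSD
histograms with a rigidity verdict, per-system hydrogen-bond statistics
with the wild-type/mutant comparison, and the per-run plus pooled
relative binding free energy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hbond import (
    HBondCriteria,
    HBondSummary,
    assign_donors_acceptors,
    detect_hbonds,
    detect_water_bridges,
    hbond_statistics,
)
from .lie import LIEParams, LIEResult, ddg_bind, mean_interaction_energies, pool_runs
from .rmsd import (
    RMSDHistogram,
    RMSDSeries,
    RigiditySummary,
    rigidity_summary,
    rmsd_histogram,
    rmsd_series,
)
from .structio import (
    ENVIRONMENTS,
    VARIANTS,
    EnergySeries,
    Structure,
    Trajectory,
    read_energy_table,
    read_pdb,
    read_trajectory,
    write_energy_table,
    write_pdb,
    write_trajectory,
)
from .synthetic_data import SyntheticDataset, pair_centroid, preset as build_preset

__all__ = [
    "PipelineConfig",
    "Report",
    "run_pipeline",
    "write_dataset",
    "load_dataset",
    "write_report",
]

SYSTEM_KEYS = [(v, e) for v in VARIANTS for e in ENVIRONMENTS]


class IncompleteDesignError(ValueError):
    """The four-system design is missing cells or run counts differ."""


@dataclass
class PipelineConfig:
    """Everything one pipeline invocation needs; defaults follow the
    canonical analysis profile (3.0 A / 20 deg bonds, 10 A bridge
    radius, alpha 0.18 / beta 0.43, 16 replicate runs)."""

    preset: str | None = "paper_default"
    input_dir: str | Path | None = None
    output_dir: str | Path | None = None
    selection: str = "heavy"
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    lie_params: LIEParams = field(default_factory=LIEParams)
    block_count: int = 10
    bin_width: float = 0.1
    bridge_radius: float = 10.0
    seed: int = 42
    n_runs: int = 16
    n_samples: int = 10_000
    n_frames: int = 50

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.input_dir is None):
            raise ValueError("set exactly one of preset / input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "criteria" in raw:
            raw["criteria"] = HBondCriteria(**raw["criteria"])
        if "lie_params" in raw:
            raw["lie_params"] = LIEParams(**raw["lie_params"])
        return cls(**raw)

    def to_provenance(self) -> dict:
        out = asdict(self)
        out["input_dir"] = str(self.input_dir) if self.input_dir else None
        out["output_dir"] = str(self.output_dir) if self.output_dir else None
        return out


@dataclass
class Report:
    """Combined machine-readable pipeline result."""

    histograms: dict[tuple[str, str], RMSDHistogram]
    rmsd_runs: dict[tuple[str, str], list[RMSDSeries]]
    rigidity: dict[str, RigiditySummary]  # per environment
    hbond_summaries: dict[str, list[HBondSummary]]  # per variant (complexes)
    hbond_mean_counts: dict[str, float]
    bridge_mean_counts: dict[str, float]
    lie: LIEResult
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "rigidity": {
                env: asdict(summary) for env, summary in self.rigidity.items()
            },
            "hbond_mean_counts": self.hbond_mean_counts,
            "bridge_mean_counts": self.bridge_mean_counts,
            "hbonds": {
                variant: [asdict(s) for s in summaries]
                for variant, summaries in self.hbond_summaries.items()
            },
            "lie": {
                "dg_bind_at": self.lie.dg_bind_at,
                "dg_bind_gc": self.lie.dg_bind_gc,
                "ddg": self.lie.ddg,
                "ddg_el_component": self.lie.ddg_el_component,
                "ddg_vdw_component": self.lie.ddg_vdw_component,
                "se_ddg": self.lie.se_ddg,
                "per_run": self.lie.per_run.to_dict(orient="records"),
            },
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# Dataset directory layout
# ---------------------------------------------------------------------------


def _tag(variant: str, environment: str) -> str:
    return f"{variant}_{environment}"


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write a SyntheticDataset as the on-disk layout the stages consume."""
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    (outdir / "traj").mkdir(exist_ok=True)
    (outdir / "energies").mkdir(exist_ok=True)
    for key, structure in dataset.structures.items():
        write_pdb(structure, outdir / "structures" / f"{_tag(*key)}.pdb")
    for key, runs in dataset.trajectories.items():
        for i, traj in enumerate(runs, start=1):
            write_trajectory(traj, outdir / "traj" / f"{_tag(*key)}_run{i:02d}.pdb")
    for key, runs in dataset.energies.items():
        for i, series in enumerate(runs, start=1):
            write_energy_table(
                series, outdir / "energies" / f"{_tag(*key)}_run{i:02d}.csv"
            )
    meta = {
        "name": dataset.name,
        "sequence": dataset.sequence,
        "site": dataset.site,
        "n_runs": max((len(r) for r in dataset.trajectories.values()), default=0),
    }
    (outdir / "meta.yaml").write_text(yaml.safe_dump(meta))


def load_dataset(indir: str | Path) -> SyntheticDataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    meta = yaml.safe_load((indir / "meta.yaml").read_text())
    structures: dict[tuple[str, str], Structure] = {}
    trajectories: dict[tuple[str, str], list[Trajectory]] = {}
    energies: dict[tuple[str, str], list[EnergySeries]] = {}
    for key in SYSTEM_KEYS:
        spath = indir / "structures" / f"{_tag(*key)}.pdb"
        if spath.exists():
            structures[key] = read_pdb(spath)
        tpaths = sorted((indir / "traj").glob(f"{_tag(*key)}_run*.pdb"))
        if tpaths and key in structures:
            trajectories[key] = [read_trajectory(p, structures[key]) for p in tpaths]
        epaths = sorted((indir / "energies").glob(f"{_tag(*key)}_run*.csv"))
        if epaths:
            energies[key] = [read_energy_table(p) for p in epaths]
    return SyntheticDataset(
        structures=structures,
        trajectories=trajectories,
        energies=energies,
        energy_preset=None,  # unknown for on-disk data
        site=int(meta["site"]),
        sequence=str(meta["sequence"]),
        name=str(meta.get("name", indir.name)),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _validate(dataset: SyntheticDataset) -> int:
    missing = [key for key in SYSTEM_KEYS if key not in dataset.energies]
    missing += [key for key in SYSTEM_KEYS if key not in dataset.trajectories]
    if missing:
        raise IncompleteDesignError(
            f"four-system design incomplete; missing cells: {sorted(set(missing))}"
        )
    run_counts = {len(dataset.energies[k]) for k in SYSTEM_KEYS} | {
        len(dataset.trajectories[k]) for k in SYSTEM_KEYS
    }
    if len(run_counts) != 1:
        raise IncompleteDesignError(
            f"mismatched run counts across systems: {sorted(run_counts)}"
        )
    return run_counts.pop()


def _rmsd_stage(dataset: SyntheticDataset, config: PipelineConfig):
    runs: dict[tuple[str, str], list[RMSDSeries]] = {}
    for key in SYSTEM_KEYS:
        series = []
        for i, traj in enumerate(dataset.trajectories[key], start=1):
            # reference: the run's own first frame, a self-contained measure
            ref = traj.topology.with_coordinates(traj.frames[0])
            series.append(
                rmsd_series(
                    traj,
                    ref,
                    selection=config.selection,
                    fit=True,
                    run_id=f"{_tag(*key)}_run{i:02d}",
                )
            )
        runs[key] = series
    histograms = {
        key: rmsd_histogram(series, bin_width=config.bin_width)
        for key, series in runs.items()
    }
    rigidity = {
        env: rigidity_summary(runs[("AT", env)], runs[("GC", env)])
        for env in ENVIRONMENTS
    }
    return runs, histograms, rigidity


def _hbond_stage(dataset: SyntheticDataset, config: PipelineConfig):
    summaries: dict[str, list[HBondSummary]] = {}
    mean_counts: dict[str, float] = {}
    bridge_means: dict[str, float] = {}
    for variant in VARIANTS:
        key = (variant, "Complex")
        topology = dataset.trajectories[key][0].topology
        table = assign_donors_acceptors(topology)
        all_counts: list[np.ndarray] = []
        all_bridges: list[int] = []
        pooled_events = []
        pooled_frames = 0
        dt_ps = dataset.trajectories[key][0].dt_ps
        for traj in dataset.trajectories[key]:
            events_per_frame = []
            for f in range(traj.n_frames):
                coords = traj.frames[f]
                events = detect_hbonds(
                    coords, table, criteria=config.criteria, frame=pooled_frames + f
                )
                events_per_frame.append(events)
                center = pair_centroid(
                    topology.with_coordinates(coords), dataset.site
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bridges = detect_water_bridges(
                        coords,
                        topology,
                        center,
                        radius=config.bridge_radius,
                        criteria=config.criteria,
                        table=table,
                        frame=f,
                    )
                all_bridges.append(len(bridges))
            _, counts = hbond_statistics(
                events_per_frame, traj.n_frames, traj.dt_ps, topology
            )
            all_counts.append(counts)
            pooled_events.extend(events_per_frame)
            pooled_frames += traj.n_frames
        pooled_summaries, _ = hbond_statistics(
            pooled_events, pooled_frames, dt_ps, topology
        )
        summaries[variant] = pooled_summaries
        mean_counts[variant] = float(np.concatenate(all_counts).mean())
        bridge_means[variant] = float(np.mean(all_bridges))
    return summaries, mean_counts, bridge_means


def _lie_stage(dataset: SyntheticDataset, config: PipelineConfig) -> LIEResult:
    n_runs = len(dataset.energies[("AT", "Complex")])
    per_run = []
    for run in range(n_runs):
        cells = {
            key: mean_interaction_energies(
                dataset.energies[key][run], block_count=config.block_count
            )
            for key in SYSTEM_KEYS
        }
        per_run.append(ddg_bind(cells, params=config.lie_params, run_label=run + 1))
    if len(per_run) == 1:
        return per_run[0]
    return pool_runs(per_run)


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute the full four-system analysis and optionally write outputs."""
    if config.preset is not None:
        dataset = build_preset(
            config.preset,
            n_runs=config.n_runs,
            n_samples=config.n_samples,
            n_frames=config.n_frames,
            seed=config.seed,
        )
    else:
        dataset = load_dataset(config.input_dir)
    _validate(dataset)

    rmsd_runs, histograms, rigidity = _rmsd_stage(dataset, config)
    hbond_summaries, mean_counts, bridge_means = _hbond_stage(dataset, config)
    lie_result = _lie_stage(dataset, config)

    provenance = {
        "package_version": __version__,
        "config": config.to_provenance(),
        "dataset": dataset.name,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    report = Report(
        histograms=histograms,
        rmsd_runs=rmsd_runs,
        rigidity=rigidity,
        hbond_summaries=hbond_summaries,
        hbond_mean_counts=mean_counts,
        bridge_mean_counts=bridge_means,
        lie=lie_result,
        provenance=provenance,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: Report, outdir: str | Path) -> None:
    """Write per-stage CSVs and the combined JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, hist in report.histograms.items():
        rows = pd.DataFrame(
            {
                "bin_start": hist.bin_edges[:-1],
                "bin_end": hist.bin_edges[1:],
                "count": hist.counts,
            }
        )
        rows.to_csv(outdir / f"rmsd_hist_{_tag(*key)}.csv", index=False)
    for variant, summaries in report.hbond_summaries.items():
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(
            outdir / f"hbonds_{variant}_Complex.csv", index=False
        )
    ddg_table = report.lie.per_run.copy()
    pooled = pd.DataFrame(
        [
            {
                "run": "pooled",
                "ddg": report.lie.ddg,
                "el_component": report.lie.ddg_el_component,
                "vdw_component": report.lie.ddg_vdw_component,
                "se_ddg": report.lie.se_ddg,
            }
        ]
    )
    pd.concat([ddg_table, pooled], ignore_index=True).to_csv(
        outdir / "ddg.csv", index=False
    )
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
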