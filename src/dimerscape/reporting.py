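"""End-to-end pipeline runs and report bundles.

:func:`run_pipeline` drives the full analysis — inverse-distance features,
PCA, free-energy surface, basins, per-frame classification, probability
tables, hydrogen-bond maps, representative structures and the transition
graph — and writes every artifact into one output directory. Each table
carries the SHA-256 hash of the effective configuration in a leading
comment line, so identical configs provably produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationConfig, hb_probability_maps, trajectory_metrics
from .core import Trajectory, TrajectoryMetadata
from .geometry import feature_matrix
from .landscape import (BasinDecomposition, FESGrid, assign_basins,
                        fes_from_projection, fit_pca, project,
                        representative_structure, thermal_energy)
from .pdbio import read_multimodel_pdb, write_multimodel_pdb
from .states import (ORIENTATION_CLASSES, REGION_LABELS, classify_regions,
                     orientation_classes, transition_graph,
                     window_probability_table)

#: number formatting for all report tables — fixed so identical configs
#: reproduce byte-identical files
_FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    input_path: str | None = None        # multi-model PDB; None = synthetic
    output_dir: str = "report"
    ph_mode: str | None = None           # "physiological" | "acidic" | None
    temperature: float = 300.0           # K
    kT: float | None = None              # kJ/mol; None → k_B · temperature
    nbins: int = 60
    prominence: float = 0.5              # kJ/mol, minima merging threshold
    hb_distance_cutoff: float = 0.35     # nm
    hb_angle_cutoff: float = 30.0        # degrees
    hb_method: str = "geometric"
    contact_cutoff: float = 0.54         # nm
    window: int | None = None            # frames; None → 100 ns of frames
    cluster_cutoff: float = 0.2          # nm, representative clustering
    max_cluster_frames: int = 150        # per-basin clustering sample cap
    seed: int = 0                        # synthetic generation
    n_frames: int = 2000                 # synthetic generation
    noise_sigma: float = 0.02            # nm, synthetic generation

    def __post_init__(self) -> None:
        for name in ("temperature", "nbins", "prominence", "hb_distance_cutoff",
                     "hb_angle_cutoff", "contact_cutoff", "cluster_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window is not None and self.window < 1:
            raise ValueError("window must be at least 1 frame")

    @property
    def effective_kT(self) -> float:
        return self.kT if self.kT is not None else thermal_energy(self.temperature)

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            hb_distance_cutoff=self.hb_distance_cutoff,
            hb_angle_cutoff=self.hb_angle_cutoff,
            hb_method=self.hb_method,
            contact_cutoff=self.contact_cutoff,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form of this configuration.

        The output directory is excluded: it changes where the report goes,
        not what is computed, and two runs of the same analysis must carry
        the same hash.
        """
        d = self.to_dict()
        d.pop("output_dir")
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML or JSON config file; keyword overrides win."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ReportBundle:
    """Paths and key results of a completed pipeline run."""

    config: RunConfig
    output_dir: Path
    files: dict[str, Path]
    n_frames: int
    n_basins: int
    basin_table: pd.DataFrame
    region_table: pd.DataFrame
    orientation_table: pd.DataFrame


def _write_table(df: pd.DataFrame, path: Path, config_hash: str,
                 sep: str = "\t") -> None:
    df = df.copy()
    for col in df.select_dtypes(include=float):
        df[col] = df[col] + 0.0          # canonicalize -0.0
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FORMAT,
                  lineterminator="\n")


def _write_matrix(matrix: np.ndarray, path: Path, config_hash: str,
                  row_labels, col_labels) -> None:
    df = pd.DataFrame(np.asarray(matrix) + 0.0, index=row_labels,
                      columns=col_labels)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, float_format=_FLOAT_FORMAT, lineterminator="\n")


def _default_window(config: RunConfig, traj: Trajectory) -> int:
    """Window of frames spanning 100 ns at the trajectory's frame spacing."""
    if config.window is not None:
        return config.window
    spacing = traj.metadata.frame_spacing_ps or 2.0
    return max(1, int(round(100_000.0 / spacing)))


def _basin_frames(decomp: BasinDecomposition, scores: np.ndarray) -> dict[str, np.ndarray]:
    labels = decomp.frame_labels(scores[:, 0], scores[:, 1])
    return {b.label: np.flatnonzero(labels == b.label) for b in decomp.basins}


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig,
                 traj: Trajectory | None = None) -> ReportBundle:
    """Run the complete analysis and write the report bundle.

    ``traj`` may be passed directly (e.g. fresh from the generator);
    otherwise ``config.input_path`` is read. With neither, a synthetic
    five-state reference trajectory is generated from ``config.seed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    files: dict[str, Path] = {}
    ann = config.annotation_config()
    kT = config.effective_kT

    truth = None
    with _stage("input"):
        if traj is None and config.input_path is not None:
            meta = TrajectoryMetadata(ph_mode=config.ph_mode,
                                      temperature=config.temperature)
            traj = read_multimodel_pdb(config.input_path, metadata=meta)
        elif traj is None:
            from .synth import five_state_spec, markov_trajectory
            spec = five_state_spec(n_frames=config.n_frames, seed=config.seed,
                                   noise_sigma=config.noise_sigma)
            traj, truth = markov_trajectory(spec)

    with _stage("features"):
        x, (n1, n2) = feature_matrix(traj)

    with _stage("pca"):
        model = fit_pca(x)
        scores = project(model, x, k=2)

    with _stage("fes"):
        grid = fes_from_projection(scores[:, 0], scores[:, 1],
                                   nbins=config.nbins, kT=kT)
        files["fes_grid"] = out / "fes_grid.csv"
        _write_matrix(grid.F, files["fes_grid"], chash,
                      row_labels=[f"x{i}" for i in range(grid.F.shape[0])],
                      col_labels=[f"y{j}" for j in range(grid.F.shape[1])])
        files["fes_sidecar"] = out / "fes_grid.json"
        files["fes_sidecar"].write_text(json.dumps({
            "config_hash": chash,
            "x_edges": grid.x_edges.tolist(),
            "y_edges": grid.y_edges.tolist(),
            "kT_kJ_per_mol": grid.kT,
            "convention": grid.convention,
            "n_frames": int(grid.counts.sum()),
            "pc_variance_fractions": model.variance_fractions[:2].tolist(),
        }, indent=2, sort_keys=True) + "\n")

    with _stage("basins"):
        decomp = assign_basins(grid, prominence=config.prominence)
        members = _basin_frames(decomp, scores)
        basin_table = pd.DataFrame([
            {"basin": b.label,
             "minimum_F_kJ_per_mol": b.minimum_F,
             "relative_depth_kJ_per_mol": b.relative_depth,
             "population": len(members[b.label]) / len(traj)}
            for b in decomp.basins
        ])
        files["basins"] = out / "basins.tsv"
        _write_table(basin_table, files["basins"], chash)

    with _stage("classification"):
        metrics = trajectory_metrics(traj, ann)
        regions = classify_regions(metrics)
        orients = orientation_classes(metrics)
        frame_table = metrics.copy()
        frame_table.insert(0, "frame", np.arange(len(traj)))
        frame_table["region"] = regions.values
        frame_table["orientation"] = orients.values
        frame_table["basin"] = decomp.frame_labels(scores[:, 0], scores[:, 1])
        if truth is not None:
            frame_table["true_state"] = truth["label"].values
            frame_table["true_region"] = truth["region"].values
        files["frame_metrics"] = out / "frame_metrics.tsv"
        _write_table(frame_table, files["frame_metrics"], chash)

    with _stage("tables"):
        window = _default_window(config, traj)
        region_table = window_probability_table(
            list(regions), window, label_order=list(REGION_LABELS))
        files["region_probabilities"] = out / "region_probabilities.tsv"
        _write_table(region_table, files["region_probabilities"], chash)
        orientation_table = window_probability_table(
            list(orients), window, label_order=list(ORIENTATION_CLASSES))
        files["orientation_probabilities"] = out / "orientation_probabilities.tsv"
        _write_table(orientation_table, files["orientation_probabilities"], chash)

    with _stage("hb_maps"):
        intra, inter = hb_probability_maps(traj, config=ann)
        res_a = [f"{r.name}{r.index}" for r in traj.topology.chains[0].residues]
        res_b = [f"{r.name}{r.index}" for r in traj.topology.chains[1].residues]
        n = intra.matrix.shape[0]
        res_n = res_a if len(res_a) == n else [f"res{i + 1}" for i in range(n)]
        files["hb_map_intra"] = out / "hb_map_intra.csv"
        _write_matrix(intra.matrix, files["hb_map_intra"], chash, res_n, res_n)
        files["hb_map_inter"] = out / "hb_map_inter.csv"
        _write_matrix(inter.matrix, files["hb_map_inter"], chash, res_a, res_b)

    with _stage("representatives"):
        for basin, idx in members.items():
            if len(idx) == 0:
                continue
            if len(idx) > config.max_cluster_frames:
                # deterministic even subsample keeps clustering O(cap²)
                take = np.linspace(0, len(idx) - 1, config.max_cluster_frames)
                idx = idx[np.unique(take.astype(int))]
            rep = representative_structure(traj, idx, cutoff=config.cluster_cutoff)
            path = out / f"representative_{basin}.pdb"
            write_multimodel_pdb(traj.subset([rep]), path)
            files[f"representative_{basin}"] = path

    with _stage("graphs"):
        graph = transition_graph(list(regions))
        files["transitions_dot"] = out / "transitions.dot"
        files["transitions_dot"].write_text(graph.to_dot())
        files["transitions_edges"] = out / "transition_edges.csv"
        _write_table(graph.edge_list(), files["transitions_edges"], chash, sep=",")

    with _stage("log"):
        files["run_log"] = out / "run.json"
        from . import __version__ as pkg_version
        files["run_log"].write_text(json.dumps({
            "package_version": pkg_version,
            "config": config.to_dict(),
            "config_hash": chash,
            "effective_kT_kJ_per_mol": kT,
            "window_frames": window,
            "n_frames": len(traj),
            "feature_dimension": int(n1 * n2),
            "n_basins": len(decomp.basins),
        }, indent=2, sort_keys=True) + "\n")

    return ReportBundle(
        config=config, output_dir=out, files=files, n_frames=len(traj),
        n_basins=len(decomp.basins), basin_table=basin_table,
        region_table=region_table, orientation_table=orientation_table,
    )
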