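"""Configuration files, seed streams, run manifests, and result export.

All randomness in a run flows from one master seed through named child
streams (a counter-based spawn scheme, so adding a stream never perturbs
existing ones).  A :class:`RunManifest` records the resolved configuration,
the seeds, the package version and checksums of every output file;
re-running from a manifest reproduces the deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from notchsim.model import PerturbationSpec, PERTURBATION_PRESETS
from notchsim.simulate import RunConfig

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "child_seed",
    "combine_perturbations",
    "write_outputs",
]

# named child streams: the registry index doubles as the spawn key, so the
# mapping is append-only
_STREAMS = {"geometry": 0, "init_noise": 1}

_CONFIG_KEYS = {
    "preset", "genotype", "treatment", "overrides", "t_end", "dt", "window",
    "n_cells", "n_iterations", "seed", "uniform_neighbors", "initial_noise",
    "dll1_delay", "ptf1a_timescale", "nicd_variant",
}


def child_seed(master_seed: int, stream: str) -> int:
    """Deterministic per-stream seed derived from the master seed."""
    try:
        key = _STREAMS[stream]
    except KeyError:
        raise KeyError(f"unknown seed stream {stream!r}; known: {sorted(_STREAMS)}") from None
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def combine_perturbations(a: PerturbationSpec, b: PerturbationSpec) -> PerturbationSpec:
    """Stack two perturbations (e.g. a genotype and a treatment).

    Overrides merge with the second spec winning on conflicts; term masks
    AND together; delays and timescale factors must not both be non-default.
    """
    if a.dll1_delay > 0 and b.dll1_delay > 0:
        raise ValueError("both perturbations set dll1_delay")
    if a.ptf1a_timescale != 1.0 and b.ptf1a_timescale != 1.0:
        raise ValueError("both perturbations set ptf1a_timescale")
    return PerturbationSpec(
        overrides={**a.overrides, **b.overrides},
        cis_D=a.cis_D and b.cis_D,
        cis_J=a.cis_J and b.cis_J,
        trans_D=a.trans_D and b.trans_D,
        trans_J=a.trans_J and b.trans_J,
        dll1_delay=max(a.dll1_delay, b.dll1_delay),
        ptf1a_timescale=a.ptf1a_timescale * b.ptf1a_timescale,
        nicd_variant=a.nicd_variant or b.nicd_variant,
        name=f"{a.name}+{b.name}",
    )


def _resolve_perturbation(raw: dict) -> PerturbationSpec:
    pert = PerturbationSpec.from_preset(raw.get("genotype", "wild_type"))
    if raw.get("treatment") not in (None, "none"):
        pert = combine_perturbations(pert, PerturbationSpec.from_preset(raw["treatment"]))
    extra = raw.get("overrides") or {}
    if not isinstance(extra, dict):
        raise TypeError("field 'overrides' must be a mapping")
    updates = {}
    for f in ("dll1_delay", "ptf1a_timescale", "nicd_variant"):
        if f in raw:
            updates[f] = raw[f]
    if extra or updates:
        from dataclasses import replace

        pert = replace(pert, overrides={**pert.overrides, **extra}, **updates)
    return pert


def config_from_dict(raw: dict) -> RunConfig:
    """Build a fully resolved RunConfig from a plain dict (schema-checked)."""
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    pert = _resolve_perturbation(raw)
    master = int(raw.get("seed", 0))
    kwargs = dict(
        preset=raw.get("preset", "table1_3d"),
        perturbation=pert,
        geometry_seed=child_seed(master, "geometry"),
        noise_seed=child_seed(master, "init_noise"),
    )
    for f in ("t_end", "dt", "n_cells", "n_iterations", "uniform_neighbors", "initial_noise"):
        if f in raw:
            kwargs[f] = raw[f]
    if "window" in raw:
        w = raw["window"]
        if not (isinstance(w, (list, tuple)) and len(w) == 2):
            raise TypeError("field 'window' must be a [start, end] pair")
        kwargs["window"] = (float(w[0]), float(w[1]))
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid configuration: {err}") from None


def load_config(path) -> RunConfig:
    """Read a YAML run configuration and resolve presets and defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ValueError(f"malformed config {path}: {err}") from None
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    return config_from_dict(raw)


def save_config(config: RunConfig, path, master_seed: int | None = None) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    pert = config.perturbation
    raw = {
        "preset": config.preset,
        "genotype": pert.name if pert.name in PERTURBATION_PRESETS else "wild_type",
        "t_end": config.t_end,
        "dt": config.dt,
        "window": list(config.window),
        "n_cells": config.n_cells,
        "n_iterations": config.n_iterations,
        "initial_noise": config.initial_noise,
    }
    if pert.name not in PERTURBATION_PRESETS and pert.overrides:
        raw["overrides"] = dict(pert.overrides)
    if pert.dll1_delay:
        raw["dll1_delay"] = pert.dll1_delay
    if pert.ptf1a_timescale != 1.0:
        raw["ptf1a_timescale"] = pert.ptf1a_timescale
    if pert.nicd_variant:
        raw["nicd_variant"] = True
    if config.uniform_neighbors is not None:
        raw["uniform_neighbors"] = config.uniform_neighbors
    if master_seed is not None:
        raw["seed"] = master_seed
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class RunManifest:
    """Record of one run: config, seeds, version, outputs with checksums."""

    config: dict
    master_seed: int | None
    child_seeds: dict
    version: str
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    trajset,
    fate_table,
    outdir,
    master_seed: int | None = None,
    trajectory_format: str | None = None,
    trajectory_stride: int = 10,
) -> RunManifest:
    """Export one run: graph CSVs, fate table CSV, summary JSON, manifest.

    ``trajectory_format`` may be ``'h5'`` (compact container) or ``'csv'``
    (long format, down-sampled by ``trajectory_stride``); the default skips
    the bulky per-timepoint data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from notchsim import __version__

    graph = trajset.graph
    written = []

    if graph is not None:
        cls = (
            graph.cell_class
            if graph.cell_class is not None
            else np.array(["unlabeled"] * graph.n_cells)
        )
        nodes = pd.DataFrame(
            {
                "cell_id": np.arange(graph.n_cells),
                "x": graph.positions[:, 0],
                "y": graph.positions[:, 1],
                "z": graph.positions[:, 2],
                "cell_class": cls,
                "n_neighbors": graph.neighbor_counts,
            }
        )
        nodes.to_csv(outdir / "nodes.csv", index=False)
        pd.DataFrame(graph.edges(), columns=["i", "j"]).to_csv(
            outdir / "edges.csv", index=False
        )
        written += ["nodes.csv", "edges.csv"]

    fate_table.per_cell.to_csv(outdir / "fate_table.csv", index=False)
    written.append("fate_table.csv")

    summary = {
        "proportions": fate_table.proportions,
        "counts": fate_table.counts,
        "n_cells": fate_table.n_cells,
        "window": list(fate_table.window),
        "thresholds": asdict(fate_table.thresholds),
        "perturbation": trajset.config.perturbation.name,
        "preset": trajset.config.preset,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    written.append("summary.json")

    if trajectory_format == "h5":
        import h5py

        with h5py.File(outdir / "trajectory.h5", "w") as f:
            f.create_dataset("t", data=trajset.t)
            f.create_dataset("y", data=trajset.trajectory.y, compression="gzip")
            f.create_dataset("cell_ids", data=trajset.cell_ids)
        written.append("trajectory.h5")
    elif trajectory_format == "csv":
        from notchsim.model import VARIABLES

        t = trajset.t[::trajectory_stride]
        frames = []
        for vi, var in enumerate(VARIABLES):
            mat = trajset.trajectory.y[::trajectory_stride, :, vi]
            df = pd.DataFrame(mat, columns=[str(c) for c in trajset.cell_ids])
            df.insert(0, "time", t)
            long = df.melt(id_vars="time", var_name="cell_id", value_name="value")
            long.insert(2, "variable", var)
            frames.append(long)
        pd.concat(frames).to_csv(outdir / "trajectory.csv", index=False)
        written.append("trajectory.csv")
    elif trajectory_format is not None:
        raise ValueError("trajectory_format must be 'h5', 'csv', or None")

    manifest = RunManifest(
        config={
            "preset": trajset.config.preset,
            "perturbation": trajset.config.perturbation.name,
            "overrides": dict(trajset.config.perturbation.overrides),
            "t_end": trajset.config.t_end,
            "dt": trajset.config.dt,
            "window": list(trajset.config.window),
            "n_cells": trajset.config.n_cells,
            "uniform_neighbors": trajset.config.uniform_neighbors,
            "initial_noise": trajset.config.initial_noise,
        },
        master_seed=master_seed,
        child_seeds={
            "geometry": trajset.config.geometry_seed,
            "init_noise": trajset.config.noise_seed,
        },
        version=__version__,
        outputs={name: _sha256(outdir / name) for name in written},
    )
    manifest.save(outdir / "manifest.json")
    return manifest
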