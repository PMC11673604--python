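"""Readers, writers and seeded fixture generation.

Two on-disk formats carry a multichannel recording:

* delimited text — one row per channel, whitespace- or comma-separated,
  with a JSON sidecar (``<file>.json``) holding ``fs``, channel names
  and provenance (seed, config hash);
* a columnar binary container (NumPy ``.npz``) holding the data matrix
  plus the same metadata, byte-identical across write/read round trips.

Coefficient trajectories and sPDC grids use the binary container only.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from .datatypes import CoefficientTrajectory, TimeSeries

from .mvar import TrajectorySpec, benchmark_trajectory, simulate_mvar
from .noise import NoiseSource


class FormatError(ValueError):
    """Unparseable or inconsistent on-disk data."""


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# time-series matrices
# ---------------------------------------------------------------------------


def write_matrix(
    ts: TimeSeries,
    path: str | Path,
    fmt: str = "delimited",
    metadata: dict[str, Any] | None = None,
) -> Path:
    """Write a TimeSeries as delimited text (+ JSON sidecar) or as the
    binary container, chosen by ``fmt`` in {'delimited', 'binary'}."""
    path = Path(path)
    meta = {"fs": ts.fs, "channel_names": ts.channel_names}
    meta.update(metadata or {})
    if fmt == "delimited":
        np.savetxt(path, ts.data, delimiter="\t")
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    elif fmt == "binary":
        np.savez(path, data=ts.data, meta=json.dumps(meta))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_matrix(path: str | Path, fmt: str | None = None) -> TimeSeries:
    """Read a channels-by-samples matrix; format inferred from the
    suffix unless given.  The sidecar (or embedded) metadata must
    supply the sampling rate."""
    path = Path(path)
    if fmt is None:
        fmt = "binary" if path.suffix == ".npz" else "delimited"
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    if fmt == "binary":
        with np.load(path, allow_pickle=False) as z:
            if "data" not in z or "meta" not in z:
                raise FormatError(f"{path}: not a time-series container")
            data = z["data"]
            meta = json.loads(str(z["meta"]))
    else:
        text = path.read_text().strip()
        if not text:
            raise FormatError(f"{path}: empty file")
        rows = []
        width = None
        for ln, line in enumerate(text.splitlines(), start=1):
            parts = line.replace(",", " ").split()
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise FormatError(
                    f"{path}: ragged row at line {ln} ({len(parts)} vs {width} columns)"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell at line {ln}: {exc}") from None
        data = np.array(rows)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"{path}: missing metadata sidecar {sidecar.name} (need fs)")
        meta = json.loads(sidecar.read_text())

    if "fs" not in meta:
        raise FormatError(f"{path}: metadata lacks sampling rate 'fs'")
    return TimeSeries(data, fs=float(meta["fs"]), channel_names=meta.get("channel_names"))


# ---------------------------------------------------------------------------
# coefficient trajectories
# ---------------------------------------------------------------------------


def write_trajectory(
    traj: CoefficientTrajectory, path: str | Path, metadata: dict[str, Any] | None = None
) -> Path:
    path = Path(path)
    meta = dict(metadata or {})
    np.savez(
        path,
        coeffs=traj.coeffs,
        diverged=traj.diverged,
        meta=json.dumps(meta),
    )
    return path


def read_trajectory(path: str | Path) -> CoefficientTrajectory:
    with np.load(Path(path), allow_pickle=False) as z:
        if "coeffs" not in z:
            raise FormatError(f"{path}: not a trajectory container")
        return CoefficientTrajectory(z["coeffs"], diverged=z["diverged"])


# ---------------------------------------------------------------------------
# config stanzas
# ---------------------------------------------------------------------------


def trajectory_spec_from_dict(d: dict[str, Any]) -> TrajectorySpec:
    """Build a TrajectorySpec from a YAML/JSON config stanza."""
    return TrajectorySpec(**d)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML (superset of JSON) config file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("gaussian_bench", "alpha_bench", "pink_bench", "static_ar2")


def make_fixture(name: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small seeded simulation for test use.

    ``*_bench`` fixtures are 10 s renditions of the 3-channel benchmark
    under the named noise; ``static_ar2`` is a single-channel AR(2)
    with coefficients (1.58, -0.96) and unit Gaussian noise.  Each
    fixture comprises the series (delimited), the ground-truth
    trajectory (binary) where applicable, and a JSON config.
    """
    from .bench import make_noise_source

    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = 1000.0
    paths: dict[str, Path] = {}

    if name == "static_ar2":
        T = 10_000
        coeffs = np.zeros((T, 2, 1, 1))
        coeffs[:, 0, 0, 0] = 1.58
        coeffs[:, 1, 0, 0] = -0.96
        truth = CoefficientTrajectory(coeffs)
        src = NoiseSource(kind="gaussian", variance=1.0)
    else:
        T = 10_000
        truth = benchmark_trajectory(n_samples=T, fs=fs)
        src = make_noise_source(
            {"gaussian_bench": "gaussian", "alpha_bench": "alpha_stable", "pink_bench": "pink"}[name]
        )

    ts = simulate_mvar(truth, src, fs=fs, seed=seed)
    cfg = {
        "name": name,
        "seed": seed,
        "fs": fs,
        "n_samples": T,
        "order": truth.order,
        "noise": src.kind,
    }
    cfg["config_hash"] = config_hash(cfg)
    paths["series"] = write_matrix(
        ts, out_dir / f"{name}.tsv", fmt="delimited", metadata={"seed": seed, "config_hash": cfg["config_hash"]}
    )
    paths["truth"] = write_trajectory(truth, out_dir / f"{name}_truth.npz", metadata=cfg)
    config_path = out_dir / f"{name}_config.json"
    config_path.write_text(json.dumps(cfg, indent=2))
    paths["config"] = config_path
    return paths
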