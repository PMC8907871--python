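"""Data ingestion, standardization and model serialization.

Time series load from delimited text (TSV/CSV, one T x N matrix per
subject) or HDF5 arrays; every channel is z-scored at load time.  Fitted
models round-trip through a single versioned HDF5 container with groups
/basis, /weights and /config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .model import StateBasis, TimeSeriesData, standardize
from .inference import FittedModel, LossReport, MageNetworks, TrainingConfig

__all__ = ["Dataset", "load_dataset", "load_timeseries", "save_model", "load_model"]

FORMAT_VERSION = "1"


@dataclass
class Dataset:
    """A cohort of subjects sharing a channel count."""

    subjects: list
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("empty dataset")
        N = self.subjects[0].n_channels
        if any(s.n_channels != N for s in self.subjects):
            raise ValueError("subjects disagree in channel count")

    @property
    def n_channels(self) -> int:
        return self.subjects[0].n_channels

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def _read_matrix(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            key = "data" if "data" in f else next(iter(f.keys()))
            return np.asarray(f[key], dtype=np.float64)
    text = path.read_text()
    delim = "," if "," in text.splitlines()[0] else None
    return np.loadtxt(path, delimiter=delim, dtype=np.float64, ndmin=2)


def load_timeseries(path, dt: float = 1.0) -> TimeSeriesData:
    """One subject's T x N matrix, z-scored per channel."""
    path = Path(path)
    vals = _read_matrix(path)
    bad = np.argwhere(~np.isfinite(vals))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"{path}: NaN/Inf at row {r}, column {c} "
                         f"({len(bad)} bad cell(s) total)")
    return TimeSeriesData(standardize(vals), dt=dt, subject_id=path.stem)


def load_dataset(paths, dt: float = 1.0) -> Dataset:
    """Load and standardize a cohort; deterministic order (path sort)."""
    paths = sorted(Path(p) for p in paths)
    if not paths:
        raise ValueError("no input paths")
    subjects = [load_timeseries(p, dt=dt) for p in paths]
    N = subjects[0].n_channels
    for p, s in zip(paths, subjects):
        if s.n_channels != N:
            raise ValueError(
                f"{p}: has {s.n_channels} channels, expected {N} (from {paths[0]})"
            )
    return Dataset(
        subjects=subjects,
        dt=dt,
        meta={"source_paths": [str(p) for p in paths], "standardized": True},
    )


def save_model(model: FittedModel, path) -> None:
    """Serialize basis, network weights, config and loss traces to HDF5."""
    cfg = model.config
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("basis")
        g.create_dataset("mean_maps", data=model.basis.mean_maps)
        g.create_dataset("corr_states", data=model.basis.corr_states)
        g.create_dataset("std_maps", data=model.basis.std_maps)
        w = f.create_group("weights")
        for name, arr in model.networks.state_dict().items():
            w.create_dataset(name, data=arr)
        f.create_group("config").attrs["json"] = json.dumps(vars(cfg))
        lr = f.create_group("loss")
        rep = model.loss_report
        for key in ("train_total", "train_recon", "train_reg",
                    "val_total", "val_recon", "val_reg"):
            lr.create_dataset(key, data=np.asarray(getattr(rep, key)))
        lr.attrs["best_epoch"] = rep.best_epoch
        f.attrs["n_channels"] = model.basis.n_channels


def load_model(path) -> FittedModel:
    """Rebuild a fitted model; weights reproduce bit-exactly."""
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise ValueError(f"cannot read model file {path}: {e}") from e
    with f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"model format version {version!r} != supported {FORMAT_VERSION!r}"
            )
        cfg = TrainingConfig(**json.loads(f["config"].attrs["json"]))
        basis = StateBasis(
            mean_maps=np.asarray(f["basis/mean_maps"]),
            corr_states=np.asarray(f["basis/corr_states"]),
            std_maps=np.asarray(f["basis/std_maps"]),
        )
        n_channels = int(f.attrs["n_channels"])
        nets = MageNetworks(cfg, n_channels, np.random.default_rng(cfg.seed))
        nets.load_state_dict({k: np.asarray(v) for k, v in f["weights"].items()})
        report = LossReport(
            train_total=list(f["loss/train_total"][...]),
            train_recon=list(f["loss/train_recon"][...]),
            train_reg=list(f["loss/train_reg"][...]),
            val_total=list(f["loss/val_total"][...]),
            val_recon=list(f["loss/val_recon"][...]),
            val_reg=list(f["loss/val_reg"][...]),
            best_epoch=int(f["loss"].attrs["best_epoch"]),
        )
    return FittedModel(basis=basis, networks=nets, config=cfg, loss_report=report)
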