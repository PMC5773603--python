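"""Shared file I/O: YAML/JSON configs, HDF5 field/ensemble containers,
CSV histograms and traces, float TIFF maps, and provenance records.

All HDF5 datasets carry a ``units`` attribute; readers refuse containers
without one.  CSV is RFC-4180 with '.' decimal; metadata travels in
``#``-prefixed header lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import yaml

from . import __version__
from .flim import DecayHistogram, IRF
from .fluctuation import TrialEnsemble
from .rd import (
    BufferSpec,
    ChannelCluster,
    ConcentrationFields,
    ReportedCalciumMap,
    SimulationConfig,
    build_channel_cluster,
)

__all__ = [
    "load_simulation_config",
    "simulation_config_to_dict",
    "write_fields_h5",
    "read_fields_h5",
    "write_map_tiff",
    "write_profile_csv",
    "write_histogram_csv",
    "read_histogram_csv",
    "read_irf_csv",
    "write_ensemble_h5",
    "read_ensemble_h5",
    "provenance",
]


class FormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------- YAML

def _cluster_from_dict(d: dict) -> ChannelCluster:
    if "positions_nm" in d:
        return ChannelCluster(
            np.asarray(d["positions_nm"], dtype=float),
            d.get("i_single_pA", 0.137),
            d.get("p_open", 0.4),
            d.get("length_nm", 430.0),
            d.get("width_nm", 67.0),
        )
    return build_channel_cluster(
        n=d.get("n", 120),
        length_nm=d.get("length_nm", 430.0),
        width_nm=d.get("width_nm", 67.0),
        min_nn_nm=d.get("min_nn_nm", 10.0),
        seed=d.get("seed", 0),
        i_single_pA=d.get("i_single_pA", 0.137),
        p_open=d.get("p_open", 0.4),
    )


def load_simulation_config(path: str | Path,
                           **overrides: Any) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML/JSON file.

    The file mirrors the simulation parameter table field for field:
    buffer blocks (name, D, K_D, k_on, total, fluorescent), a channel
    cluster block, grid geometry and timing.  Keyword overrides replace
    top-level entries (e.g. ``h_nm=10`` for a coarser test grid).
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    data.update(overrides)
    buffers = tuple(
        BufferSpec(
            name=b["name"], D=b["D"], K_D=b["K_D"], k_on=b["k_on"],
            total=b["total"], fluorescent=b.get("fluorescent", False),
        )
        for b in data.get("buffers", [])
    )
    cluster = data.get("cluster")
    if isinstance(cluster, dict):
        cluster = _cluster_from_dict(cluster)
    kwargs = dict(
        extent_nm=tuple(data.get("extent_nm", (800.0, 800.0, 300.0))),
        h_nm=float(data.get("h_nm", 5.0)),
        dt_ns=data.get("dt_ns"),
        duration_ms=float(data.get("duration_ms", 1.0)),
        ca_rest_uM=float(data.get("ca_rest_uM", 0.05)),
        quarter=bool(data.get("quarter", False)),
    )
    if buffers:
        kwargs["buffers"] = buffers
    if cluster is not None:
        kwargs["cluster"] = cluster
    if "bc" in data:
        kwargs["bc"] = tuple(data["bc"])
    return SimulationConfig(**kwargs)


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    d = {
        "extent_nm": list(config.extent_nm),
        "h_nm": config.h_nm,
        "dt_ns": config.dt_ns,
        "duration_ms": config.duration_ms,
        "ca_rest_uM": config.ca_rest_uM,
        "quarter": config.quarter,
        "bc": list(config.bc),
        "buffers": [
            {"name": b.name, "D": b.D, "K_D": b.K_D, "k_on": b.k_on,
             "total": b.total, "fluorescent": b.fluorescent}
            for b in config.buffers
        ],
    }
    if config.cluster is not None:
        c = config.cluster
        d["cluster"] = {
            "positions_nm": c.positions_nm.tolist(),
            "i_single_pA": c.i_single_pA,
            "p_open": c.p_open,
            "length_nm": c.length_nm,
            "width_nm": c.width_nm,
        }
    return d


# --------------------------------------------------------------------- HDF5

def write_fields_h5(path: str | Path, fields: ConcentrationFields) -> None:
    """Write per-species 3D concentration datasets with grid metadata."""
    with h5py.File(path, "w") as f:
        f.attrs["h_nm"] = fields.h_nm
        f.attrs["origin_nm"] = fields.origin_nm
        f.attrs["t_ms"] = fields.t_ms
        f.attrs["quarter"] = fields.quarter
        f.attrs["azcal_version"] = __version__
        d = f.create_dataset("ca", data=fields.ca)
        d.attrs["units"] = "uM"
        g = f.create_group("bound")
        for name, arr in fields.bound.items():
            d = g.create_dataset(name, data=arr)
            d.attrs["units"] = "uM"
        bspec = f.create_group("buffers")
        for b in fields.buffers:
            gb = bspec.create_group(b.name)
            for k in ("D", "K_D", "k_on", "total"):
                gb.attrs[k] = getattr(b, k)
            gb.attrs["fluorescent"] = b.fluorescent


def read_fields_h5(path: str | Path) -> ConcentrationFields:
    with h5py.File(path, "r") as f:
        if "units" not in f["ca"].attrs:
            raise FormatError(f"{path}: dataset 'ca' lacks a units attribute")
        buffers = tuple(
            BufferSpec(
                name=name,
                D=float(g.attrs["D"]),
                K_D=float(g.attrs["K_D"]),
                k_on=float(g.attrs["k_on"]),
                total=float(g.attrs["total"]),
                fluorescent=bool(g.attrs["fluorescent"]),
            )
            for name, g in f["buffers"].items()
        )
        return ConcentrationFields(
            ca=f["ca"][()],
            bound={name: ds[()] for name, ds in f["bound"].items()},
            buffers=buffers,
            h_nm=float(f.attrs["h_nm"]),
            origin_nm=tuple(f.attrs["origin_nm"]),
            t_ms=float(f.attrs["t_ms"]),
            quarter=bool(f.attrs["quarter"]),
        )


def write_ensemble_h5(path: str | Path, ens: TrialEnsemble) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trials", data=ens.trials)
        d.attrs["units"] = "counts" if ens.kind == "fluorescence" else "pA"
        f.attrs["rate_hz"] = ens.rate_hz
        f.attrs["kind"] = ens.kind
        f.attrs["baseline"] = ens.baseline


def read_ensemble_h5(path: str | Path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        if "units" not in f["trials"].attrs:
            raise FormatError(f"{path}: trials lack a units attribute")
        return TrialEnsemble(
            trials=f["trials"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            kind=str(f.attrs["kind"]),
            baseline=tuple(int(x) for x in f.attrs["baseline"]),
        )


# --------------------------------------------------------------------- TIFF

def write_map_tiff(path: str | Path, cmap: ReportedCalciumMap | np.ndarray,
                   z_nm: float = 0.0) -> None:
    """Single-plane 32-bit float TIFF (values in µM for reported maps)."""
    import tifffile

    arr = cmap.plane(z_nm) if isinstance(cmap, ReportedCalciumMap) else cmap
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def write_profile_csv(path: str | Path, cmap: ReportedCalciumMap,
                      axis: int = 0, z_nm: float = 0.0) -> None:
    """CSV line profile through the maximum of a reported-[Ca2+] plane:
    columns position_nm, ca_uM."""
    plane = cmap.plane(z_nm)
    i, j = np.unravel_index(int(np.argmax(plane)), plane.shape)
    profile = plane[:, j] if axis == 0 else plane[i, :]
    with open(path, "w") as f:
        f.write(f"# h_nm={cmap.h_nm}\n# K_D_uM={cmap.K_D}\n")
        f.write("position_nm,ca_uM\n")
        for k, v in enumerate(profile):
            f.write(f"{k * cmap.h_nm:.6g},{v:.6g}\n")


# ---------------------------------------------------------------------- CSV

def write_histogram_csv(path: str | Path, hist: DecayHistogram) -> None:
    with open(path, "w") as f:
        f.write(f"# bin_ps={hist.bin_ps}\n# mode={hist.mode}\n")
        f.write("bin_index,counts\n")
        for i, c in enumerate(hist.counts):
            f.write(f"{i},{c:.0f}\n")


def _read_csv_body(path: Path) -> tuple[dict, list[list[str]]]:
    meta: dict = {}
    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        rows.append([c.strip() for c in line.split(",")])
    return meta, rows


def read_histogram_csv(path: str | Path) -> DecayHistogram:
    path = Path(path)
    meta, rows = _read_csv_body(path)
    if not rows:
        raise FormatError(f"{path}: empty histogram file")
    header, body = rows[0], rows[1:]
    if header[:2] != ["bin_index", "counts"]:
        raise FormatError(f"{path}: line 1: expected 'bin_index,counts' header")
    counts = np.zeros(len(body))
    for i, row in enumerate(body):
        try:
            counts[int(row[0])] = float(row[1])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: line {i + 2}: bad row {row}") from exc
    return DecayHistogram(
        counts,
        bin_ps=float(meta.get("bin_ps", 25.0)),
        mode=meta.get("mode", "confocal"),
    )


def read_irf_csv(path: str | Path, bin_ps: float = 25.0) -> IRF:
    """IRF from a one- or two-column CSV (curve, or bin_index,curve)."""
    path = Path(path)
    meta, rows = _read_csv_body(path)
    vals = []
    for i, row in enumerate(rows):
        try:
            vals.append(float(row[-1]))
        except ValueError:
            if i == 0:
                continue  # header line
            raise FormatError(f"{path}: line {i + 1}: bad value {row!r}")
    if not vals:
        raise FormatError(f"{path}: empty IRF file")
    return IRF(np.asarray(vals), float(meta.get("bin_ps", bin_ps)))


# --------------------------------------------------------------- provenance

def provenance(config: dict | None = None, seed: int | None = None,
               inputs: list[str | Path] | None = None) -> dict:
    """Reproducibility record for an output bundle: package version, the
    configuration (and its hash), the seed, and input-file hashes."""
    rec: dict = {"azcal_version": __version__}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        rec["config"] = config
        rec["config_sha256"] = hashlib.sha256(blob).hexdigest()
    if seed is not None:
        rec["seed"] = int(seed)
    if inputs:
        rec["inputs"] = {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in inputs
        }
    return rec
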