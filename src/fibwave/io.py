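"""Readers/writers and pipeline orchestration.

Artifact formats: domains and field movies as ``.npz`` array archives;
domains and voltage frames additionally as legacy-ASCII VTK structured
points (loadable in ParaView); filaments as VTK polydata; metrics as CSV
with a versioned column schema; run configuration as YAML. The pipeline
(:func:`run_pipeline`) chains geometry -> protocol -> simulation -> phase/
filament analysis -> metrics with per-stage caching keyed on a hash of the
configuration, and records everything in a :class:`RunRecord`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Domain, StructureConfig, conductivity_field, make_biventricular_shell, make_sheet, make_slab
from .solver import FieldMovie, SimulationConfig, run as solver_run

log = logging.getLogger("fibwave.io")

CSV_SCHEMA_VERSION = 1

__all__ = ["save_domain", "load_domain", "save_movie", "load_movie",
           "write_vtk_structured", "write_vtk_polylines", "save_metrics_csv",
           "load_metrics_csv", "load_config", "dump_config", "config_hash",
           "RunRecord", "run_pipeline"]


# ---------------------------------------------------------------- arrays

def _write_npz(path, **arrays) -> None:
    """Deterministic .npz writer: fixed zip timestamps so identical data
    produce byte-identical archives (plain np.savez stamps wall-clock
    times into the zip entries)."""
    import io as _io
    import zipfile

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asanyarray(arr))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def save_domain(path, domain: Domain) -> None:
    _write_npz(
        path, spacing=domain.spacing, mask=domain.mask,
        dimensionality=domain.dimensionality, descriptor=domain.descriptor,
        fibers=domain.fibers if domain.fibers is not None else np.zeros(0),
        surfaces=domain.surfaces if domain.surfaces is not None else np.zeros(0),
        seed=-1 if domain.seed is None else domain.seed)


def load_domain(path) -> Domain:
    d = np.load(path, allow_pickle=False)
    fibers = d["fibers"] if d["fibers"].size else None
    surfaces = d["surfaces"] if d["surfaces"].size else None
    seed = int(d["seed"])
    return Domain(spacing=float(d["spacing"]), mask=d["mask"],
                  dimensionality=int(d["dimensionality"]),
                  descriptor=str(d["descriptor"]), fibers=fibers,
                  surfaces=surfaces, seed=None if seed < 0 else seed)


def save_movie(path, movie: FieldMovie) -> None:
    """Movies with non-finite frames are rejected (frame index reported)."""
    bad = np.nonzero(~np.isfinite(movie.frames).reshape(len(movie.frames), -1).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"refusing to write movie with non-finite frame {bad[0]}")
    _write_npz(path, times=movie.times, frames=movie.frames,
               spacing=movie.spacing,
               provenance=json.dumps(movie.provenance, default=float))


def load_movie(path) -> FieldMovie:
    d = np.load(path, allow_pickle=False)
    return FieldMovie(times=d["times"], frames=d["frames"],
                      spacing=float(d["spacing"]),
                      provenance=json.loads(str(d["provenance"])))


# ---------------------------------------------------------------- VTK text

def _vtk_header(f, title: str, kind: str) -> None:
    f.write("# vtk DataFile Version 3.0\n")
    f.write(title[:255] + "\n")
    f.write("ASCII\n")
    f.write(f"DATASET {kind}\n")


def write_vtk_structured(path, domain: Domain,
                         fields: Optional[dict] = None) -> None:
    """Legacy-ASCII VTK STRUCTURED_POINTS with the mask, surface labels,
    fiber components and any extra scalar ``fields`` as point data."""
    shape = domain.shape if domain.dimensionality == 3 else domain.shape + (1,)
    nx, ny, nz = shape
    data = {"mask": domain.mask.astype(np.uint8)}
    if domain.surfaces is not None:
        data["surface"] = domain.surfaces
    if domain.fibers is not None:
        for c, name in enumerate(("fiber_x", "fiber_y", "fiber_z")):
            data[name] = domain.fibers[..., c]
    data.update(fields or {})
    with open(path, "w") as f:
        _vtk_header(f, f"fibwave domain {domain.descriptor}", "STRUCTURED_POINTS")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {domain.spacing} {domain.spacing} {domain.spacing}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in data.items():
            arr3 = arr.reshape(shape)
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK structured points run x fastest
            flat = np.transpose(arr3, (2, 1, 0)).ravel()
            np.savetxt(f, flat.reshape(-1, 1), fmt="%.6g")


def write_vtk_polylines(path, polylines, title: str = "fibwave filaments") -> None:
    """Legacy-ASCII VTK POLYDATA of polylines (e.g. filament curves);
    ``polylines`` is an iterable of (n_i, 3) coordinate arrays in cm."""
    polylines = [np.atleast_2d(np.asarray(p, dtype=float)) for p in polylines]
    n_pts = sum(len(p) for p in polylines)
    with open(path, "w") as f:
        _vtk_header(f, title, "POLYDATA")
        f.write(f"POINTS {n_pts} float\n")
        for p in polylines:
            np.savetxt(f, p, fmt="%.6g")
        size = sum(len(p) + 1 for p in polylines)
        f.write(f"LINES {len(polylines)} {size}\n")
        offset = 0
        for p in polylines:
            idx = " ".join(str(offset + i) for i in range(len(p)))
            f.write(f"{len(p)} {idx}\n")
            offset += len(p)


# ---------------------------------------------------------------- CSV

def save_metrics_csv(path, df: pd.DataFrame, kind: str) -> None:
    """CSV with a versioned schema comment line."""
    with open(path, "w") as f:
        f.write(f"# fibwave-metrics kind={kind} schema={CSV_SCHEMA_VERSION} "
                f"version={__version__}\n")
        df.to_csv(f, index=False)


def load_metrics_csv(path, expect_kind: Optional[str] = None) -> pd.DataFrame:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("# fibwave-metrics"):
            raise ValueError(f"{path}: not a fibwave metrics CSV")
        meta = dict(tok.split("=") for tok in header.split()[2:])
        if int(meta["schema"]) != CSV_SCHEMA_VERSION:
            raise ValueError(f"{path}: schema {meta['schema']} unsupported")
        if expect_kind is not None and meta["kind"] != expect_kind:
            raise ValueError(f"{path}: kind {meta['kind']} != {expect_kind}")
        return pd.read_csv(f)


# ---------------------------------------------------------------- config

REQUIRED_FIELDS = ("name", "geometry", "cell", "conductivity", "simulation")


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    missing = [k for k in REQUIRED_FIELDS if k not in cfg]
    if missing:
        raise ValueError(f"config missing required field(s): {', '.join(missing)}")
    return cfg


def dump_config(path, cfg: dict) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config dict (field order independent)."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()).hexdigest()[:16]


# ---------------------------------------------------------------- pipeline

@dataclass
class RunRecord:
    label: str
    config_digest: str
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    wall_times: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _build_domain(gcfg: dict) -> Domain:
    kind = gcfg.get("kind", "sheet")
    if kind == "sheet":
        return make_sheet(side=gcfg.get("side", 3.5),
                          spacing=gcfg.get("spacing", 0.0125),
                          fiber_angle=gcfg.get("fiber_angle"))
    if kind == "slab":
        return make_slab(dims=tuple(gcfg.get("dims", (2.0, 2.0, 0.4))),
                         spacing=gcfg.get("spacing", 0.025),
                         fiber_rotation=gcfg.get("fiber_rotation", 0.0))
    if kind == "shell":
        sc = None
        if gcfg.get("structure", False):
            sc = StructureConfig(seed=int(gcfg.get("seed", 0)))
        return make_biventricular_shell(config=sc,
                                        spacing=gcfg.get("spacing", 0.05),
                                        with_fibers=gcfg.get("fibers", False))
    raise ValueError(f"unknown geometry kind {kind!r}")


def run_pipeline(cfg: dict, out_dir, force: bool = False) -> RunRecord:
    """Execute geometry -> protocol -> simulation -> analysis -> metrics.

    Each stage's artifact is cached in ``out_dir`` under the config hash;
    reruns with an identical config are cache hits and bitwise identical.
    Stage errors are recorded in the RunRecord and downstream stages are
    skipped.
    """
    from .cells import CellParameters, diastolic_threshold
    from .metrics import mean_cycle_length
    from .phase import compute_phase, track_tips
    from .protocols import find_s2_time, s1s2_protocol

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(cfg)
    rec = RunRecord(label=cfg["name"], config_digest=digest,
                    seeds={"geometry": cfg["geometry"].get("seed")})
    base = out / f"{cfg['name']}-{digest}"

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
            rec.wall_times[name] = round(time.time() - t0, 3)
            log.info("stage %-10s done in %.1fs", name, time.time() - t0)
            return result
        except Exception as exc:
            rec.errors[name] = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed: %s", name, exc)
            return None

    dom_path = base.with_suffix(".domain.npz")

    def geom():
        if dom_path.exists() and not force:
            return load_domain(dom_path)
        d = _build_domain(cfg["geometry"])
        save_domain(dom_path, d)
        return d

    domain = stage("geometry", geom)
    if domain is None:
        rec.save(base.with_suffix(".record.json"))
        return rec
    rec.outputs["domain"] = str(dom_path)

    params = CellParameters.from_label(cfg["cell"])
    cond = conductivity_field(domain, **cfg["conductivity"])
    scfg = SimulationConfig(cell=params, **cfg["simulation"])

    mov_path = base.with_suffix(".movie.npz")

    def simulate():
        if mov_path.exists() and not force:
            return load_movie(mov_path)
        thr = diastolic_threshold(params)
        pcfg = cfg.get("protocol", {})
        t2 = pcfg.get("t2")
        if t2 is None:
            t2 = find_s2_time(domain, params, cond, dt=scfg.dt)
        proto = s1s2_protocol(domain, t2, amplitude=pcfg.get("s2_amplitude",
                                                            1.3 * thr),
                              params=params)
        proto.events[0].amplitude = pcfg.get("s1_amplitude", 2.0 * thr)
        total = SimulationConfig(
            dt=scfg.dt, duration=t2 + scfg.duration,
            snapshot_interval=scfg.snapshot_interval, cell=params)
        mv = solver_run(domain, total, protocol=proto, conductivity=cond)
        mv.provenance["t2"] = t2
        mv.provenance["protocol"] = proto.to_dict()
        save_movie(mov_path, mv)
        return mv

    movie = stage("simulate", simulate)
    if movie is None:
        rec.save(base.with_suffix(".record.json"))
        return rec
    rec.outputs["movie"] = str(mov_path)

    def metrics():
        t2 = movie.provenance.get("t2", 0.0)
        rows = []
        if domain.dimensionality == 2:
            pm = compute_phase(movie)
            tracks = track_tips(pm, min_duration=100.0)
            cl = mean_cycle_length(movie, window=(t2 + 1000, t2 + 2000),
                                   label=cfg["name"])
            rows.append({"label": cfg["name"], "mean_cl_ms": cl.mean,
                         "n_intervals": len(cl.intervals),
                         "n_tracks": len(tracks)})
        else:
            from .filaments import count_series
            cs = count_series(movie, domain, label=cfg["name"])
            rows.append({"label": cfg["name"],
                         "mean_filaments": cs.windowed_mean(t2 + 500,
                                                            movie.times[-1]),
                         "final_count": int(cs.counts[-1])})
        df = pd.DataFrame(rows)
        p = base.with_suffix(".metrics.csv")
        save_metrics_csv(p, df, kind="summary")
        return p

    mpath = stage("metrics", metrics)
    if mpath is not None:
        rec.outputs["metrics"] = str(mpath)
    rec.save(base.with_suffix(".record.json"))
    return rec
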