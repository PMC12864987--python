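"""Morphomovie archives, digitised-pattern persistence and VTK export.

An archive is a directory: a JSON manifest (model hash, trajectory hash,
config including the seed, snapshot index with times) plus numpy ``.npy``
arrays (little-endian, 64-bit floats) for per-frame meshes and per-snapshot
fields — streamable, inspectable, diff-able. Snapshot round trips are
bit-exact. Frames can be exported as legacy-ASCII VTK unstructured grids, one
file per snapshot with zero-padded numbering and all reactant fields attached
as cell data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .analysis import DigitisedPattern
from .domain import (
    BoundaryCurve,
    BoundaryMesh,
    DomainTrajectory,
    StageFrame,
    TriMesh,
)
from .engine import FieldState, Morphomovie, SimulationConfig, Snapshot
from .modelspec import ModelSpec, dumps_model, loads_model

__all__ = [
    "ArchiveError",
    "write_morphomovie",
    "read_morphomovie",
    "export_frames",
    "write_fit_trace",
    "write_pattern",
    "read_pattern",
]


class ArchiveError(ValueError):
    pass


def _save(path: Path, arr: np.ndarray) -> str:
    arr = np.ascontiguousarray(arr)
    if arr.dtype == np.float64:
        arr = arr.astype("<f8")
    elif arr.dtype == np.int64:
        arr = arr.astype("<i8")
    np.save(path, arr)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest(hashes) -> str:
    h = hashlib.sha256()
    for x in hashes:
        h.update(x.encode())
    return h.hexdigest()


def write_morphomovie(movie: Morphomovie, path) -> None:
    """Persist a simulation result as an archive directory."""
    root = Path(path)
    (root / "frames").mkdir(parents=True, exist_ok=True)
    (root / "snapshots").mkdir(exist_ok=True)

    model_text = dumps_model(movie.model)
    (root / "model.yaml").write_text(model_text)
    model_hash = hashlib.sha256(model_text.encode()).hexdigest()

    traj = movie.trajectory
    frame_hashes = []
    frames_meta = []
    for k, f in enumerate(traj.frames):
        d = root / "frames" / f"{k:04d}"
        d.mkdir(exist_ok=True)
        hs = [
            _save(d / "vertices.npy", f.mesh.vertices),
            _save(d / "triangles.npy", f.mesh.triangles),
            _save(d / "end_positions.npy", f.end_positions),
            _save(d / "ectoderm_elements.npy", f.ectoderm.elements),
            _save(d / "ectoderm_owners.npy", f.ectoderm.owner_triangle),
        ]
        frame_hashes.extend(hs)
        frames_meta.append(
            {
                "index": f.index,
                "n_boundary": int(f.mesh.n_boundary),
                "stage_label": f.boundary.stage_label,
                "flank_edge": list(f.boundary.flank_edge) if f.boundary.flank_edge else None,
                "ectoderm_closed": bool(f.ectoderm.closed),
            }
        )

    snap_meta = []
    for i, s in enumerate(movie.snapshots):
        d = root / "snapshots" / f"{i:06d}"
        d.mkdir(exist_ok=True)
        _save(d / "positions.npy", s.positions)
        for name, u in s.state.mesenchyme.items():
            _save(d / f"mes_{name}.npy", u)
        for name, u in s.state.ectoderm.items():
            _save(d / f"ect_{name}.npy", u)
        snap_meta.append({"time": s.time, "frame_index": s.frame_index})

    manifest = {
        "format": "limbrd-morphomovie-1",
        "model_hash": model_hash,
        "trajectory_hash": _digest(frame_hashes),
        "frame_duration": traj.frame_duration,
        "config": asdict(movie.config),
        "frames": frames_meta,
        "snapshots": snap_meta,
        "mesenchyme_species": sorted(movie.snapshots[0].state.mesenchyme)
        if movie.snapshots else [],
        "ectoderm_species": sorted(movie.snapshots[0].state.ectoderm)
        if movie.snapshots else [],
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_morphomovie(path, verify: bool = True) -> Morphomovie:
    """Load an archive; raises :class:`ArchiveError` for missing components,
    warns (via the manifest check) on hash mismatch."""
    import warnings

    root = Path(path)
    mf = root / "manifest.json"
    if not mf.exists():
        raise ArchiveError(f"archive {root} is missing its manifest")
    manifest = json.loads(mf.read_text())
    if not (root / "model.yaml").exists():
        raise ArchiveError(f"archive {root} is missing model.yaml")
    model_text = (root / "model.yaml").read_text()
    model = loads_model(model_text)
    if verify:
        h = hashlib.sha256(model_text.encode()).hexdigest()
        if h != manifest.get("model_hash"):
            warnings.warn("model hash mismatch: archive may have been edited")

    frames = []
    frame_hashes = []
    for meta in manifest["frames"]:
        d = root / "frames" / f"{meta['index']:04d}"
        try:
            arrays = {
                name: np.load(d / f"{name}.npy")
                for name in ("vertices", "triangles", "end_positions",
                             "ectoderm_elements", "ectoderm_owners")
            }
        except FileNotFoundError as e:
            raise ArchiveError(f"archive frame {meta['index']} missing {e.filename}")
        if verify:
            for name in ("vertices", "triangles", "end_positions",
                         "ectoderm_elements", "ectoderm_owners"):
                frame_hashes.append(
                    hashlib.sha256((d / f"{name}.npy").read_bytes()).hexdigest()
                )
        nb = meta["n_boundary"]
        fe = meta.get("flank_edge")
        boundary = BoundaryCurve(
            arrays["vertices"][:nb],
            stage_label=meta.get("stage_label"),
            flank_edge=tuple(fe) if fe else None,
        )
        mesh = TriMesh(
            vertices=arrays["vertices"], triangles=arrays["triangles"], n_boundary=nb
        )
        ecto = BoundaryMesh(
            elements=arrays["ectoderm_elements"],
            owner_triangle=arrays["ectoderm_owners"],
            closed=meta["ectoderm_closed"],
        )
        frames.append(
            StageFrame(
                index=meta["index"], boundary=boundary, mesh=mesh, ectoderm=ecto,
                end_positions=arrays["end_positions"],
            )
        )
    if verify and _digest(frame_hashes) != manifest.get("trajectory_hash"):
        warnings.warn("trajectory hash mismatch: archive may have been edited")

    trajectory = DomainTrajectory(frames=frames,
                                  frame_duration=manifest["frame_duration"])
    cfg = manifest["config"]
    config = SimulationConfig(**cfg)

    snapshots = []
    for i, meta in enumerate(manifest["snapshots"]):
        d = root / "snapshots" / f"{i:06d}"
        if not d.exists():
            raise ArchiveError(
                f"manifest lists {len(manifest['snapshots'])} snapshots but "
                f"snapshot {i} is missing"
            )
        state = FieldState(time=meta["time"])
        for name in manifest["mesenchyme_species"]:
            state.mesenchyme[name] = np.load(d / f"mes_{name}.npy")
        for name in manifest["ectoderm_species"]:
            state.ectoderm[name] = np.load(d / f"ect_{name}.npy")
        snapshots.append(
            Snapshot(
                time=meta["time"], frame_index=meta["frame_index"],
                positions=np.load(d / "positions.npy"), state=state,
            )
        )
    extra = sorted(p.name for p in (root / "snapshots").iterdir()) if (
        root / "snapshots").exists() else []
    if len(extra) != len(snapshots):
        raise ArchiveError(
            f"manifest snapshot count {len(snapshots)} does not match stored "
            f"count {len(extra)}"
        )
    return Morphomovie(model=model, trajectory=trajectory, config=config,
                       snapshots=snapshots)


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------


def _write_vtk(path: Path, positions: np.ndarray, triangles: np.ndarray,
               cell_data: dict[str, np.ndarray], title: str) -> None:
    n, m = len(positions), len(triangles)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for p in positions:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} 0\n")
        fh.write(f"CELLS {m} {4 * m}\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["5"] * m) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            for name, u in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.17g}" for v in u) + "\n")


def export_frames(movie: Morphomovie, path, format: str = "vtk") -> list[Path]:
    """Write one unstructured-grid file per snapshot (mesenchyme cell data).

    File names are zero-padded so they sort lexicographically in time order.
    """
    if format != "vtk":
        raise ValueError(f"unsupported export format {format!r} (only 'vtk')")
    if not movie.snapshots:
        raise ValueError("morphomovie has no snapshots to export")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    out = []
    for i, s in enumerate(movie.snapshots):
        frame = movie.trajectory.frames[s.frame_index]
        fp = root / f"frame_{i:06d}.vtk"
        _write_vtk(fp, s.positions, frame.mesh.triangles, s.state.mesenchyme,
                   title=f"t={s.time:g}")
        out.append(fp)
    return out


# ---------------------------------------------------------------------------
# Small text artefacts
# ---------------------------------------------------------------------------


def write_fit_trace(trace, path) -> None:
    """Delimited-text fit trace: iteration, parameters, objective."""
    path = Path(path)
    if not trace:
        path.write_text("iteration\tobjective\n")
        return
    names = sorted(trace[0][0])
    lines = ["iteration\t" + "\t".join(names) + "\tobjective"]
    for i, (params, f) in enumerate(trace):
        lines.append(
            f"{i}\t" + "\t".join(f"{params[n]:.12g}" for n in names) + f"\t{f:.12g}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_pattern(pattern: DigitisedPattern, path) -> None:
    """Persist a digitised pattern with its provenance block."""
    doc = {
        "format": "limbrd-pattern-1",
        "image_id": pattern.image_id,
        "transform": pattern.transform.matrix.tolist() if pattern.transform else None,
        "invert_intensity": bool(pattern.transform.invert_intensity)
        if pattern.transform else None,
        "values": [float(v) for v in pattern.values],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_pattern(path) -> DigitisedPattern:
    from .analysis import AlignmentTransform

    doc = json.loads(Path(path).read_text())
    tf = None
    if doc.get("transform") is not None:
        tf = AlignmentTransform(
            matrix=np.asarray(doc["transform"]),
            invert_intensity=bool(doc.get("invert_intensity")),
        )
    return DigitisedPattern(
        values=np.asarray(doc["values"]), image_id=doc.get("image_id"), transform=tf
    )
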