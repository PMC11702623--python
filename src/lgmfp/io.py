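"""File formats and manifests.

Vertex maps travel as GIFTI metric files (``.func.gii``) or single-column
headerless CSV; meshes as GIFTI surfaces (``.surf.gii``) or plain-text OFF;
label maps and index lists as one integer per line (0-based).  Manifests
are UTF-8 TSV with a header row.  Reports are JSON and carry a schema
version plus a verbatim echo of the run configuration for provenance.
LCM tensors are persisted as a ``.npy`` array next to a JSON axis manifest
(subject order, centers, ring radius, deformable flag).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fingerprint import IdentificationReport, LcmTensor
from .lgm import VertexMap
from .mesh import SphericalMesh, level_for_vertex_count, _cyclic_rings

__all__ = [
    "SCHEMA_VERSION",
    "read_vertex_map",
    "write_vertex_map",
    "read_labels",
    "write_labels",
    "read_mesh_off",
    "write_mesh_off",
    "write_mesh_gifti",
    "read_manifest",
    "write_report",
    "save_lcm_tensor",
    "load_lcm_tensor",
]

SCHEMA_VERSION = "1"


def read_vertex_map(
    path: str | Path, mesh_level: int | None = None, kind: str = "generic"
) -> VertexMap:
    """Load a per-vertex scalar map from GIFTI metric or single-column CSV.

    If ``mesh_level`` is given the length is validated against it and a
    mismatch raises with both counts named.
    """
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        values = np.asarray(img.darrays[0].data, dtype=float)
        meta = dict(img.darrays[0].meta)
        kind = meta.get("lgmfp_kind", kind)
    else:
        values = np.loadtxt(path, dtype=float, ndmin=1)
    if mesh_level is not None:
        from .mesh import icosphere_vertex_count

        expected = icosphere_vertex_count(mesh_level)
        if values.size != expected:
            raise ValueError(
                f"{path}: expected {expected} values for level {mesh_level}, "
                f"found {values.size}"
            )
    return VertexMap(values, kind=kind)


def write_vertex_map(vmap: VertexMap, path: str | Path) -> None:
    """Write a map as GIFTI metric (``.gii``) or single-column CSV."""
    path = Path(path)
    if path.suffix == ".gii":
        darray = nib.gifti.GiftiDataArray(
            vmap.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
        )
        darray.meta = nib.gifti.GiftiMetaData(lgmfp_kind=vmap.kind)
        nib.save(nib.gifti.GiftiImage(darrays=[darray]), str(path))
    else:
        np.savetxt(path, vmap.values, fmt="%.17g")


def read_labels(path: str | Path) -> np.ndarray:
    """Per-vertex integer labels: GIFTI label file or one integer per line."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=np.int64)
    return np.loadtxt(path, dtype=np.int64, ndmin=1)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".gii":
        darray = nib.gifti.GiftiDataArray(
            np.asarray(labels, dtype=np.int32), intent="NIFTI_INTENT_LABEL"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[darray]), str(path))
    else:
        np.savetxt(path, np.asarray(labels, dtype=np.int64), fmt="%d")


def read_mesh_off(path: str | Path) -> SphericalMesh:
    """Read an OFF triangle mesh and rebuild the ring structure."""
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        cnt = int(tokens[pos])
        if cnt != 3:
            raise ValueError("only triangle meshes are supported")
        faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
        pos += 4
    triangles = np.asarray(faces, dtype=np.int64)
    rings = _cyclic_rings(nv, triangles)
    return SphericalMesh(
        vertex_coords=verts,
        triangles=triangles,
        neighbor_rings=rings,
        level=level_for_vertex_count(nv),
    )


def write_mesh_off(mesh: SphericalMesh, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.triangles.shape[0]} 0\n")
        for x, y, z in mesh.vertex_coords:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")


def write_mesh_gifti(mesh: SphericalMesh, path: str | Path) -> None:
    coords = nib.gifti.GiftiDataArray(
        mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))


def read_manifest(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    """Load a TSV manifest, checking required columns and path existence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest lacks columns {missing}")
    if "path" in df.columns:
        base = Path(path).parent
        resolved = []
        for p in df["path"]:
            candidate = Path(p)
            if not candidate.is_absolute():
                candidate = base / candidate
            if not candidate.exists():
                raise FileNotFoundError(f"{path}: listed file {p} does not exist")
            resolved.append(str(candidate))
        df["path"] = resolved
    return df


def write_report(
    report: IdentificationReport | dict,
    path: str | Path,
    config: dict | None = None,
    votes_path: str | Path | None = None,
) -> None:
    """Write an identification (or other) report as schema-versioned JSON;
    optionally a TSV sidecar with one vote-fraction row per target/base pair."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": config or {},
        "report": report.to_dict() if isinstance(report, IdentificationReport) else report,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    if votes_path is not None and isinstance(report, IdentificationReport):
        rows = []
        for i, t in enumerate(report.target_ids):
            for j, b in enumerate(report.base_ids):
                rows.append((t, b, report.vote_fractions[i, j]))
        pd.DataFrame(rows, columns=["target", "base", "vote_fraction"]).to_csv(
            votes_path, sep="\t", index=False
        )


def save_lcm_tensor(tensor: LcmTensor, prefix: str | Path) -> None:
    """Persist as ``{prefix}.npy`` plus ``{prefix}.json`` axis manifest."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), tensor.values)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "target_ids": tensor.target_ids,
        "base_ids": tensor.base_ids,
        "centers": [int(c) for c in tensor.centers],
        "r": tensor.r,
        "deformable": tensor.deformable,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh)
        fh.write("\n")


def load_lcm_tensor(prefix: str | Path) -> LcmTensor:
    prefix = Path(prefix)
    values = np.load(prefix.with_suffix(".npy"))
    with open(prefix.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    return LcmTensor(
        values=values,
        centers=np.asarray(manifest["centers"], dtype=np.int64),
        r=manifest["r"],
        deformable=manifest["deformable"],
        target_ids=manifest["target_ids"],
        base_ids=manifest["base_ids"],
    )
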