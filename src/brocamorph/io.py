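"""Readers and writers for the standard neuroimaging surface formats.

Meshes travel as GIFTI surface files (coordinate + topology arrays) or
ASCII PLY, with the spherical parameterization in a companion file
(``<stem>.sphere.gii`` / ``<stem>.sphere.csv``) and hemisphere/space
metadata either in the GIFTI header or a ``<stem>.meta.json`` sidecar.
Scalar and label maps are GIFTI functional/label files or single-column
CSV; label tables go in the GIFTI label table or a sidecar JSON.  Label
volumes are NIfTI with the affine preserved exactly.  The CSV fallbacks
make the package exercisable without any neuroimaging tooling downstream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh_core import LabelMap, ScalarMap, TriangleMesh
from .vol2surf import LabelVolume


def _stem(path: Path) -> Path:
    """Path without recognized suffix chains (``.surf.gii`` -> base)."""
    name = path.name
    for suffix in (".surf.gii", ".sphere.gii", ".func.gii", ".label.gii",
                   ".gii", ".ply", ".csv", ".nii.gz", ".nii", ".json"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path.with_suffix("")


def sphere_companion(path: Path) -> Path:
    path = Path(path)
    ext = ".sphere.gii" if path.name.endswith(".gii") else ".sphere.csv"
    return _stem(path).with_name(_stem(path).name + ext)


def _meta_companion(path: Path) -> Path:
    return _stem(path).with_name(_stem(path).name + ".meta.json")


# ---------------------------------------------------------------------------
# meshes


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh plus its spherical-parameterization companion file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"hemisphere": mesh.hemisphere, "space_tag": mesh.space_tag}
    if path.name.endswith(".gii"):
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            )
        )
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            )
        )
        img.meta = nib.gifti.GiftiMetaData(**meta)
        nib.save(img, path)
        simg = nib.gifti.GiftiImage()
        simg.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                mesh.sphere_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            )
        )
        nib.save(simg, sphere_companion(path))
    elif path.name.endswith(".ply"):
        import trimesh

        tm = trimesh.Trimesh(
            vertices=mesh.vertex_coords, faces=mesh.faces, process=False
        )
        tm.export(path, file_type="ply", encoding="ascii")
        pd.DataFrame(mesh.sphere_coords, columns=["sx", "sy", "sz"]).to_csv(
            sphere_companion(path), index=False
        )
        _meta_companion(path).write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read a mesh and its spherical companion; warn on non-manifold input."""
    import warnings

    path = Path(path)
    comp = sphere_companion(path)
    if not comp.exists():
        raise FileNotFoundError(
            f"missing spherical-parameterization companion file: {comp}"
        )
    meta = {"hemisphere": "left", "space_tag": ""}
    if path.name.endswith(".gii"):
        img = nib.load(path)
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        gmeta = dict(img.meta) if img.meta else {}
        meta.update({k: v for k, v in gmeta.items() if k in meta})
        simg = nib.load(comp)
        sphere = simg.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    elif path.name.endswith(".ply"):
        import trimesh

        tm = trimesh.load(path, file_type="ply", process=False)
        coords = np.asarray(tm.vertices)
        faces = np.asarray(tm.faces)
        sphere = pd.read_csv(comp).to_numpy()
        mpath = _meta_companion(path)
        if mpath.exists():
            meta.update(json.loads(mpath.read_text()))
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")
    # guard against float drift in the companion file
    sphere = np.asarray(sphere, dtype=float)
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    mesh = TriangleMesh(
        vertex_coords=np.asarray(coords, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        sphere_coords=sphere,
        hemisphere=str(meta["hemisphere"]),
        space_tag=str(meta["space_tag"]),
    )
    try:
        mesh.validate()
    except ValueError as exc:
        warnings.warn(f"loaded mesh fails manifold checks: {exc}", stacklevel=2)
    return mesh


# ---------------------------------------------------------------------------
# per-vertex maps


def write_scalar_map(smap: ScalarMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".gii"):
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                smap.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
        )
        img.meta = nib.gifti.GiftiMetaData(name=smap.name, mesh_tag=smap.mesh_tag)
        nib.save(img, path)
    else:
        pd.DataFrame({smap.name: smap.values}).to_csv(path, index=False)


def read_scalar_map(path: str | Path, name: str | None = None) -> ScalarMap:
    path = Path(path)
    if path.name.endswith(".gii"):
        img = nib.load(path)
        values = img.darrays[0].data.astype(float)
        meta = dict(img.meta) if img.meta else {}
        return ScalarMap(
            values,
            name=name or meta.get("name", "other"),
            mesh_tag=meta.get("mesh_tag", ""),
        )
    df = pd.read_csv(path)
    col = df.columns[0]
    return ScalarMap(df[col].to_numpy(dtype=float), name=name or col)


def write_label_map(lmap: LabelMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".gii"):
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                lmap.values.astype(np.int32), intent="NIFTI_INTENT_LABEL"
            )
        )
        table = nib.gifti.GiftiLabelTable()
        for key, label_name in sorted(lmap.label_names.items()):
            lab = nib.gifti.GiftiLabel(key=int(key))
            lab.label = label_name
            table.labels.append(lab)
        img.labeltable = table
        nib.save(img, path)
    else:
        pd.DataFrame({"label": lmap.values}).to_csv(path, index=False)
        sidecar = _stem(path).with_name(_stem(path).name + ".labels.json")
        sidecar.write_text(
            json.dumps({str(k): v for k, v in lmap.label_names.items()})
        )


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    if path.name.endswith(".gii"):
        img = nib.load(path)
        values = img.darrays[0].data.astype(np.int64)
        names = {
            int(lab.key): lab.label
            for lab in img.labeltable.labels
            if lab.key != 0
        }
        return LabelMap(values, label_names=names)
    df = pd.read_csv(path)
    values = df[df.columns[0]].to_numpy(dtype=np.int64)
    sidecar = _stem(path).with_name(_stem(path).name + ".labels.json")
    names: dict[int, str] = {}
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        names = {int(v): f"label_{v}" for v in np.unique(values) if v != 0}
    return LabelMap(values, label_names=names)


# ---------------------------------------------------------------------------
# label volumes


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.array.astype(np.int16), vol.affine)
    nib.save(img, path)
    if vol.label_names:
        sidecar = _stem(path).with_name(_stem(path).name + ".labels.json")
        sidecar.write_text(
            json.dumps({str(k): v for k, v in vol.label_names.items()})
        )


def read_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = nib.load(path)
    sidecar = _stem(path).with_name(_stem(path).name + ".labels.json")
    names: dict[int, str] = {}
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelVolume(
        array=np.asarray(img.dataobj).astype(np.int64),
        affine=np.asarray(img.affine),
        label_names=names,
    )


# ---------------------------------------------------------------------------
# warps and provenance


def write_warp(warp, path: str | Path) -> None:
    """Serialize a spherical warp as a per-vertex coordinate table."""
    from .registration import SphericalWarp  # noqa: F401

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        np.hstack([warp.target_points, warp.source_sphere]),
        columns=["tx", "ty", "tz", "sx", "sy", "sz"],
    )
    df.to_csv(path, index=False)
    sidecar = _stem(path).with_name(_stem(path).name + ".warp.json")
    sidecar.write_text(
        json.dumps(
            {
                "source_tag": warp.source_tag,
                "target_tag": warp.target_tag,
                "faces": warp.source_faces.tolist(),
            }
        )
    )


def read_warp(path: str | Path):
    from .registration import SphericalWarp

    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _stem(path).with_name(_stem(path).name + ".warp.json")
    meta = json.loads(sidecar.read_text())
    target = df[["tx", "ty", "tz"]].to_numpy()
    target /= np.linalg.norm(target, axis=1, keepdims=True)
    return SphericalWarp(
        target_points=target,
        source_sphere=df[["sx", "sy", "sz"]].to_numpy(),
        source_faces=np.asarray(meta["faces"], dtype=np.int64),
        source_tag=meta["source_tag"],
        target_tag=meta["target_tag"],
    )


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(path: str | Path, seed: int, config: dict) -> None:
    """Record the seed and configuration hash every report must carry."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("brocamorph")
    except PackageNotFoundError:
        pkg_version = "unknown"
    payload = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "package_version": pkg_version,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str))
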