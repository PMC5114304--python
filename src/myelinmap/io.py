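"""Standard-format I/O: GIFTI surfaces/metrics/labels, CSV vertex tables,
YAML configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml
import nibabel as nib
from nibabel import gifti

from .atlas import ROIAtlas, RegionInfo
from .errors import SchemaError
from .mesh import SurfaceMesh

__all__ = ["save_surface_gifti", "load_surface_gifti", "save_metric_gifti",
           "load_metric_gifti", "save_label_gifti", "load_label_gifti",
           "write_vertex_table", "read_vertex_table", "load_config",
           "save_config"]


def save_surface_gifti(mesh: SurfaceMesh, path) -> None:
    img = gifti.GiftiImage(darrays=[
        gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                             intent="NIFTI_INTENT_POINTSET"),
        gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                             intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def load_surface_gifti(path) -> SurfaceMesh:
    img = nib.load(str(path))
    pts = tris = None
    for da in img.darrays:
        if da.intent == gifti.gifti.intent_codes["NIFTI_INTENT_POINTSET"]:
            pts = np.asarray(da.data, dtype=float)
        elif da.intent == gifti.gifti.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(da.data, dtype=np.int64)
    if pts is None or tris is None:
        raise SchemaError(f"{path}: missing POINTSET or TRIANGLE array")
    return SurfaceMesh(pts, tris)


def save_metric_gifti(maps: dict, path) -> None:
    """Write named per-vertex float maps as one metric file (float32)."""
    darrays = []
    for name, values in maps.items():
        da = gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                                  intent="NIFTI_INTENT_NONE")
        da.meta["Name"] = name
        darrays.append(da)
    nib.save(gifti.GiftiImage(darrays=darrays), str(path))


def load_metric_gifti(path) -> dict:
    img = nib.load(str(path))
    out = {}
    for k, da in enumerate(img.darrays):
        name = da.meta.get("Name", f"column_{k}")
        out[name] = np.asarray(da.data, dtype=float)
    if not out:
        raise SchemaError(f"{path}: no metric data arrays")
    return out


def save_label_gifti(atlas: ROIAtlas, path) -> None:
    da = gifti.GiftiDataArray(atlas.labels.astype(np.int32),
                              intent="NIFTI_INTENT_LABEL")
    table = gifti.GiftiLabelTable()
    for lb in sorted(atlas.table):
        info = atlas.table[lb]
        lab = gifti.GiftiLabel(key=int(lb))
        lab.label = f"{info.name}|{info.myelin_class}|{'' if info.neighbor_label is None else info.neighbor_label}"
        table.labels.append(lab)
    img = gifti.GiftiImage(darrays=[da], labeltable=table)
    nib.save(img, str(path))


def load_label_gifti(path) -> ROIAtlas:
    img = nib.load(str(path))
    labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    table = {}
    for lab in img.labeltable.labels:
        try:
            name, cls, nb = lab.label.split("|")
        except ValueError as exc:
            raise SchemaError(f"{path}: malformed label entry {lab.label!r}") from exc
        table[int(lab.key)] = RegionInfo(name, cls, int(nb) if nb else None)
    if not table:
        raise SchemaError(f"{path}: empty label table")
    return ROIAtlas(labels, table)


VERTEX_TABLE_COLUMNS = ("vertex_id", "label", "depth", "parameter", "value")


def write_vertex_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in VERTEX_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"vertex table missing column(s): {', '.join(missing)}")
    df.to_csv(path, index=False)


def read_vertex_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in VERTEX_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
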