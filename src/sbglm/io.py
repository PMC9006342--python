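"""File formats: GIFTI surfaces / metric / label maps and documented
TSV dialects (UTF-8, tab-separated, '.' decimal, mandatory header).

The vertex order of the surface file is canonical; per-vertex maps are
never reordered on read, and the vertex counts of surfaces and maps are
cross-checked.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import gifti

from .mesh import TriangularMesh


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def write_surface_gifti(mesh: TriangularMesh, path: str | Path) -> None:
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def read_surface_gifti(path: str | Path) -> TriangularMesh:
    img = nib.load(str(path))
    codes = nib.nifti1.intent_codes.code
    verts = faces = None
    for da in img.darrays:
        if da.intent == codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(da.data, dtype=float)
        elif da.intent == codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, dtype=np.int64)
    if verts is None or faces is None:
        raise FormatError(f"{path}: not a GIFTI surface (pointset + triangles)")
    return TriangularMesh(verts, faces)


def write_surface_tsv(mesh: TriangularMesh, vertex_path, face_path) -> None:
    pd.DataFrame(mesh.vertices, columns=["x", "y", "z"]).to_csv(
        vertex_path, sep="\t", index=False
    )
    pd.DataFrame(mesh.faces, columns=["v0", "v1", "v2"]).to_csv(
        face_path, sep="\t", index=False
    )


def read_surface_tsv(vertex_path, face_path,
                     mask_path=None) -> TriangularMesh:
    verts = pd.read_csv(vertex_path, sep="\t")[["x", "y", "z"]].to_numpy(float)
    faces = pd.read_csv(face_path, sep="\t")[["v0", "v1", "v2"]].to_numpy(np.int64)
    mask = None
    if mask_path is not None:
        mask = read_mask_tsv(mask_path, len(verts))
    return TriangularMesh(verts, faces, mask)


def read_mask_tsv(path, n_vertices: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    col = df.iloc[:, 0].to_numpy()
    if col.size != n_vertices:
        raise FormatError(
            f"{path}: mask has {col.size} rows but the surface has {n_vertices} vertices"
        )
    return col.astype(bool)


# ---------------------------------------------------------------------------
# per-vertex maps and timeseries
# ---------------------------------------------------------------------------


def write_metric_gifti(values: np.ndarray, path: str | Path) -> None:
    """Per-vertex scalar map(s); ``values`` is (n,) or (n_maps, n)."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float32))
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(row, intent="NIFTI_INTENT_NONE") for row in values
        ]
    )
    nib.save(img, str(path))


def read_metric_gifti(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.stack([np.asarray(da.data, dtype=float) for da in img.darrays])
    if n_vertices is not None and data.shape[1] != n_vertices:
        raise FormatError(
            f"{path}: metric has {data.shape[1]} vertices, surface has {n_vertices}"
        )
    return data[0] if data.shape[0] == 1 else data


def write_label_gifti(
    labels: np.ndarray, path: str | Path, label_table: dict[int, str] | None = None
) -> None:
    labels = np.asarray(labels).astype(np.int32)
    table = gifti.GiftiLabelTable()
    entries = label_table or {0: "inactive", 1: "active"}
    rng = np.random.default_rng(0)
    for key, name in sorted(entries.items()):
        lab = gifti.GiftiLabel(key, *rng.uniform(0, 1, 3), 1.0)
        lab.label = name
        table.labels.append(lab)
    img = gifti.GiftiImage(labeltable=table)
    img.add_gifti_data_array(
        gifti.GiftiDataArray(labels, intent="NIFTI_INTENT_LABEL", datatype="NIFTI_TYPE_INT32")
    )
    nib.save(img, str(path))


def read_label_gifti(path: str | Path) -> tuple[np.ndarray, dict[int, str]]:
    img = nib.load(str(path))
    labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    table = {lab.key: lab.label for lab in img.labeltable.labels}
    return labels, table


def write_timeseries_tsv(data: np.ndarray, path: str | Path) -> None:
    """T x N BOLD matrix with v<i> column headers."""
    cols = [f"v{i}" for i in range(data.shape[1])]
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    data = pd.read_csv(path, sep="\t").to_numpy(float)
    if n_vertices is not None and data.shape[1] != n_vertices:
        raise FormatError(
            f"{path}: timeseries has {data.shape[1]} columns, expected {n_vertices}"
        )
    return data


def read_events_tsv(path: str | Path) -> tuple[dict, dict]:
    """Events table with columns task, onset_s, duration_s."""
    df = pd.read_csv(path, sep="\t")
    required = {"task", "onset_s", "duration_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: events TSV needs columns {sorted(required)}")
    onsets: dict[str, list[float]] = {}
    durations: dict[str, list[float]] = {}
    for task, sub in df.groupby("task", sort=False):
        onsets[str(task)] = sub["onset_s"].astype(float).tolist()
        durations[str(task)] = sub["duration_s"].astype(float).tolist()
    return onsets, durations


def write_events_tsv(onsets: dict, durations: dict, path: str | Path) -> None:
    rows = [
        {"task": task, "onset_s": o, "duration_s": d}
        for task in onsets
        for o, d in zip(onsets[task], durations[task])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_motion_tsv(path: str | Path) -> np.ndarray:
    """Motion parameter table (T x 6); first differences are appended
    downstream."""
    data = pd.read_csv(path, sep="\t").to_numpy(float)
    if data.shape[1] != 6:
        raise FormatError(f"{path}: motion TSV must have 6 columns")
    return data
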