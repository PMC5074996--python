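"""Volume and tree I/O with JSON provenance sidecars.

Supported volume formats: multi-page TIFF (voxel size in a JSON sidecar),
NIfTI (voxel size from the header; must be isotropic), and raw binary with a
mandatory JSON sidecar describing shape, dtype and voxel size.  Voxel size is
never defaulted silently.

Centerline trees are exported as SWC (one record per node: id, type, x, y, z
in mm with origin at the volume corner, radius = D_CT / 2 in mm when set,
parent id) and as CSV node/edge tables.  Array indices are 0-based (z, y, x)
internally; all exported coordinates are in mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import tifffile

from .segmentation import CenterlineTree
from .vesselness import IntensityVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_tree",
    "read_tree",
    "write_sidecar",
    "read_sidecar",
]

_VERSION = "0.1.0"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_sidecar(path, payload: dict) -> Path:
    """Write a JSON provenance sidecar (<file>.json next to <file>)."""
    sc = _sidecar_path(Path(path))
    body = {"software": "vesscal", "version": _VERSION}
    body.update(payload)
    sc.write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")
    return sc


def read_sidecar(path) -> dict:
    sc = _sidecar_path(Path(path))
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar {sc}")
    return json.loads(sc.read_text())


def read_volume(path) -> IntensityVolume:
    """Read a 3D volume with its mandatory isotropic voxel size (mm)."""
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix in (".nii", ".nii.gz"):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if max(zooms) - min(zooms) > 1e-3 * max(zooms):
            raise ValueError(
                f"{path}: anisotropic voxels {zooms}; the caliber method "
                "assumes isotropic sampling"
            )
        data = np.asarray(img.dataobj).T  # nibabel is (x, y, z); we use (z, y, x)
        return IntensityVolume(voxels=np.ascontiguousarray(data),
                               voxel_size=float(zooms[0]))
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(str(path))
        meta = read_sidecar(path)
        if "voxel_size_mm" not in meta:
            raise ValueError(f"{path}: sidecar lacks voxel_size_mm")
        return IntensityVolume(voxels=np.asarray(data),
                               voxel_size=float(meta["voxel_size_mm"]))
    if suffix == ".raw":
        meta = read_sidecar(path)
        for key in ("shape", "dtype", "voxel_size_mm"):
            if key not in meta:
                raise ValueError(f"{path}: sidecar lacks {key}")
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        data = data.reshape(tuple(meta["shape"]))
        return IntensityVolume(voxels=data, voxel_size=float(meta["voxel_size_mm"]))
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(vol, path, voxel_size: float | None = None, **provenance) -> Path:
    """Write a volume as TIFF stack (+ sidecar) or NIfTI (+ sidecar)."""
    path = Path(path)
    if isinstance(vol, IntensityVolume):
        data, vs = vol.voxels, vol.voxel_size
    else:
        data = np.asarray(vol)
        if voxel_size is None:
            raise ValueError("voxel_size is required for bare arrays")
        vs = float(voxel_size)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix in (".nii", ".nii.gz"):
        affine = np.diag([vs, vs, vs, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32).T, affine), str(path))
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))
    else:
        raise ValueError(f"unsupported volume format: {path}")
    write_sidecar(path, {"voxel_size_mm": vs, "shape": list(data.shape),
                         "axes": "zyx", **provenance})
    return path


# ---------------------------------------------------------------------------
# Trees


def write_tree(tree: CenterlineTree, path, fmt: str = "swc", root=None,
               **provenance) -> Path:
    """Export a centerline tree as SWC or CSV node/edge tables.

    SWC coordinates are (x, y, z) in mm with origin at the volume corner;
    radius is d_ct / 2 (mm) when mapped, 0 otherwise.  SWC requires an
    acyclic graph.
    """
    path = Path(path)
    g = tree.graph
    if fmt == "swc":
        if not nx.is_forest(g):
            raise ValueError("SWC export requires an acyclic (tree) graph")
        vs = tree.voxel_size
        lines = ["# id type x y z radius parent  (mm; origin at volume corner)"]
        swc_id = {}
        next_id = 1
        for comp in (sorted(c) for c in sorted(
                nx.connected_components(g), key=lambda c: min(c))):
            comp_root = root if root in comp else comp[0]
            for parent, child in [(None, comp_root)] + list(
                    nx.bfs_edges(g.subgraph(comp), comp_root)):
                swc_id[child] = next_id
                data = g.nodes[child]
                z, y, x = data["coord"]
                d_ct = data.get("d_ct")
                radius = (d_ct / 2.0) if (d_ct is not None and np.isfinite(d_ct)) else 0.0
                pid = swc_id[parent] if parent is not None else -1
                lines.append(
                    f"{next_id} 2 {x * vs:.6g} {y * vs:.6g} {z * vs:.6g} "
                    f"{radius:.6g} {pid}"
                )
                next_id += 1
        path.write_text("\n".join(lines) + "\n")
        write_sidecar(path, {"format": "swc", "voxel_size_mm": vs,
                             "volume_shape": list(tree.volume_shape), **provenance})
        return path
    if fmt == "csv":
        import pandas as pd

        nodes = []
        for n in sorted(g.nodes):
            data = g.nodes[n]
            z, y, x = data["coord"]
            nodes.append({
                "id": n, "z": z, "y": y, "x": x,
                "s_max": data.get("s_max", np.nan),
                "d_ct": data.get("d_ct", np.nan),
            })
        edges = [{"id1": min(a, b), "id2": max(a, b)} for a, b in sorted(
            (tuple(sorted(e)) for e in g.edges))]
        nodes_path = path.with_name(path.stem + "_nodes.csv")
        edges_path = path.with_name(path.stem + "_edges.csv")
        pd.DataFrame(nodes).to_csv(nodes_path, index=False)
        pd.DataFrame(edges, columns=["id1", "id2"]).to_csv(edges_path, index=False)
        write_sidecar(nodes_path, {"format": "csv",
                                   "voxel_size_mm": tree.voxel_size,
                                   "volume_shape": list(tree.volume_shape),
                                   **provenance})
        return nodes_path
    raise ValueError(f"unknown tree format {fmt!r}")


def read_tree(path, fmt: str = "swc") -> CenterlineTree:
    """Read back a tree written by :func:`write_tree`."""
    path = Path(path)
    meta = read_sidecar(path)
    vs = float(meta["voxel_size_mm"])
    shape = tuple(meta["volume_shape"])
    g = nx.Graph()
    if fmt == "swc":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, _type, x, y, z, radius, parent = line.split()
            sid, parent = int(sid), int(parent)
            coord = (round(float(z) / vs), round(float(y) / vs), round(float(x) / vs))
            r = float(radius)
            g.add_node(sid, coord=coord,
                       d_ct=(2.0 * r if r > 0 else None))
            if parent != -1:
                g.add_edge(sid, parent)
        return CenterlineTree(g, shape, voxel_size=vs)
    if fmt == "csv":
        import pandas as pd

        nodes = pd.read_csv(path)
        edges = pd.read_csv(path.with_name(path.name.replace("_nodes", "_edges")))
        for row in nodes.itertuples(index=False):
            g.add_node(int(row.id), coord=(int(row.z), int(row.y), int(row.x)),
                       s_max=(None if np.isnan(row.s_max) else float(row.s_max)),
                       d_ct=(None if np.isnan(row.d_ct) else float(row.d_ct)))
        for row in edges.itertuples(index=False):
            g.add_edge(int(row.id1), int(row.id2))
        return CenterlineTree(g, shape, voxel_size=vs)
    raise ValueError(f"unknown tree format {fmt!r}")
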