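"""File I/O helpers: Gmsh MSH export/import and voltage CSV round-trips.

Meshes are exchanged in the ASCII Gmsh MSH 2.2 format (nodes, triangles,
and boundary line elements; the physical tag of a line element is its
electrode label, 0 off-electrode, and the tag of a triangle is its distance
layer).  Only the subset of the format the package produces is read back.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .forward import Protocol, VoltageVector


def write_msh(mesh, path) -> None:
    """Write the mesh as ASCII Gmsh MSH 2.2."""
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.12g} {y:.12g} 0\n")
        f.write("$EndNodes\n$Elements\n")
        n_el = len(mesh.boundary_edges) + mesh.n_elements
        f.write(f"{n_el}\n")
        k = 1
        for (a, b), lab in zip(mesh.boundary_edges, mesh.boundary_labels):
            f.write(f"{k} 1 2 {lab} {lab} {a + 1} {b + 1}\n")
            k += 1
        for (a, b, c), mark in zip(mesh.triangles, mesh.element_markers):
            f.write(f"{k} 2 2 {mark} {mark} {a + 1} {b + 1} {c + 1}\n")
            k += 1
        f.write("$EndElements\n")


def read_msh(path) -> dict:
    """Read back an MSH 2.2 file written by :func:`write_msh`.

    Returns a dict with ``nodes``, ``triangles``, ``boundary_edges``,
    ``boundary_labels`` and ``element_markers`` arrays (geometry-only; the
    domain/electrode objects are not reconstructed).
    """
    nodes, lines, line_tags, tris, tri_tags = [], [], [], [], []
    with open(path) as f:
        section = None
        for raw in f:
            tok = raw.split()
            if not tok:
                continue
            if tok[0].startswith("$"):
                section = tok[0][1:] if not tok[0].startswith("$End") else None
                continue
            if section == "Nodes" and len(tok) == 4:
                nodes.append((float(tok[1]), float(tok[2])))
            elif section == "Elements" and len(tok) >= 7:
                etype, ntags = int(tok[1]), int(tok[2])
                conn = [int(v) - 1 for v in tok[3 + ntags:]]
                tag = int(tok[3])
                if etype == 1:
                    lines.append(conn)
                    line_tags.append(tag)
                elif etype == 2:
                    tris.append(conn)
                    tri_tags.append(tag)
    if not nodes or not tris:
        raise ValidationError(f"no mesh content found in {path}")
    return {
        "nodes": np.asarray(nodes, dtype=float),
        "triangles": np.asarray(tris, dtype=np.int64),
        "boundary_edges": np.asarray(lines, dtype=np.int64),
        "boundary_labels": np.asarray(line_tags, dtype=np.int64),
        "element_markers": np.asarray(tri_tags, dtype=np.int64),
    }


def read_voltages_csv(path, protocol: Protocol, mesh_hash: str = "",
                      normalized: bool = False) -> VoltageVector:
    """Load a voltage vector from CSV, checking the index columns."""
    df = pd.read_csv(path)
    need = ["j_plus", "j_minus", "i_plus", "i_minus", "V"]
    if list(df.columns[:5]) != need:
        raise ValidationError(f"voltage CSV must have columns {need}")
    idx = protocol.index
    if len(df) != len(idx):
        raise ValidationError(
            f"CSV has {len(df)} rows, protocol expects {len(idx)}"
        )
    got = list(zip(zip(df.j_plus, df.j_minus), zip(df.i_plus, df.i_minus)))
    want = [((d[0], d[1]), (m[0], m[1])) for d, m in idx]
    if got != want:
        raise ValidationError("voltage CSV rows are not in canonical order")
    return VoltageVector(
        values=df.V.to_numpy(), protocol=protocol, mesh_hash=mesh_hash,
        normalized=normalized,
    )
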