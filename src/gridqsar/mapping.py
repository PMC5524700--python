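"""Mapping influential descriptors back into 3D: the hotspot analysis.

Descriptors weighted by univariate correlation (r) or by the PLS
regression coefficients (rc) of a chosen model are decoded from their
"ix,iy,iz_P_K" labels to grid-node positions, partitioned by sign, and
reported against the structure: residues with any atom within a radius of
a selected node are the candidate activity/specificity hotspots.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .ensemble import Ensemble
from .errors import GridQSARError, ParseError
from .grid import GridSpec, IEDTensor, KINDS

__all__ = ["MappedIED", "parse_label", "select_top_ieds", "neighbor_residues",
           "cluster_nodes", "export_pseudoatoms", "export_dx", "read_dx"]

_LABEL_RE = re.compile(r"^(-?\d+),(-?\d+),(-?\d+)_(.+)_(LJ|C)$")


def parse_label(label: str) -> tuple[tuple[int, int, int], str, str]:
    """Split "ix,iy,iz_P_K" into node index triple, probe name and kind."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ParseError(f"malformed descriptor label {label!r}")
    idx = (int(m.group(1)), int(m.group(2)), int(m.group(3)))
    return idx, m.group(4), m.group(5)


@dataclass(frozen=True)
class MappedIED:
    """One selected descriptor placed in 3D."""

    label: str
    position: tuple[float, float, float]
    weight: float
    kind: str
    probe: str

    @property
    def sign(self) -> str:
        return "negative" if self.weight < 0 else "positive"


def select_top_ieds(weights, grid: GridSpec, cutoff: float,
                    sign: str | None = None) -> list[MappedIED]:
    """Descriptors with |weight| >= cutoff (optionally one sign only),
    decoded to grid positions.

    ``weights`` is a label -> weight mapping (dict or Series); the weight
    may be a univariate r or a model regression coefficient.
    """
    if sign not in (None, "positive", "negative"):
        raise ValueError("sign must be None, 'positive' or 'negative'")
    items = weights.items() if hasattr(weights, "items") else weights
    out = []
    for label, w in items:
        w = float(w)
        if abs(w) < cutoff:
            continue
        if sign == "positive" and w <= 0:
            continue
        if sign == "negative" and w >= 0:
            continue
        idx, probe, kind = parse_label(label)
        pos = tuple(grid.node_position(idx))
        out.append(MappedIED(label=label, position=pos, weight=w, kind=kind,
                             probe=probe))
    return out


def neighbor_residues(ieds: list[MappedIED], structure: Ensemble,
                      radius: float, frame: int = 0,
                      roles=("enzyme", "substrate")) -> pd.DataFrame:
    """Residues with >= 1 atom within ``radius`` of >= 1 selected node.

    Returns a frame with one row per residue (chain, residue number and
    name, role), the number of distinct nodes it touches and the summed
    weight of those nodes, ordered by chain then residue number.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cols = ["chain", "residue_number", "residue_name", "role", "n_ieds",
            "sum_weight"]
    if not ieds:
        return pd.DataFrame(columns=cols)
    sel = structure.atom_indices(roles)
    coords = structure.coords[frame][sel]
    tree = cKDTree(np.array([m.position for m in ieds]))
    near = tree.query_ball_point(coords, r=radius)
    per_residue: dict[tuple, set[int]] = {}
    meta = {}
    for local_i, atom_i in enumerate(sel):
        hits = near[local_i]
        if not hits:
            continue
        a = structure.topology[atom_i]
        key = (a.chain_id, a.residue_number)
        per_residue.setdefault(key, set()).update(hits)
        meta[key] = (a.residue_name, a.role)
    rows = []
    for (chain, resnum), hit_ids in sorted(per_residue.items()):
        resname, role = meta[(chain, resnum)]
        rows.append({
            "chain": chain, "residue_number": resnum,
            "residue_name": resname, "role": role,
            "n_ieds": len(hit_ids),
            "sum_weight": float(sum(ieds[i].weight for i in hit_ids)),
        })
    return pd.DataFrame(rows, columns=cols)


def cluster_nodes(ieds: list[MappedIED], grid: GridSpec) -> list[list[MappedIED]]:
    """Group selected nodes into 26-connected lattice components.

    A neutral stand-in for hand-annotated descriptor regions: components
    are returned largest-first, with no claim about their identity.
    """
    if not ieds:
        return []
    n = grid.nodes_per_axis
    mask = np.zeros((n, n, n), dtype=bool)
    by_idx: dict[tuple, list[MappedIED]] = {}
    for m in ieds:
        idx, _, _ = parse_label(m.label)
        mask[idx] = True
        by_idx.setdefault(idx, []).append(m)
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    comps: list[list[MappedIED]] = [[] for _ in range(n_comp)]
    for idx, members in by_idx.items():
        comps[labels[idx] - 1].extend(members)
    return sorted(comps, key=len, reverse=True)


def export_pseudoatoms(ieds: list[MappedIED], path) -> None:
    """Write selected descriptors as PDB HETATM pseudo-atoms.

    Occupancy carries |weight| scaled to [0, 1] over the written set; the
    B-factor carries the raw weight; the element column distinguishes the
    two kinds (LJ vs C).
    """
    if not ieds:
        raise GridQSARError("no descriptors to export")
    wmax = max(abs(m.weight) for m in ieds) or 1.0
    with open(path, "w") as fh:
        for i, m in enumerate(ieds, start=1):
            x, y, z = m.position
            elem = "LJ" if m.kind == "LJ" else " C"
            fh.write(
                f"HETATM{i % 100000:5d}  IED IED X{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{abs(m.weight) / wmax:6.2f}"
                f"{m.weight:6.2f}          {elem:>2s}\n"
            )
        fh.write("END\n")


def export_dx(tensor: IEDTensor, probe: str, kind: str, path) -> None:
    """Write one (probe, kind) scalar field as an OpenDX regular grid."""
    values = tensor.kind_values(probe, kind)
    n = tensor.grid.nodes_per_axis
    # storage is x-fastest; DX data order runs z fastest
    vol = values.reshape(n, n, n).transpose(2, 1, 0).ravel()
    ox, oy, oz = tensor.grid.origin
    s = tensor.grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {n} {n} {n}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {s:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {s:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {n} {n} {n}\n")
        fh.write(f"object 3 class array type double rank 0 items {vol.size} "
                 "data follows\n")
        for start in range(0, vol.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vol[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def read_dx(path) -> tuple[GridSpec, np.ndarray]:
    """Parse an OpenDX regular scalar grid back into (GridSpec, values in
    x-fastest node order)."""
    counts = origin = None
    deltas = []
    data = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("object") and "gridpositions" in line:
                counts = [int(v) for v in line.split("counts")[1].split()]
            elif line.startswith("origin"):
                origin = [float(v) for v in line.split()[1:4]]
            elif line.startswith("delta"):
                deltas.append([float(v) for v in line.split()[1:4]])
            elif "data follows" in line:
                in_data = True
            elif line.startswith("attribute"):
                in_data = False
            elif in_data:
                data.extend(float(v) for v in line.split())
    if counts is None or origin is None or len(deltas) < 3:
        raise ParseError(f"not a regular OpenDX scalar grid: {path}")
    if len(set(counts)) != 1:
        raise ParseError("only cubic grids are supported")
    n = counts[0]
    spacing = deltas[0][0]
    spec = GridSpec(origin=tuple(origin), edge_length=spacing * (n - 1),
                    spacing=spacing)
    vol = np.asarray(data).reshape(n, n, n)  # (x, y, z), z fastest on disk
    values = vol.transpose(2, 1, 0).ravel()  # back to x-fastest
    return spec, values
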