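"""Probe interaction-energy descriptors (IEDs) on a regular lattice.

For each node of a cubic grid enclosing a CEP, and for each single-site
probe, two descriptors are evaluated: the ensemble-mean Lennard-Jones and
the ensemble-mean Coulomb interaction energy between the probe at that
node and all (parameterized) atoms of the complex, averaged over the
conformations,

    LJ(node)  = <sum_a C12_ap / r^12 - C6_ap / r^6>_frames
    C(node)   = <sum_a k_e q_a q_p / (eps r)>_frames

with k_e = 332.0636 kcal*A/(mol*e^2). Each descriptor carries a label
"ix,iy,iz_P_K" encoding the integer node index, the probe name P and the
kind K (LJ or C). Energies at or above a cap (default 30 kcal/mol) are
logarithmically compressed so that near-clash nodes do not dominate the
regression.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ensemble import AtomRecord, Ensemble
from .errors import GridSpecError, GridQSARError

__all__ = [
    "COULOMB_CONSTANT", "Probe", "GridSpec", "IEDTensor", "default_probes",
    "load_probes", "make_grid", "pair_energy", "compute_ied", "cap_energies",
    "cap_value", "descriptor_labels",
]

#: Coulomb constant in kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0636

KINDS = ("LJ", "C")


@dataclass(frozen=True)
class Probe:
    """A single-site interaction probe (effective chemotype site)."""

    name: str
    charge: float
    c6: float
    c12: float

    def __post_init__(self):
        if self.c6 < 0 or self.c12 < 0:
            raise ValueError("probe C6 and C12 must be non-negative")


def load_probes(path=None) -> list[Probe]:
    """Load a probe table (name, charge, c6, c12); default = bundled set."""
    if path is None:
        ref = importlib.resources.files("gridqsar.data") / "probes.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    probes = [Probe(str(r.name), float(r.charge), float(r.c6), float(r.c12))
              for r in df.itertuples(index=False)]
    names = [p.name for p in probes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate probe names in table")
    return probes


def default_probes() -> list[Probe]:
    """The five bundled chemotype probes: O-H, Ar(NH), SH, COO-, H2O."""
    return load_probes(None)


@dataclass(frozen=True)
class GridSpec:
    """A cubic, boundary-inclusive lattice.

    ``edge_length``/``spacing`` must be integral; an edge of 24 A at 1 A
    spacing gives 25 nodes per axis, 15,625 nodes in total.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    edge_length: float = 24.0
    spacing: float = 1.0

    def __post_init__(self):
        if self.spacing <= 0 or self.edge_length <= 0:
            raise GridSpecError("edge_length and spacing must be positive")
        ratio = self.edge_length / self.spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise GridSpecError(
                f"edge_length/spacing = {ratio} is not integral")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @classmethod
    def centered(cls, center, edge_length: float = 24.0,
                 spacing: float = 1.0) -> "GridSpec":
        center = np.asarray(center, dtype=float)
        origin = tuple(center - edge_length / 2.0)
        return cls(origin=origin, edge_length=edge_length, spacing=spacing)

    @property
    def nodes_per_axis(self) -> int:
        return int(round(self.edge_length / self.spacing)) + 1

    @property
    def n_nodes(self) -> int:
        return self.nodes_per_axis ** 3

    def node_indices(self) -> np.ndarray:
        """Integer (ix, iy, iz) triples in x-fastest order, shape (N, 3)."""
        n = self.nodes_per_axis
        iz, iy, ix = np.meshgrid(np.arange(n), np.arange(n), np.arange(n),
                                 indexing="ij")
        return np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])

    def nodes(self) -> np.ndarray:
        """Node coordinates in Angstrom, x-fastest order, shape (N, 3)."""
        return np.asarray(self.origin) + self.node_indices() * self.spacing

    def node_position(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * self.spacing

    def compatible_with(self, other: "GridSpec") -> bool:
        return (np.allclose(self.origin, other.origin, atol=1e-9)
                and abs(self.edge_length - other.edge_length) < 1e-9
                and abs(self.spacing - other.spacing) < 1e-9)


def make_grid(spec: GridSpec) -> np.ndarray:
    """Enumerate grid node coordinates (deterministic x-fastest order)."""
    return spec.nodes()


def descriptor_labels(spec: GridSpec, probes: Sequence[Probe]) -> list[str]:
    """All "ix,iy,iz_P_K" labels in canonical probe -> kind -> node order."""
    idx = spec.node_indices()
    coord_part = [f"{ix},{iy},{iz}" for ix, iy, iz in idx]
    return [f"{c}_{p.name}_{kind}"
            for p in probes for kind in KINDS for c in coord_part]


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _combine(c6_a, c12_a, probe: Probe, rule: str):
    """Pairwise C6/C12 from atom and probe single-site parameters."""
    c6_a = np.asarray(c6_a, dtype=float)
    c12_a = np.asarray(c12_a, dtype=float)
    if rule == "geometric":
        return np.sqrt(c6_a * probe.c6), np.sqrt(c12_a * probe.c12)
    if rule == "lorentz_berthelot":
        # convert C6/C12 -> (sigma, eps), combine sigma arithmetically and
        # eps geometrically, convert back; zero-parameter partners give zero
        def to_sig_eps(c6, c12):
            with np.errstate(divide="ignore", invalid="ignore"):
                sig = np.where(c6 > 0, (c12 / np.maximum(c6, 1e-300)) ** (1 / 6), 0.0)
                eps = np.where(c12 > 0, c6 ** 2 / (4 * np.maximum(c12, 1e-300)), 0.0)
            return sig, eps

        sig_a, eps_a = to_sig_eps(c6_a, c12_a)
        sig_p, eps_p = to_sig_eps(np.array(probe.c6), np.array(probe.c12))
        sig = 0.5 * (sig_a + sig_p)
        eps = np.sqrt(eps_a * eps_p)
        c6 = 4 * eps * sig ** 6
        c12 = 4 * eps * sig ** 12
        return c6, c12
    raise ValueError(f"unknown combining rule {rule!r}")


def pair_energy(atom: AtomRecord, probe: Probe, r: float,
                dielectric: float = 1.0, combining: str = "geometric",
                clamp: float = 0.05) -> tuple[float, float]:
    """(Lennard-Jones, Coulomb) energy of one atom-probe pair at distance r."""
    r = max(float(r), clamp)
    c6, c12 = _combine(atom.c6, atom.c12, probe, combining)
    inv6 = 1.0 / r ** 6
    lj = float(c12) * inv6 * inv6 - float(c6) * inv6
    coulomb = COULOMB_CONSTANT * atom.charge * probe.charge / (dielectric * r)
    return float(lj), float(coulomb)


@dataclass
class IEDTensor:
    """Mean probe interaction energies of one code on one grid.

    ``values`` has shape (n_probes, 2, n_nodes); axis 1 is (LJ, C). The
    flattened probe -> kind -> node order matches :func:`descriptor_labels`.
    """

    code: str
    grid: GridSpec
    probes: list[Probe]
    values: np.ndarray
    capped: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.probes), 2, self.grid.n_nodes)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def n_descriptors(self) -> int:
        return 2 * len(self.probes) * self.grid.n_nodes

    def labels(self) -> list[str]:
        return descriptor_labels(self.grid, self.probes)

    def flat_values(self) -> np.ndarray:
        return self.values.reshape(-1)

    def kind_values(self, probe_name: str, kind: str) -> np.ndarray:
        names = [p.name for p in self.probes]
        if probe_name not in names or kind not in KINDS:
            raise GridQSARError(f"unknown probe/kind ({probe_name!r}, {kind!r})")
        return self.values[names.index(probe_name), KINDS.index(kind)]


def compute_ied(cep: Ensemble, grid: GridSpec, probes: Sequence[Probe],
                roles: Iterable[str] = ("enzyme", "substrate"),
                dielectric: float = 1.0, combining: str = "geometric",
                clamp: float = 0.05, conf_chunk: int = 32) -> IEDTensor:
    """Evaluate mean LJ and Coulomb probe energies at every grid node.

    The CEP must be aligned and parameterized. ``roles`` selects which
    atoms contribute (solvent is excluded by default). Values are raw
    (uncapped) kcal/mol; apply :func:`cap_energies` before assembling the
    descriptor matrix.
    """
    if not cep.parameterized:
        raise GridQSARError(
            f"ensemble {cep.code!r} has no parameters; call assign_parameters")
    sel = cep.atom_indices(roles)
    if sel.size == 0:
        raise GridQSARError(f"no atoms with roles {tuple(roles)}")
    nodes = grid.nodes()
    q = cep.charges()[sel]
    c6 = cep.c6s()[sel]
    c12 = cep.c12s()[sel]

    n_probes = len(probes)
    acc = np.zeros((n_probes, 2, grid.n_nodes))
    pc6 = np.empty((n_probes, sel.size))
    pc12 = np.empty((n_probes, sel.size))
    for pi, p in enumerate(probes):
        pc6[pi], pc12[pi] = _combine(c6, c12, p, combining)

    coords = cep.coords[:, sel, :]
    n_conf = coords.shape[0]
    n2 = (nodes ** 2).sum(axis=1)
    clamp2 = clamp * clamp
    for start in range(0, n_conf, conf_chunk):
        block = coords[start:start + conf_chunk]
        flat = block.reshape(-1, 3)  # (B*A, 3)
        d2 = (flat ** 2).sum(axis=1)[:, None] + n2[None, :]
        d2 -= 2.0 * (flat @ nodes.T)
        np.maximum(d2, clamp2, out=d2)
        inv2 = 1.0 / d2
        inv = np.sqrt(inv2)
        inv6 = inv2 * inv2 * inv2
        inv12 = inv6 * inv6
        b = block.shape[0]
        for pi, p in enumerate(probes):
            w12 = np.tile(pc12[pi], b)
            w6 = np.tile(pc6[pi], b)
            acc[pi, 0] += w12 @ inv12 - w6 @ inv6
            acc[pi, 1] += (COULOMB_CONSTANT * p.charge / dielectric) * \
                (np.tile(q, b) @ inv)
    acc /= n_conf
    return IEDTensor(code=cep.code, grid=grid, probes=list(probes), values=acc)


# ---------------------------------------------------------------------------
# energy capping
# ---------------------------------------------------------------------------

def cap_value(values, threshold: float = 30.0, base: float = 10.0,
              symmetric: bool = False):
    """Logarithmic compression of energies at or above ``threshold``.

    Piecewise and monotone non-decreasing:

    * E < threshold            -> E (unchanged)
    * threshold <= E <= thr+1  -> threshold
    * E > threshold + 1        -> threshold + log_base(E - threshold)

    The middle branch pins the residual-log formula, which would diverge
    to -inf as E approaches the threshold from above, at the threshold.
    With ``symmetric=True`` the same compression is mirrored onto large
    negative energies (E <= -threshold -> -cap(-E)), taming attractive
    near-singularities as well as repulsive ones.
    """
    v = np.asarray(values, dtype=float)
    out = v.copy()
    mid = (v >= threshold) & (v <= threshold + 1.0)
    out[mid] = threshold
    high = v > threshold + 1.0
    out[high] = threshold + np.log(v[high] - threshold) / np.log(base)
    if symmetric:
        mid = (v <= -threshold) & (v >= -threshold - 1.0)
        out[mid] = -threshold
        low = v < -threshold - 1.0
        out[low] = -(threshold + np.log(-v[low] - threshold) / np.log(base))
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def cap_energies(tensor: IEDTensor, threshold: float = 30.0,
                 base: float = 10.0, symmetric: bool = False) -> IEDTensor:
    """Apply :func:`cap_value` to all values of a tensor (post-averaging)."""
    return IEDTensor(code=tensor.code, grid=tensor.grid, probes=tensor.probes,
                     values=cap_value(tensor.values, threshold, base,
                                      symmetric=symmetric),
                     capped=True)
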