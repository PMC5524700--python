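"""Multi-conformation structure I/O and per-atom interaction parameters.

An :class:`Ensemble` is the unit the whole pipeline operates on: a fixed
atom topology (one :class:`AtomRecord` per atom) plus an ordered stack of
conformations of that topology, typically the frames of a short MD
trajectory of an enzyme active site complexed with its substrate.

Coordinates are Angstrom throughout; charges are elementary charge units;
the Lennard-Jones dispersion/repulsion coefficients C6 and C12 are in
kcal*A^6/mol and kcal*A^12/mol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingParameterError, ParseError, TopologyMismatchError

logger = logging.getLogger(__name__)

ROLES = ("enzyme", "substrate", "solvent")

#: residue names treated as solvent when inferring roles
SOLVENT_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "SPC"})

#: default chain-id -> role map; unlisted chains default to "enzyme"
DEFAULT_CHAIN_ROLES: Mapping[str, str] = {"S": "substrate", "W": "solvent"}


@dataclass
class AtomRecord:
    """One atom of the shared topology, with its interaction parameters."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str = "A"
    element: str = "C"
    role: str = "enzyme"
    charge: float = 0.0
    c6: float = 0.0
    c12: float = 0.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.c6 < 0 or self.c12 < 0:
            raise ValueError("C6 and C12 must be non-negative")


@dataclass
class Ensemble:
    """A conformational ensemble of one enzyme-variant/substrate complex.

    ``coords`` has shape (n_conformations, n_atoms, 3) in Angstrom. After
    rigid-body alignment of the frames this is the conformational ensemble
    profile (CEP) on which grid descriptors are evaluated.
    """

    code: str
    topology: list[AtomRecord]
    coords: np.ndarray
    parameterized: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.code:
            raise ValueError("ensemble code must be non-empty")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_conf, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one conformation")
        if self.coords.shape[1] != len(self.topology):
            raise TopologyMismatchError(
                f"{self.coords.shape[1]} coordinates per frame for "
                f"{len(self.topology)} topology atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, roles: Iterable[str]) -> np.ndarray:
        """Indices of atoms whose role is in ``roles``."""
        roles = set(roles)
        return np.array(
            [i for i, a in enumerate(self.topology) if a.role in roles], dtype=int
        )

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.topology])

    def c6s(self) -> np.ndarray:
        return np.array([a.c6 for a in self.topology])

    def c12s(self) -> np.ndarray:
        return np.array([a.c12 for a in self.topology])


def _infer_role(chain_id: str, residue_name: str,
                chain_roles: Mapping[str, str]) -> str:
    if residue_name.upper() in SOLVENT_RESNAMES:
        return "solvent"
    return chain_roles.get(chain_id, "enzyme")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_ensemble(path, format: str = "pdb_multimodel", code: str | None = None,
                  chain_roles: Mapping[str, str] | None = None) -> Ensemble:
    """Read a multi-conformation structure file into an :class:`Ensemble`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb_multimodel"`` (MODEL/ENDMDL blocks) or ``"xyz_trajectory"``
        (concatenated XYZ frames).
    code:
        Ensemble label; defaults to the file stem.
    chain_roles:
        chain-id -> role override map used to tag atoms as enzyme,
        substrate or solvent (PDB has no native role field).

    Interaction parameters are left zeroed; attach them afterwards with
    :func:`assign_parameters`.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    code = code or path.stem
    chain_roles = dict(DEFAULT_CHAIN_ROLES if chain_roles is None else chain_roles)
    if format == "pdb_multimodel":
        return _read_pdb(path, code, chain_roles)
    if format == "xyz_trajectory":
        return _read_xyz(path, code)
    raise ValueError(f"unknown format {format!r}")


def _read_pdb(path: Path, code: str, chain_roles: Mapping[str, str]) -> Ensemble:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(code, str(path))
    except Exception as exc:  # Biopython raises assorted exceptions
        raise ParseError(f"cannot parse PDB {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ParseError(f"no MODEL blocks or atoms in {path}")

    frames = []
    topology: list[AtomRecord] | None = None
    for model in models:
        atoms = []
        records = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atoms.append(atom.get_coord())
                    records.append(AtomRecord(
                        atom_name=atom.get_name(),
                        residue_name=residue.get_resname().strip(),
                        residue_number=residue.get_id()[1],
                        chain_id=chain.get_id(),
                        element=(atom.element or "C").strip() or "C",
                        role=_infer_role(chain.get_id(),
                                         residue.get_resname().strip(),
                                         chain_roles),
                    ))
        if not atoms:
            raise ParseError(f"empty MODEL in {path}")
        if topology is None:
            topology = records
        elif len(records) != len(topology):
            raise TopologyMismatchError(
                f"{path}: MODEL with {len(records)} atoms, expected "
                f"{len(topology)}"
            )
        frames.append(np.asarray(atoms, dtype=float))
    return Ensemble(code=code, topology=topology, coords=np.stack(frames))


def _read_xyz(path: Path, code: str) -> Ensemble:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"empty file: {path}")
    frames = []
    symbols: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParseError(f"{path}: bad frame header at line {i + 1}") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated frame at line {i + 1}")
        syms, xyz = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: bad atom line {ln!r}")
            syms.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if symbols is None:
            symbols = syms
        elif len(syms) != len(symbols):
            raise TopologyMismatchError(
                f"{path}: frame with {len(syms)} atoms, expected {len(symbols)}"
            )
        frames.append(np.asarray(xyz))
        i += 2 + n
    if not frames:
        raise ParseError(f"no frames in {path}")
    topology = [
        AtomRecord(atom_name=f"{s}{k + 1}", residue_name="UNK",
                   residue_number=1, chain_id="A", element=s, role="enzyme")
        for k, s in enumerate(symbols)
    ]
    return Ensemble(code=code, topology=topology, coords=np.stack(frames))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: Ensemble, path, format: str = "pdb_multimodel") -> None:
    """Write an ensemble; a read-back reproduces coordinates to 1e-3 A (PDB)."""
    path = Path(path)
    if format == "pdb_multimodel":
        _write_pdb(ensemble, path)
    elif format == "xyz_trajectory":
        _write_xyz(ensemble, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_pdb(ens: Ensemble, path: Path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(ens.coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (atom, (x, y, z)) in enumerate(zip(ens.topology, frame), start=1):
                name = atom.atom_name[:4]
                # PDB convention: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {i % 100000:5d} {name_field}"
                    f" {atom.residue_name[:3]:>3s} {atom.chain_id[:1]}"
                    f"{atom.residue_number % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element[:2]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_xyz(ens: Ensemble, path: Path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(ens.coords):
            fh.write(f"{ens.n_atoms}\n{ens.code} frame {m}\n")
            for atom, (x, y, z) in zip(ens.topology, frame):
                fh.write(f"{atom.element:<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


# ---------------------------------------------------------------------------
# parameter assignment
# ---------------------------------------------------------------------------

def read_parameter_table(path) -> pd.DataFrame:
    """Read a delimited (residue_name, atom_name) -> (charge, c6, c12) table."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    required = {"residue_name", "atom_name", "charge", "c6", "c12"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"parameter table missing columns: {sorted(missing)}")
    return df


def _as_lookup(params) -> dict[tuple[str, str], tuple[float, float, float]]:
    if isinstance(params, (str, Path)):
        params = read_parameter_table(params)
    if isinstance(params, pd.DataFrame):
        return {
            (str(r.residue_name), str(r.atom_name)): (r.charge, r.c6, r.c12)
            for r in params.itertuples()
        }
    if isinstance(params, Mapping):
        return {k: tuple(v) for k, v in params.items()}
    raise TypeError("params must be a path, DataFrame or mapping")


def assign_parameters(ensemble: Ensemble, params,
                      policy: str = "strict") -> Ensemble:
    """Return a copy of the ensemble with charge/C6/C12 attached to each atom.

    ``params`` maps ``(residue_name, atom_name)`` to ``(charge, c6, c12)``;
    it may be a mapping, a DataFrame or a path to a delimited table. With
    ``policy="strict"`` unresolvable atoms raise
    :class:`MissingParameterError`; with ``policy="zero"`` they are zeroed
    and a warning is logged. Assignment is idempotent.
    """
    if policy not in ("strict", "zero"):
        raise ValueError("policy must be 'strict' or 'zero'")
    table = _as_lookup(params)
    new_topology = []
    missing = []
    for atom in ensemble.topology:
        key = (atom.residue_name, atom.atom_name)
        if key in table:
            q, c6, c12 = table[key]
            new_topology.append(replace(atom, charge=float(q), c6=float(c6),
                                        c12=float(c12)))
        else:
            missing.append(key)
            new_topology.append(replace(atom, charge=0.0, c6=0.0, c12=0.0))
    if missing:
        if policy == "strict":
            raise MissingParameterError(
                f"no parameters for atoms: {sorted(set(missing))}")
        logger.warning("zeroed parameters for %d unresolvable atoms: %s",
                       len(missing), sorted(set(missing))[:10])
    return Ensemble(code=ensemble.code, topology=new_topology,
                    coords=ensemble.coords.copy(), parameterized=True)


def parameter_table_from_topology(topology: Sequence[AtomRecord]) -> pd.DataFrame:
    """Export the parameters carried by a topology as a table (round trip)."""
    rows, seen = [], set()
    for a in topology:
        key = (a.residue_name, a.atom_name)
        if key in seen:
            continue
        seen.add(key)
        rows.append({"residue_name": a.residue_name, "atom_name": a.atom_name,
                     "charge": a.charge, "c6": a.c6, "c12": a.c12})
    return pd.DataFrame(rows)
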