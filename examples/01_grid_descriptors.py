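"""Evaluate probe interaction-energy descriptors on a tiny complex.

Builds a three-atom "active site" with one substrate atom, samples a small
jittered ensemble, aligns it, and evaluates the mean Lennard-Jones and
Coulomb probe energies on a coarse grid — the descriptors every later
stage consumes.
"""

import numpy as np

from gridqsar import (GridSpec, cap_energies, compute_ied, default_probes)
from gridqsar.alignment import build_cep
from gridqsar.ensemble import AtomRecord, Ensemble

rng = np.random.default_rng(0)

topology = [
    AtomRecord("OG", "SER", 195, "A", "O", "enzyme", charge=-0.55,
               c6=600.0, c12=5e5),
    AtomRecord("NE2", "HIS", 57, "A", "N", "enzyme", charge=-0.40,
               c6=700.0, c12=6e5),
    AtomRecord("OD1", "ASP", 102, "A", "O", "enzyme", charge=-0.60,
               c6=600.0, c12=5e5),
    AtomRecord("C1", "SUB", 1, "S", "C", "substrate", charge=0.35,
               c6=800.0, c12=7e5),
]
base = np.array([[0.0, 0.0, 0.0], [3.0, 0.5, 0.0],
                 [1.5, 2.5, 1.0], [1.5, 0.8, 2.0]])
frames = base[None] + rng.normal(0, 0.2, size=(50, 4, 3))
ensemble = Ensemble(code="demo", topology=topology, coords=frames,
                    parameterized=True)

cep = build_cep(ensemble, ensemble.atom_indices(["enzyme"]))
grid = GridSpec.centered(cep.coords[0].mean(axis=0), edge_length=8.0,
                         spacing=2.0)
probes = default_probes()
tensor = cap_energies(compute_ied(cep, grid, probes))

print(f"{tensor.n_descriptors} descriptors "
      f"({len(probes)} probes x 2 kinds x {grid.n_nodes} nodes)")
for probe in probes[:2]:
    lj = tensor.kind_values(probe.name, "LJ")
    c = tensor.kind_values(probe.name, "C")
    print(f"probe {probe.name:>6s}: LJ mean {lj.mean():8.3f} kcal/mol, "
          f"Coulomb range [{c.min():7.2f}, {c.max():7.2f}] kcal/mol")
# Each value is the ensemble-average interaction energy a chemotype probe
# would feel at that grid node; capped values >= 30 kcal/mol mark nodes
# inside the repulsive core of an atom.
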