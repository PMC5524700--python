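"""Rigid-body superposition of conformations: building the CEP.

Every frame of an ensemble is least-squares superposed (Kabsch) onto the
first frame using a caller-chosen fit selection; the aligned stack is the
conformational ensemble profile (CEP). A second, cross-code alignment step
puts all ensembles of a study into one shared frame so that the same grid
node is spatially comparable across codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .ensemble import Ensemble

__all__ = ["RigidTransform", "superpose", "build_cep", "align_to_reference"]


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation (proper rotation, det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[RigidTransform, float]:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    Returns the rigid transform minimizing the least-squares deviation and
    the minimized RMSD. Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise AlignmentError("point sets must have equal shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise AlignmentError("need >= 3 points of dimension 3")

    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear (or coincident) points leave a rotation axis undetermined
    if S[1] <= 1e-10 * max(S[0], 1e-30):
        raise AlignmentError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mobile) - reference) ** 2,
                                        axis=1))))
    return transform, rmsd


def build_cep(ensemble: Ensemble, selection: np.ndarray | list[int]) -> Ensemble:
    """Superpose every conformation onto the first, fitting on ``selection``.

    The fitted transform of each frame moves *all* atoms of that frame;
    the first conformation is the (unchanged) reference. The result is the
    CEP of the ensemble.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AlignmentError("empty fit selection")
    if selection.min() < 0 or selection.max() >= ensemble.n_atoms:
        raise AlignmentError("fit selection outside topology")
    ref = ensemble.coords[0][selection]
    out = np.empty_like(ensemble.coords)
    out[0] = ensemble.coords[0]
    for i in range(1, ensemble.n_conformations):
        tr, _ = superpose(ensemble.coords[i][selection], ref)
        out[i] = tr.apply(ensemble.coords[i])
    return Ensemble(code=ensemble.code, topology=ensemble.topology, coords=out,
                    parameterized=ensemble.parameterized)


def align_to_reference(ensemble: Ensemble, reference: Ensemble,
                       selection: np.ndarray | list[int],
                       ref_selection: np.ndarray | list[int] | None = None
                       ) -> Ensemble:
    """Rigidly move a whole CEP into the frame of a reference code.

    The first frame of ``ensemble`` is superposed onto the first frame of
    ``reference`` using the given atom selections (which must pair up
    one-to-one), and the resulting single transform is applied to every
    frame. This makes grid descriptors spatially commensurate across codes.
    """
    selection = np.asarray(selection, dtype=int)
    ref_selection = (selection if ref_selection is None
                     else np.asarray(ref_selection, dtype=int))
    if selection.size != ref_selection.size:
        raise AlignmentError("selections must pair up one-to-one")
    tr, _ = superpose(ensemble.coords[0][selection],
                      reference.coords[0][ref_selection])
    out = np.stack([tr.apply(frame) for frame in ensemble.coords])
    return Ensemble(code=ensemble.code, topology=ensemble.topology, coords=out,
                    parameterized=ensemble.parameterized)
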