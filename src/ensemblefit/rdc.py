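"""Residual dipolar couplings from molecular shape.

Weak steric alignment in a compressed gel is modelled by an alignment
tensor derived from each conformer's shape: the traceless part of the
gyration tensor of the molecule's van-der-Waals surface, normalized to unit
Frobenius magnitude.  The surface second moments are computed analytically
(each atom contributes its sphere-surface area and moment; sphere overlap is
ignored), so the tensor is deterministic.  A one-bond C-H coupling is then
D = scale * < b^T S b > averaged over conformers, with one fitted magnitude
scale per alignment medium; only the tensor's orientation and rhombicity
matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InputError
from .geometry import VDW_RADII

__all__ = [
    "AlignmentTensor",
    "steric_alignment_tensor",
    "alignment_tensors",
    "predict_rdc",
    "rdc_effective_error",
]


@dataclass
class AlignmentTensor:
    S: np.ndarray  # symmetric traceless 3x3, unit Frobenius norm
    medium_id: str = ""
    magnitude: float = 1.0  # fitted per-medium scale (Hz)


def _surface_gyration(coords, radii):
    """Traceless surface-gyration tensors for a conformer batch.

    coords: (n, na, 3); radii: (na,).  Returns (n, 3, 3).
    """
    w = radii**2  # sphere surface area up to 4*pi
    wsum = w.sum()
    mu = np.einsum("a,nak->nk", w, coords) / wsum
    X = coords - mu[:, None, :]
    M = np.einsum("a,nai,naj->nij", w, X, X) / wsum
    M += np.eye(3)[None] * (np.sum(w * radii**2 / 3.0) / wsum)
    tr = np.trace(M, axis1=1, axis2=2)
    return M - (tr / 3.0)[:, None, None] * np.eye(3)[None]


def alignment_tensors(coords, elements=None, radii=None, normalize=True):
    """Per-conformer steric alignment tensors (n, 3, 3).

    ``radii`` may be given directly; otherwise van-der-Waals radii are looked
    up per element.  Degenerate (collinear) geometries raise GeometryError.
    """
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] < 4:
        raise GeometryError("need at least 4 atoms for a shape tensor")
    if radii is None:
        if elements is None:
            raise InputError("supply elements or radii")
        radii = np.array([VDW_RADII.get(e, 1.7) for e in elements])
    else:
        radii = np.asarray(radii, float)
    S = _surface_gyration(coords, radii)
    if normalize:
        nrm = np.linalg.norm(S, axis=(1, 2))
        if np.any(nrm < 1e-12):
            # isotropic shape: leave the zero tensor (predicts zero RDCs)
            nrm = np.where(nrm < 1e-12, 1.0, nrm)
        S = S / nrm[:, None, None]
    return S


def steric_alignment_tensor(conformer_or_coords, elements=None, medium_id=""):
    """Unit-magnitude alignment tensor of a single conformer."""
    if hasattr(conformer_or_coords, "coordinates"):
        coords = conformer_or_coords.coordinates
        elements = [a.element for a in conformer_or_coords.template.atoms]
    else:
        coords = np.asarray(conformer_or_coords, float)
    S = alignment_tensors(coords, elements=elements)[0]
    return AlignmentTensor(S=S, medium_id=medium_id)


def predict_rdc(coords, tensors, c_idx, h_idx, scale=1.0):
    """Ensemble-averaged RDCs (Hz) for bonded C-H pairs.

    coords: (n, na, 3); tensors: (n, 3, 3) per-conformer alignment tensors;
    c_idx/h_idx: index arrays of the bond atoms.  Linear in ``scale``.
    """
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    tensors = np.asarray(tensors, float)
    if tensors.ndim == 2:
        tensors = tensors[None]
    c_idx = np.atleast_1d(np.asarray(c_idx, int))
    h_idx = np.atleast_1d(np.asarray(h_idx, int))
    b = coords[:, h_idx] - coords[:, c_idx]  # (n, m, 3)
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    if np.any(nb < 1e-6):
        raise InputError("zero-length bond vector in RDC prediction")
    b = b / nb
    proj = np.einsum("nmi,nij,nmj->nm", b, tensors, b)
    return scale * proj.mean(axis=0)


def rdc_effective_error(error_hz, d_max, model_fraction=0.1):
    """Angle-dependence error inflation, in quadrature.

    eps_eff^2 = eps_exp^2 + (f * D_max)^2 where D_max is the medium's maximal
    |D| at the current scale and f the model-error fraction.
    """
    if np.any(np.asarray(error_hz) <= 0):
        raise InputError("base RDC error must be > 0")
    return np.sqrt(np.asarray(error_hz, float) ** 2 + (model_fraction * d_max) ** 2)
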