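"""Ensemble-averaged three-bond scalar couplings via Karplus relations.

Couplings are evaluated per conformer from the H-X-Y-H dihedral and
averaged over the ensemble as <J>; the average is over J values, never over
angles.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .geometry import dihedral_from_coords

__all__ = ["karplus_j", "ensemble_j", "ensemble_j_many"]


def karplus_j(theta_deg, kset):
    """J(theta) in Hz for a Karplus coefficient set.

    J = A cos^2 t + B cos t + C, plus Haasnoot-Altona substituent
    corrections sum_i dchi_i (D + E cos^2(xi_i t + F |dchi_i|)) when the set
    carries substituents.  Vectorized over theta.
    """
    t = np.radians(np.asarray(theta_deg, float))
    c = np.cos(t)
    J = kset.A * c * c + kset.B * c + kset.C
    if kset.substituents:
        for dchi, xi in kset.substituents:
            corr = np.cos(xi * t + np.radians(kset.F) * abs(dchi))
            J = J + dchi * (kset.D + kset.E * corr * corr)
    return J if np.ndim(theta_deg) else float(J)


def _quad_indices(template, atoms):
    try:
        return [template.index(a) for a in atoms]
    except InputError as exc:
        raise InputError(f"J restraint {atoms}: {exc}") from None


def ensemble_j(coords, template, restraint, karplus_sets):
    """Uniform ensemble mean of karplus_j over conformers, in Hz."""
    return ensemble_j_many(coords, template, [restraint], karplus_sets)[0]


def ensemble_j_many(coords, template, restraints, karplus_sets):
    """Vectorized <J> for several restraints over one conformer batch."""
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    out = np.empty(len(restraints))
    for k, r in enumerate(restraints):
        ia, ib, ic, id_ = _quad_indices(template, r.atoms)
        theta = dihedral_from_coords(
            coords[:, ia], coords[:, ib], coords[:, ic], coords[:, id_]
        )
        kset = karplus_sets[r.karplus_id] if isinstance(karplus_sets, dict) else karplus_sets
        out[k] = float(np.mean(karplus_j(theta, kset)))
    return out
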