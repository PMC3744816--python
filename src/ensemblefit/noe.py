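"""Full relaxation-matrix prediction of NOESY cross-peak heights.

Inter-proton distances are averaged over the conformer ensemble as
<r^-6>, converted to a homonuclear dipolar relaxation-rate matrix using
Lorentzian spectral densities from a single overall tumbling correlation
time tau_c, and the first-order rate equation is solved by diagonalization:
peak heights are entries of exp(-R * tau_mix).

Equivalent protons (methyls, NH2 groups) are collapsed to one spin pool of
multiplicity n: pair r^-6 terms are summed over group members, pool
magnetization is normalized per proton ("one-mole-equivalent"), and the
reported height for a pair of pools is the symmetric, multiplicity-weighted
matrix-exponential entry.  Intra-pool dipolar interactions contribute to the
pool's auto-relaxation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SingularityError, ValidationError

__all__ = [
    "SpinSystem",
    "RelaxationMatrix",
    "ensemble_r6",
    "relaxation_matrix",
    "predict_noesy",
    "DIPOLAR_CONSTANT",
]

# (mu0/4pi)^2 * hbar^2 * gammaH^4, in A^6 s^-2 (r^-6 supplied in A^-6).
_GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
_HBAR = 1.054571817e-34  # J s
DIPOLAR_CONSTANT = (1e-7 * _HBAR * _GAMMA_H**2) ** 2 * 1e60


@dataclass
class SpinSystem:
    """Proton spins of a molecule with equivalence groups collapsed.

    ``members[i]`` lists template atom indices pooled into spin i;
    ``multiplicity[i] = len(members[i])``.  Restraint proton references
    (atom or group names) resolve to spin indices via :meth:`spin_of`.
    """

    template: object
    names: list
    members: list
    _by_name: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_template(cls, template):
        grouped = {}
        for gname, atoms in template.equivalence_groups.items():
            for a in atoms:
                if template.element(a) != "H":
                    raise ValidationError(
                        f"equivalence group {gname!r} contains non-proton {a!r}"
                    )
                grouped[a] = gname
        names, members = [], []
        seen_groups = {}
        for i, atom in enumerate(template.atoms):
            if atom.element != "H":
                continue
            g = grouped.get(atom.name)
            if g is None:
                names.append(atom.name)
                members.append([i])
            elif g not in seen_groups:
                seen_groups[g] = len(names)
                names.append(g)
                members.append([i])
            else:
                members[seen_groups[g]].append(i)
        sys = cls(template, names, members)
        sys._by_name = {n: k for k, n in enumerate(names)}
        for a, g in grouped.items():
            sys._by_name.setdefault(a, sys._by_name[g])
        return sys

    @property
    def n_spins(self):
        return len(self.names)

    @property
    def multiplicity(self):
        return np.array([len(m) for m in self.members])

    def spin_of(self, proton_name):
        try:
            return self._by_name[proton_name]
        except KeyError:
            raise InputError(f"proton or group {proton_name!r} is not a spin") from None

    @property
    def proton_indices(self):
        return np.array([i for m in self.members for i in m])

    @property
    def pool_of_proton(self):
        """Spin index for each entry of :attr:`proton_indices`."""
        return np.array([k for k, m in enumerate(self.members) for _ in m])


def ensemble_r6(coords, spins, min_separation=1e-3):
    """Pool-summed ensemble-averaged <r^-6> matrix (A^-6).

    Entry (I, J) is sum over ordered member pairs (a in I, b in J, a != b) of
    the conformer-average of r_ab^-6; symmetric, with intra-pool sums on the
    diagonal.  Coincident protons raise :class:`SingularityError`.
    """
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[0] < 1:
        raise InputError("need at least one conformer")
    pidx = spins.proton_indices
    pool = spins.pool_of_proton
    X = np.ascontiguousarray(coords[:, pidx])  # (n, P, 3)

    from . import _fastbuild

    if _fastbuild.HAVE_NUMBA:
        S, dmin2 = _fastbuild.pooled_r6(X, pool.astype(np.int64), spins.n_spins)
        if dmin2 < min_separation**2:
            raise SingularityError(
                f"coincident protons (r = {np.sqrt(max(dmin2, 0.0)):.2e} A) "
                "in the ensemble"
            )
        return S

    sq = np.einsum("npk,npk->np", X, X)
    G = X @ X.transpose(0, 2, 1)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * G
    P = X.shape[1]
    ii = np.arange(P)
    d2[:, ii, ii] = np.inf
    dmin2 = d2.min()
    if dmin2 < min_separation**2:
        n0, a0, b0 = np.unravel_index(np.argmin(d2), d2.shape)
        names = spins.template.atom_names
        raise SingularityError(
            f"coincident protons {names[pidx[a0]]} and {names[pidx[b0]]} "
            f"(r = {np.sqrt(max(dmin2, 0.0)):.2e} A) in conformer {n0}"
        )
    inv = 1.0 / np.maximum(d2, 1e-30)
    r6 = np.mean(inv * inv * inv, axis=0)  # (P, P)
    ns = spins.n_spins
    B = np.zeros((ns, P))
    B[pool, np.arange(P)] = 1.0
    return B @ r6 @ B.T


@dataclass
class RelaxationMatrix:
    R: np.ndarray  # (ns, ns) rate matrix, s^-1, pool-normalized
    tau_c: float  # s
    omega: float  # 1H Larmor angular frequency, rad/s
    multiplicity: np.ndarray

    @property
    def sym(self):
        """Similarity-transformed symmetric form D R D^-1, D = diag(sqrt n)."""
        s = np.sqrt(self.multiplicity.astype(float))
        return self.R * (s[:, None] / s[None, :])


def _spectral_densities(tau_c, omega):
    J0 = tau_c
    J1 = tau_c / (1.0 + (omega * tau_c) ** 2)
    J2 = tau_c / (1.0 + (2.0 * omega * tau_c) ** 2)
    return J0, J1, J2


def cross_relaxation_rate(r6, tau_c, field_mhz):
    """Two-spin cross-relaxation rate sigma (s^-1) for a given <r^-6> (A^-6)."""
    omega = 2.0 * np.pi * field_mhz * 1e6
    J0, J1, J2 = _spectral_densities(tau_c, omega)
    return DIPOLAR_CONSTANT / 10.0 * r6 * (6.0 * J2 - J0)


def relaxation_matrix(r6, tau_c, field_mhz, multiplicity=None, leak_rate=0.0):
    """Convert a pool-summed <r^-6> matrix to the relaxation-rate matrix.

    sigma_IJ  proportional to <r^-6> (6 J(2w) - J(0));
    rho_I     sums J(0) + 3 J(w) + 6 J(2w) terms over partners, plus the
              intra-pool contribution and a uniform leak rate.
    """
    if tau_c <= 0:
        raise ValidationError("tau_c must be > 0")
    if field_mhz <= 0:
        raise ValidationError("field must be > 0")
    r6 = np.asarray(r6, float)
    ns = r6.shape[0]
    if multiplicity is None:
        multiplicity = np.ones(ns, dtype=int)
    multiplicity = np.asarray(multiplicity)
    omega = 2.0 * np.pi * field_mhz * 1e6
    J0, J1, J2 = _spectral_densities(tau_c, omega)
    q = DIPOLAR_CONSTANT / 10.0
    c_cross = q * (6.0 * J2 - J0)
    c_auto = q * (J0 + 3.0 * J1 + 6.0 * J2)
    off = r6 - np.diag(np.diag(r6))
    R = c_cross * off / multiplicity[:, None]
    rho = (c_auto * off.sum(axis=1) + (c_auto + c_cross) * np.diag(r6)) / multiplicity
    R[np.arange(ns), np.arange(ns)] = rho + leak_rate
    if not np.all(np.isfinite(R)):
        raise ValidationError("non-finite relaxation rates")
    return RelaxationMatrix(R=R, tau_c=tau_c, omega=omega, multiplicity=multiplicity)


def dump_relaxation_matrix(rmat, spins, path):
    """Write the rate matrix and its eigenvalues to TSV for inspection."""
    import pandas as pd

    df = pd.DataFrame(rmat.R, index=spins.names, columns=spins.names)
    df.index.name = "spin"
    df.to_csv(path, sep="\t")
    w = np.linalg.eigvalsh(0.5 * (rmat.sym + rmat.sym.T))
    with open(path, "a", encoding="utf-8") as fh:
        fh.write("# eigenvalues_s^-1\t" + "\t".join(f"{x:.6g}" for x in w) + "\n")


def predict_noesy(rmat, mixing_time):
    """Peak-height matrix exp(-R * tau_mix), by eigendecomposition.

    Returns the symmetric one-mole-equivalent height matrix
    ``D exp(-R tau) D^-1`` (D = diag(sqrt multiplicity)); its (I, J) entry is
    the predicted cross-peak height for the pool pair, and the diagonal
    carries the diagonal-peak heights.  ``tau_mix = 0`` gives the identity.
    """
    if mixing_time < 0:
        raise InputError("mixing time must be >= 0")
    S = rmat.sym
    try:
        w, V = np.linalg.eigh(0.5 * (S + S.T))
        H = (V * np.exp(-w * mixing_time)) @ V.T
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        import scipy.linalg

        warnings.warn("eigendecomposition failed; falling back to expm")
        H = scipy.linalg.expm(-S * mixing_time)
    return H
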