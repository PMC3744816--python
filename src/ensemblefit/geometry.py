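"""Cartesian conformer construction from fixed internal coordinates.

A molecule is described by a :class:`MoleculeTemplate`: an ordered list of
placement rows (z-matrix rows plus two convenience placements for ring
substituents), named rotatable torsions, rings with canonical pucker states,
proton equivalence groups and prochiral swap pairs.  Bond lengths and bond
angles are fixed by the template; conformers differ only in the values
assigned to rotatable torsions and ring pucker states.

All torsion angles are handled in degrees and canonicalized to (-180, 180].
Coordinates are in Angstrom.  Construction is fully vectorized over an
ensemble: the same placement program is evaluated for ``n`` conformers at
once, which is what makes per-step re-sampling during Monte-Carlo fitting
affordable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import (
    ConfigurationError,
    GeometryError,
    InputError,
    UndefinedDihedralError,
    ValidationError,
)

__all__ = [
    "Atom",
    "ZRow",
    "BisectorRow",
    "TripodRow",
    "RingState",
    "RingSpec",
    "MoleculeTemplate",
    "CartesianConformer",
    "wrap_angle",
    "measure_dihedral",
    "dihedral_from_coords",
    "angle_from_coords",
    "build_conformer",
    "build_ensemble_coords",
    "detect_clashes",
    "geometry_report",
    "solve_ring_state",
    "improper_offset",
    "write_pdb",
    "read_pdb_coords",
]

# Van der Waals radii (A) used for the molecular-surface shape tensor.
VDW_RADII = {"H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


def wrap_angle(a):
    """Wrap angle(s) in degrees to the canonical domain (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# Vector helpers (vectorized over leading axes)
# ---------------------------------------------------------------------------

def _unit(v, eps=1e-12):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < eps):
        raise UndefinedDihedralError("degenerate (zero-length) vector in geometry")
    return v / n


def dihedral_from_coords(p0, p1, p2, p3):
    """Signed dihedral angle (deg) of the four points, IUPAC convention.

    Positive when, looking from p1 towards p2, the far bond p2->p3 is rotated
    clockwise from the near bond p1->p0.  Vectorized over leading axes.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9 * np.maximum(nb2, 1.0)) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-9 * np.maximum(nb2, 1.0)
    ):
        raise UndefinedDihedralError("collinear atoms: dihedral undefined")
    m1 = _cross(n1, b2 / nb2[..., None])
    x = np.sum(n1 * n2, axis=-1)
    y = -np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def angle_from_coords(p0, p1, p2):
    """Bond angle p0-p1-p2 in degrees, vectorized over leading axes."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = _unit(p0 - p1)
    v = _unit(p2 - p1)
    c = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def _nerf_place(a, b, c, length, angle_deg, torsion_deg):
    """Place atom D given A, B, C with |CD|, angle(BCD) and dihedral(ABCD).

    Natural extension reference frame; all arguments broadcast over the
    ensemble axis.  Sign convention matches :func:`dihedral_from_coords`.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < 1e-10):
        raise UndefinedDihedralError("collinear reference atoms in placement")
    n = n / nn
    m = np.cross(n, bc)
    st = np.sin(theta)
    d_local = (
        -bc * np.cos(theta)[..., None]
        + m * (st * np.cos(phi))[..., None]
        + n * (st * np.sin(phi))[..., None]
    )
    return c + np.asarray(length)[..., None] * d_local if np.ndim(length) else c + length * d_local


def improper_offset(theta_ab, theta_ac, theta_bc):
    """Dihedral offset (deg) between substituents B and C about the X-A axis.

    For a center X with an axis substituent A and two further substituents
    B, C: given the angles A-X-B (``theta_ab``), A-X-C (``theta_ac``) and
    B-X-C (``theta_bc``), returns the magnitude of the dihedral angle between
    the planes (A,X,B) and (A,X,C) from the spherical law of cosines.  The
    caller chooses the sign (stereochemistry).
    """
    t1, t2, t12 = (math.radians(v) for v in (theta_ab, theta_ac, theta_bc))
    denom = math.sin(t1) * math.sin(t2)
    if denom < 1e-12:
        raise GeometryError("improper offset undefined for collinear substituents")
    c = (math.cos(t12) - math.cos(t1) * math.cos(t2)) / denom
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# Placement rows
# ---------------------------------------------------------------------------
#
# Dihedral specs (ZRow.dihedral):
#   ("fixed", value)            constant dihedral
#   ("torsion", name, offset)   named rotatable torsion (or trivial rotor) + offset
#   ("ring", ring, slot)        endocyclic torsion nu_slot of a ring pucker state
#   ("relative", atom, offset)  dihedral of a previously placed atom that shares
#                               the same (dihedral_ref, angle_ref, parent) + offset
# Angle field: float, or ("ring", ring, pos) = internal ring angle at path pos.


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue: str


@dataclass(frozen=True)
class ZRow:
    atom: str
    parent: str | None = None
    angle_ref: str | None = None
    dihedral_ref: str | None = None
    length: float = 0.0
    angle: object = 0.0
    dihedral: tuple = ("fixed", 0.0)


@dataclass(frozen=True)
class BisectorRow:
    """Substituent on a ring atom, placed off the ref1-center-ref2 bisector.

    ``side`` +1/-1 selects the face (stereochemistry); the out-of-plane tilt
    is chosen so that angle(atom, center, ref1) equals ``target_angle``.
    """

    atom: str
    center: str
    ref1: str
    ref2: str
    length: float
    side: int
    target_angle: float = 109.47


@dataclass(frozen=True)
class TripodRow:
    """Fourth substituent on an sp3 center with three placed neighbours."""

    atom: str
    center: str
    refs: tuple
    length: float


@dataclass(frozen=True)
class RingState:
    """Closed internal geometry of one canonical pucker state.

    ``torsions``: achieved endocyclic torsions nu_j about bond
    (path[j], path[j+1]), cyclic.  ``angles``: achieved internal angle at each
    path atom.  ``closure_length``: the ring-closing bond length.
    """

    torsions: tuple
    angles: tuple
    closure_length: float
    label: str = ""


@dataclass(frozen=True)
class RingSpec:
    name: str
    path: tuple  # atom names in construction order; closure bond path[-1]-path[0]
    states: Mapping[str, RingState]
    default_state: str

    @property
    def state_names(self):
        return list(self.states)


@dataclass
class MoleculeTemplate:
    """Fixed internal geometry plus the conformational degrees of freedom."""

    atoms: list
    rows: list
    rotatable_bonds: dict  # name -> (a, b, c, d) atom names
    rings: dict = field(default_factory=dict)  # name -> RingSpec
    trivial_rotors: dict = field(default_factory=dict)  # name -> (a, b, c, d)
    equivalence_groups: dict = field(default_factory=dict)
    prochiral_pairs: dict = field(default_factory=dict)
    min_contact: float = 2.4
    contact_overrides: dict = field(default_factory=dict)  # frozenset({el,el}) -> A
    bond_spread: float = 0.02  # reference spread for bonds (A)
    angle_spread: float = 2.0  # reference spread for angles (deg)
    name: str = "molecule"

    # -- derived, cached ---------------------------------------------------
    def __post_init__(self):
        self._index = {a.name: i for i, a in enumerate(self.atoms)}
        if len(self._index) != len(self.atoms):
            raise ValidationError("duplicate atom names in template")
        self._cache = {}
        self.validate()

    def index(self, name):
        try:
            return self._index[name]
        except KeyError:
            raise InputError(f"unknown atom name: {name!r}") from None

    @property
    def atom_names(self):
        return [a.name for a in self.atoms]

    def element(self, name):
        return self.atoms[self.index(name)].element

    def validate(self):
        if self.min_contact <= 0:
            raise ValidationError("min_contact must be > 0")
        names = set(self._index)
        placed = set()
        for row in self.rows:
            if isinstance(row, ZRow):
                for ref in (row.parent, row.angle_ref, row.dihedral_ref):
                    if ref is not None and ref not in placed:
                        raise ValidationError(
                            f"row for {row.atom}: reference {ref} not yet placed"
                        )
                placed.add(row.atom)
            elif isinstance(row, BisectorRow):
                for ref in (row.center, row.ref1, row.ref2):
                    if ref not in placed:
                        raise ValidationError(
                            f"row for {row.atom}: reference {ref} not yet placed"
                        )
                placed.add(row.atom)
            elif isinstance(row, TripodRow):
                for ref in (row.center, *row.refs):
                    if ref not in placed:
                        raise ValidationError(
                            f"row for {row.atom}: reference {ref} not yet placed"
                        )
                placed.add(row.atom)
            else:  # pragma: no cover - defensive
                raise ValidationError(f"unknown row type {type(row)!r}")
        if placed != names:
            raise ValidationError("placement rows do not cover every atom exactly once")
        for tname, quad in {**self.rotatable_bonds, **self.trivial_rotors}.items():
            for a in quad:
                if a not in names:
                    raise ValidationError(f"torsion {tname}: unknown atom {a}")
        for ring in self.rings.values():
            for a in ring.path:
                if a not in names:
                    raise ValidationError(f"ring {ring.name}: unknown atom {a}")
        for g, members in self.equivalence_groups.items():
            for a in members:
                if a not in names:
                    raise ValidationError(f"equivalence group {g}: unknown atom {a}")
        for p, pair in self.prochiral_pairs.items():
            for a in pair:
                if a not in names:
                    raise ValidationError(f"prochiral pair {p}: unknown atom {a}")

    # -- connectivity ------------------------------------------------------
    def bonds(self):
        """List of bonded atom-name pairs implied by the placement rows."""
        if "bonds" in self._cache:
            return self._cache["bonds"]
        out = []
        for row in self.rows:
            if isinstance(row, ZRow):
                if row.parent is not None:
                    out.append((row.parent, row.atom))
            elif isinstance(row, BisectorRow):
                out.append((row.center, row.atom))
            else:
                out.append((row.center, row.atom))
        for ring in self.rings.values():
            out.append((ring.path[-1], ring.path[0]))
        self._cache["bonds"] = out
        return out

    def graph_distances(self, max_dist=3):
        """Pairwise bond-graph distances up to max_dist (BFS), as an array.

        Entries > max_dist are set to max_dist + 1.
        """
        key = ("gdist", max_dist)
        if key in self._cache:
            return self._cache[key]
        n = len(self.atoms)
        adj = [[] for _ in range(n)]
        for a, b in self.bonds():
            ia, ib = self.index(a), self.index(b)
            adj[ia].append(ib)
            adj[ib].append(ia)
        dist = np.full((n, n), max_dist + 1, dtype=np.int8)
        for s in range(n):
            dist[s, s] = 0
            frontier = [s]
            for d in range(1, max_dist + 1):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if dist[s, v] > d:
                            dist[s, v] = d
                            nxt.append(v)
                frontier = nxt
        self._cache[key] = dist
        return dist

    # -- serialization -----------------------------------------------------
    def to_json(self):
        def row_dict(row):
            if isinstance(row, ZRow):
                return {
                    "type": "z",
                    "atom": row.atom,
                    "parent": row.parent,
                    "angle_ref": row.angle_ref,
                    "dihedral_ref": row.dihedral_ref,
                    "length": row.length,
                    "angle": list(row.angle) if isinstance(row.angle, tuple) else row.angle,
                    "dihedral": list(row.dihedral),
                }
            if isinstance(row, BisectorRow):
                return {
                    "type": "bisector",
                    "atom": row.atom,
                    "center": row.center,
                    "ref1": row.ref1,
                    "ref2": row.ref2,
                    "length": row.length,
                    "side": row.side,
                    "target_angle": row.target_angle,
                }
            return {
                "type": "tripod",
                "atom": row.atom,
                "center": row.center,
                "refs": list(row.refs),
                "length": row.length,
            }

        return {
            "name": self.name,
            "atoms": [[a.name, a.element, a.residue] for a in self.atoms],
            "rows": [row_dict(r) for r in self.rows],
            "rotatable_bonds": {k: list(v) for k, v in self.rotatable_bonds.items()},
            "trivial_rotors": {k: list(v) for k, v in self.trivial_rotors.items()},
            "rings": {
                k: {
                    "path": list(r.path),
                    "default_state": r.default_state,
                    "states": {
                        s: {
                            "torsions": list(st.torsions),
                            "angles": list(st.angles),
                            "closure_length": st.closure_length,
                            "label": st.label,
                        }
                        for s, st in r.states.items()
                    },
                }
                for k, r in self.rings.items()
            },
            "equivalence_groups": {k: list(v) for k, v in self.equivalence_groups.items()},
            "prochiral_pairs": {k: list(v) for k, v in self.prochiral_pairs.items()},
            "min_contact": self.min_contact,
            "contact_overrides": [
                [sorted(k), v] for k, v in self.contact_overrides.items()
            ],
            "bond_spread": self.bond_spread,
            "angle_spread": self.angle_spread,
        }

    @classmethod
    def from_json(cls, data):
        def parse_row(d):
            if d["type"] == "z":
                ang = d["angle"]
                if isinstance(ang, list):
                    ang = tuple(ang)
                return ZRow(
                    d["atom"], d["parent"], d["angle_ref"], d["dihedral_ref"],
                    d["length"], ang, tuple(d["dihedral"]),
                )
            if d["type"] == "bisector":
                return BisectorRow(
                    d["atom"], d["center"], d["ref1"], d["ref2"], d["length"],
                    d["side"], d.get("target_angle", 109.47),
                )
            return TripodRow(d["atom"], d["center"], tuple(d["refs"]), d["length"])

        rings = {}
        for k, r in data.get("rings", {}).items():
            states = {
                s: RingState(
                    tuple(st["torsions"]), tuple(st["angles"]),
                    st["closure_length"], st.get("label", ""),
                )
                for s, st in r["states"].items()
            }
            rings[k] = RingSpec(k, tuple(r["path"]), states, r["default_state"])
        return cls(
            atoms=[Atom(*a) for a in data["atoms"]],
            rows=[parse_row(r) for r in data["rows"]],
            rotatable_bonds={k: tuple(v) for k, v in data["rotatable_bonds"].items()},
            rings=rings,
            trivial_rotors={k: tuple(v) for k, v in data.get("trivial_rotors", {}).items()},
            equivalence_groups={
                k: list(v) for k, v in data.get("equivalence_groups", {}).items()
            },
            prochiral_pairs={
                k: tuple(v) for k, v in data.get("prochiral_pairs", {}).items()
            },
            min_contact=data.get("min_contact", 2.4),
            contact_overrides={
                frozenset(k): v for k, v in data.get("contact_overrides", [])
            },
            bond_spread=data.get("bond_spread", 0.02),
            angle_spread=data.get("angle_spread", 2.0),
            name=data.get("name", "molecule"),
        )

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path):
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


@dataclass
class CartesianConformer:
    """One built 3D structure with the torsion/pucker assignment it realizes."""

    template: MoleculeTemplate
    coordinates: np.ndarray  # (natoms, 3) A
    torsion_values: dict  # torsion name -> deg
    pucker_values: dict  # ring name -> state name

    def coords_of(self, name):
        return self.coordinates[self.template.index(name)]


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _cross(a, b):
    """Cross product over the last axis without np.cross overhead."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _norml(v):
    return v / np.sqrt(np.einsum("...k,...k->...k1", v, v)[..., 0])


def _fast_unit(v):
    n = np.sqrt(v[..., 0] ** 2 + v[..., 1] ** 2 + v[..., 2] ** 2)
    return v / n[..., None]


def _compile_template(template):
    """Integer-indexed placement program for fast batch construction."""
    idx = template.index
    ring_names = list(template.rings)
    ring_tor = {}
    ring_ang = {}
    for rname, ring in template.rings.items():
        ring_tor[rname] = np.array([st.torsions for st in ring.states.values()])
        ring_ang[rname] = np.array([st.angles for st in ring.states.values()])
    ops = []
    for row in template.rows:
        i = idx(row.atom)
        if isinstance(row, ZRow):
            if row.parent is None:
                ops.append(("origin", i))
            elif row.angle_ref is None:
                ops.append(("bond", i, idx(row.parent), row.length))
            elif row.dihedral_ref is None:
                ops.append(
                    ("angle3", i, idx(row.parent), idx(row.angle_ref), row.length,
                     row.angle)
                )
            else:
                ops.append(
                    ("place", i, idx(row.dihedral_ref), idx(row.angle_ref),
                     idx(row.parent), row.length, row.angle, row.dihedral, row.atom)
                )
        elif isinstance(row, BisectorRow):
            cos_t = math.cos(math.radians(row.target_angle))
            ops.append(
                ("bis", i, idx(row.center), idx(row.ref1), idx(row.ref2),
                 row.length, float(row.side), cos_t)
            )
        else:
            ops.append(("tripod", i, idx(row.center),
                        tuple(idx(r) for r in row.refs), row.length))
    return {"ops": ops, "ring_tor": ring_tor, "ring_ang": ring_ang}


def _resolve_angle(spec, template, ring_state_idx, n):
    if isinstance(spec, tuple) and spec[0] == "ring":
        _, ring, pos = spec
        table = np.array(
            [template.rings[ring].states[s].angles[pos] for s in template.rings[ring].states]
        )
        return table[ring_state_idx[ring]]
    return np.full(n, float(spec))


def build_ensemble_coords(template, torsions, ring_states=None):
    """Vectorized conformer construction.

    Parameters
    ----------
    torsions : mapping of torsion name -> array (n,) or scalar, degrees.
        Must cover every rotatable bond; trivial rotors default to 180.
    ring_states : mapping of ring name -> state-name, or array (n,) of state
        indices into the ring's ordered state list.  Defaults to each ring's
        default state.

    Returns
    -------
    coords : (n, natoms, 3) array, plus the per-atom realized dihedral cache.
    """
    n = 1
    tvals = {}
    for tname in list(template.rotatable_bonds) + list(template.trivial_rotors):
        if tname in (torsions or {}):
            v = np.atleast_1d(np.asarray(torsions[tname], dtype=float))
        elif tname in template.trivial_rotors:
            v = np.array([180.0])
        else:
            raise InputError(f"no value supplied for rotatable bond {tname!r}")
        if not np.all(np.isfinite(v)):
            raise InputError(f"non-finite angle for torsion {tname!r}")
        tvals[tname] = wrap_angle(v)
        n = max(n, v.shape[0])
    for tname in torsions or {}:
        if tname not in tvals:
            raise InputError(f"unknown torsion or ring name: {tname!r}")
    if ring_states:
        for spec in ring_states.values():
            if spec is not None and not isinstance(spec, str):
                n = max(n, np.atleast_1d(np.asarray(spec)).shape[0])
    for tname, v in tvals.items():
        if v.shape[0] == 1 and n > 1:
            tvals[tname] = np.repeat(v, n)
        elif v.shape[0] not in (1, n):
            raise InputError("inconsistent torsion array lengths")

    ring_idx = {}
    for rname, ring in template.rings.items():
        spec = None if ring_states is None else ring_states.get(rname)
        if spec is None:
            spec = ring.default_state
        if isinstance(spec, str):
            if spec not in ring.states:
                raise InputError(f"unknown pucker state {spec!r} for ring {rname!r}")
            ring_idx[rname] = np.full(n, list(ring.states).index(spec), dtype=int)
        else:
            arr = np.atleast_1d(np.asarray(spec, dtype=int))
            ring_idx[rname] = np.repeat(arr, n) if arr.shape[0] == 1 and n > 1 else arr
    if ring_states:
        for rname in ring_states:
            if rname not in template.rings:
                raise InputError(f"unknown ring name: {rname!r}")

    from . import _fastbuild

    if _fastbuild.HAVE_NUMBA:
        fprog = template._cache.get("fastprog")
        if fprog is None:
            fprog = _fastbuild.encode_program(template)
            template._cache["fastprog"] = fprog
        torvals = np.empty((n, len(fprog["tor_names"])))
        for kk, tname in enumerate(fprog["tor_names"]):
            torvals[:, kk] = tvals[tname]
        nrings = max(len(fprog["ring_names"]), 1)
        ridx = np.zeros((nrings, n), dtype=np.int64)
        for kk, rname in enumerate(fprog["ring_names"]):
            ridx[kk] = ring_idx[rname]
        coords = _fastbuild.run_program(fprog, torvals, ridx, n, len(template.atoms))
        return coords, ring_idx

    prog = template._cache.get("compiled")
    if prog is None:
        prog = _compile_template(template)
        template._cache["compiled"] = prog
    ring_tor_tables = prog["ring_tor"]
    ring_ang_tables = prog["ring_ang"]

    na = len(template.atoms)
    coords = np.zeros((n, na, 3))
    placed_dihedral = {}  # atom -> realized dihedral array (for "relative" specs)
    deg = math.pi / 180.0

    for op in prog["ops"]:
        kind0 = op[0]
        if kind0 == "place":
            _, i, ia, ib, ic, L, angspec, dihspec, aname = op
            a = coords[:, ia]
            b = coords[:, ib]
            c = coords[:, ic]
            if isinstance(angspec, tuple):
                _, rname, pos = angspec
                ang = ring_ang_tables[rname][ring_idx[rname], pos]
            else:
                ang = float(angspec)
            dkind = dihspec[0]
            if dkind == "fixed":
                tor = float(dihspec[1])
            elif dkind == "torsion":
                _, tname, off = dihspec
                if tname not in tvals:
                    raise InputError(f"row {aname}: unknown torsion {tname!r}")
                tor = tvals[tname] + off
            elif dkind == "ring":
                _, rname, slot = dihspec
                tor = ring_tor_tables[rname][ring_idx[rname], slot]
            else:  # relative
                _, other, off = dihspec
                if other not in placed_dihedral:
                    raise ValidationError(
                        f"row {aname}: relative reference {other!r} has no dihedral"
                    )
                tor = placed_dihedral[other] + off
            placed_dihedral[aname] = tor
            theta = np.asarray(ang) * deg
            phi = np.asarray(tor) * deg
            bc = _fast_unit(c - b)
            nvec = _cross(b - a, bc)
            nvec = _fast_unit(nvec)
            m = _cross(nvec, bc)
            st = np.sin(theta)
            ct = np.cos(theta)
            if np.ndim(theta):
                ct = ct[:, None]
                st_ = st[:, None]
            else:
                st_ = st
            cp = np.cos(phi)
            sp = np.sin(phi)
            if np.ndim(phi):
                cp = cp[:, None]
                sp = sp[:, None]
            coords[:, i] = c + L * (-bc * ct + m * (st_ * cp) + nvec * (st_ * sp))
        elif kind0 == "bis":
            _, i, ic, i1, i2, L, side, cos_t = op
            cc = coords[:, ic]
            u1 = _fast_unit(coords[:, i1] - cc)
            u2 = _fast_unit(coords[:, i2] - cc)
            bis = _fast_unit(-(u1 + u2))
            nrm = _fast_unit(_cross(u1, u2))
            cos_a = np.clip(np.einsum("nk,nk->n", u1, u2), -1.0, 1.0)
            alpha = 0.5 * np.arccos(cos_a)
            cw = np.clip(-cos_t / np.cos(alpha), -1.0, 1.0)
            w = np.arccos(cw)
            coords[:, i] = cc + L * (
                bis * np.cos(w)[:, None] + side * nrm * np.sin(w)[:, None]
            )
        elif kind0 == "tripod":
            _, i, ic, refs, L = op
            cc = coords[:, ic]
            s = _fast_unit(coords[:, refs[0]] - cc)
            s = s + _fast_unit(coords[:, refs[1]] - cc)
            s = s + _fast_unit(coords[:, refs[2]] - cc)
            coords[:, i] = cc - L * _fast_unit(s)
        elif kind0 == "bond":
            _, i, ip, L = op
            coords[:, i] = coords[:, ip] + np.array([L, 0.0, 0.0])
        elif kind0 == "angle3":
            _, i, ip, ib, L, angspec = op
            c = coords[:, ip]
            b = coords[:, ib]
            if isinstance(angspec, tuple):
                _, rname, pos = angspec
                ang = ring_ang_tables[rname][ring_idx[rname], pos]
            else:
                ang = np.full(n, float(angspec))
            u = _fast_unit(b - c)
            th = np.asarray(ang) * deg
            rot = np.stack(
                [
                    u[:, 0] * np.cos(th) - u[:, 1] * np.sin(th),
                    u[:, 0] * np.sin(th) + u[:, 1] * np.cos(th),
                    np.zeros(n),
                ],
                axis=-1,
            )
            coords[:, i] = c + L * rot
        # "origin": coordinates stay at zero

    return coords, ring_idx


def build_conformer(template, torsions, puckers=None):
    """Build a single conformer; see :func:`build_ensemble_coords`.

    Ring-closure residuals beyond 0.05 A raise :class:`GeometryError` naming
    the ring.
    """
    coords, ring_idx = build_ensemble_coords(template, torsions, puckers)
    coords = coords[0]
    pucker_values = {}
    for rname, ring in template.rings.items():
        sname = list(ring.states)[int(ring_idx[rname][0])]
        st = ring.states[sname]
        i0 = template.index(ring.path[0])
        i1 = template.index(ring.path[-1])
        closure = float(np.linalg.norm(coords[i0] - coords[i1]))
        if abs(closure - st.closure_length) > 0.05:
            raise GeometryError(
                f"ring {rname!r} failed to close: bond {ring.path[-1]}-{ring.path[0]} "
                f"= {closure:.3f} A, expected {st.closure_length:.3f} A"
            )
        pucker_values[rname] = sname
    torsion_values = {}
    for tname in template.rotatable_bonds:
        v = torsions[tname]
        torsion_values[tname] = float(wrap_angle(np.atleast_1d(v)[0]))
    conf = CartesianConformer(template, coords, torsion_values, pucker_values)
    return conf


def measure_dihedral(conformer, a, b, c, d):
    """Dihedral angle a-b-c-d (deg) in (-180, 180], IUPAC sign convention."""
    names = (a, b, c, d)
    if len(set(names)) != 4:
        raise InputError("dihedral requires four distinct atoms")
    pts = [conformer.coords_of(x) for x in names]
    return float(dihedral_from_coords(*pts))


def contact_threshold(template, el_i, el_j, min_dist=None):
    """Minimum allowed heavy-atom contact distance for an element pair."""
    if min_dist is not None:
        return min_dist
    return template.contact_overrides.get(frozenset((el_i, el_j)), template.min_contact)


def _heavy_pairs(template, min_dist=None):
    """Index arrays (i, j, threshold) of testable non-bonded heavy-atom pairs."""
    key = ("heavy_pairs", min_dist)
    if key in template._cache:
        return template._cache[key]
    gd = template.graph_distances(max_dist=2)
    heavy = [i for i, a in enumerate(template.atoms) if a.element != "H"]
    ii, jj, thr = [], [], []
    for x, i in enumerate(heavy):
        for j in heavy[x + 1 :]:
            if gd[i, j] <= 2:
                continue  # 1-2 and 1-3 pairs are never tested
            ii.append(i)
            jj.append(j)
            thr.append(
                contact_threshold(
                    template, template.atoms[i].element, template.atoms[j].element, min_dist
                )
            )
    out = (np.array(ii, dtype=int), np.array(jj, dtype=int), np.array(thr))
    template._cache[key] = out
    return out


def detect_clashes(conformer, min_dist=None):
    """Non-bonded heavy-atom pairs closer than the allowed contact distance.

    Pairs separated by fewer than 3 bonds are excluded.  Returns a list of
    ((name_i, name_j), distance) sorted by distance.
    """
    t = conformer.template
    ii, jj, thr = _heavy_pairs(t, min_dist)
    if ii.size == 0:
        return []
    d = np.linalg.norm(conformer.coordinates[ii] - conformer.coordinates[jj], axis=-1)
    mask = d < thr
    names = t.atom_names
    hits = sorted(
        ((float(x), names[a], names[b]) for a, b, x in zip(ii[mask], jj[mask], d[mask])),
    )
    return [((a, b), x) for x, a, b in hits]


def clash_mask(template, coords, min_dist=None):
    """Boolean (n,) mask of conformers containing at least one clash."""
    ii, jj, thr = _heavy_pairs(template, min_dist)
    if ii.size == 0:
        return np.zeros(coords.shape[0], dtype=bool)
    d = np.linalg.norm(coords[:, ii] - coords[:, jj], axis=-1)
    return np.any(d < thr[None, :], axis=1)


def geometry_report(conformer, template=None, z_threshold=3.0):
    """Z-score check of every bond length and placement angle.

    Z = |observed - reference| / reference_spread; features with Z strictly
    greater than ``z_threshold`` are flagged.  Returns a pandas DataFrame.
    """
    import pandas as pd

    t = template or conformer.template
    if t.bond_spread <= 0 or t.angle_spread <= 0:
        raise ConfigurationError("reference spreads must be positive")
    X = conformer.coordinates
    recs = []

    eps = 1e-9  # strict ">" robust to float round-off

    def bond_rec(a, b, ref):
        d = float(np.linalg.norm(X[t.index(a)] - X[t.index(b)]))
        z = abs(d - ref) / t.bond_spread
        recs.append(("bond", f"{a}-{b}", d, ref, t.bond_spread, z, z > z_threshold + eps))

    def angle_rec(a, b, c, ref):
        obs = float(angle_from_coords(X[t.index(a)], X[t.index(b)], X[t.index(c)]))
        z = abs(obs - ref) / t.angle_spread
        recs.append(
            ("angle", f"{a}-{b}-{c}", obs, ref, t.angle_spread, z, z > z_threshold + eps)
        )

    state_of = {r: conformer.pucker_values.get(r) for r in t.rings}
    for row in t.rows:
        if isinstance(row, ZRow):
            if row.parent is None:
                continue
            bond_rec(row.parent, row.atom, row.length)
            if row.angle_ref is not None:
                if isinstance(row.angle, tuple):
                    _, rname, pos = row.angle
                    ref = t.rings[rname].states[state_of[rname]].angles[pos]
                else:
                    ref = float(row.angle)
                angle_rec(row.angle_ref, row.parent, row.atom, ref)
        elif isinstance(row, BisectorRow):
            bond_rec(row.center, row.atom, row.length)
            angle_rec(row.ref1, row.center, row.atom, row.target_angle)
        else:
            bond_rec(row.center, row.atom, row.length)
    for rname, ring in t.rings.items():
        st = ring.states[state_of[rname]]
        bond_rec(ring.path[-1], ring.path[0], st.closure_length)
        angle_rec(ring.path[-2], ring.path[-1], ring.path[0], st.angles[-1])
        angle_rec(ring.path[-1], ring.path[0], ring.path[1], st.angles[0])
    return pd.DataFrame(
        recs, columns=["feature", "atoms", "observed", "reference", "spread", "z", "flagged"]
    )


# ---------------------------------------------------------------------------
# Ring pucker state solving
# ---------------------------------------------------------------------------

def solve_ring_state(
    lengths,
    ideal_angles,
    target_torsions,
    entry_index=None,
    label="",
    closure_tol=1e-4,
):
    """Find a closed ring geometry near the requested canonical pucker.

    Parameters
    ----------
    lengths : (N,) bond lengths; lengths[j] is the bond path[j]-path[j+1]
        (cyclic, so lengths[-1] is the closing bond).
    ideal_angles : (N,) ideal internal angle at each path atom.
    target_torsions : (N,) target endocyclic torsions nu_j about bond j.
    entry_index : path position whose internal angle is held fixed at its
        ideal value (the ring-entry atom of a glycosidic attachment), or None.

    Bond lengths are held exactly; placement angles and free torsions are
    adjusted by least squares so that the ring closes (hard) while staying
    near the ideal angles and the canonical torsion pattern (soft).
    """
    from scipy.optimize import least_squares

    N = len(lengths)
    lengths = np.asarray(lengths, float)
    ideal_angles = np.asarray(ideal_angles, float)
    target_torsions = wrap_angle(np.asarray(target_torsions, float))

    free_angle_pos = [i for i in range(1, N - 1) if i != entry_index]
    n_free_tor = N - 3

    def chain(x):
        angles = ideal_angles.copy()
        angles[free_angle_pos] = x[: len(free_angle_pos)]
        tors = x[len(free_angle_pos) :]
        p = np.zeros((N, 3))
        p[1] = [lengths[0], 0.0, 0.0]
        th = math.radians(angles[1])
        p[2] = p[1] + lengths[1] * np.array([-math.cos(th), math.sin(th), 0.0])
        for k in range(3, N):
            p[k] = _nerf_place(
                p[k - 3][None], p[k - 2][None], p[k - 1][None],
                lengths[k - 1], np.array([angles[k - 1]]), np.array([tors[k - 3]]),
            )[0]
        return p, angles

    def residuals(x):
        p, angles = chain(x)
        r = []
        closure = np.linalg.norm(p[N - 1] - p[0])
        r.append(200.0 * (closure - lengths[N - 1]))
        r.append(2.0 * (float(angle_from_coords(p[N - 2], p[N - 1], p[0])) - ideal_angles[N - 1]) / 57.3)
        r.append(2.0 * (float(angle_from_coords(p[N - 1], p[0], p[1])) - ideal_angles[0]) / 57.3)
        for j in range(N):
            nu = float(
                dihedral_from_coords(
                    p[j % N], p[(j + 1) % N], p[(j + 2) % N], p[(j + 3) % N]
                )
            )
            # nu about bond (j+1, j+2); compare to target at that bond
            r.append(0.010 * wrap_angle(nu - target_torsions[(j + 1) % N]))
        for pos, a in zip(free_angle_pos, x[: len(free_angle_pos)]):
            r.append(0.004 * (a - ideal_angles[pos]))
        return np.array(r)

    x0 = np.concatenate(
        [ideal_angles[free_angle_pos], target_torsions[1 : 1 + n_free_tor]]
    )
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    p, angles = chain(sol.x)
    closure = float(np.linalg.norm(p[N - 1] - p[0]))
    if abs(closure - lengths[N - 1]) > closure_tol:
        raise GeometryError(
            f"ring closure failed for pucker {label!r}: "
            f"closing bond {closure:.4f} vs {lengths[N - 1]:.4f} A"
        )
    achieved_tor = []
    for b in range(N):
        j = (b - 1) % N
        nu = float(
            dihedral_from_coords(p[j], p[(j + 1) % N], p[(j + 2) % N], p[(j + 3) % N])
        )
        achieved_tor.append(nu)
    achieved_ang = []
    for i in range(N):
        achieved_ang.append(
            float(angle_from_coords(p[(i - 1) % N], p[i], p[(i + 1) % N]))
        )
    return RingState(
        torsions=tuple(achieved_tor),
        angles=tuple(achieved_ang),
        closure_length=float(lengths[N - 1]),
        label=label,
    )


# ---------------------------------------------------------------------------
# PDB I/O (multi-model, via gemmi)
# ---------------------------------------------------------------------------

def write_pdb(path, template, coords, occupancies=None):
    """Write conformers as a multi-model PDB file.

    ``coords`` is (nmodels, natoms, 3); ``occupancies`` an optional (nmodels,)
    array recorded in the occupancy column (used for macrostate files).
    """
    import gemmi

    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    st = gemmi.Structure()
    st.name = template.name
    name_map = pdb_name_map(template)
    residues = []
    for a in template.atoms:
        if a.residue not in residues:
            residues.append(a.residue)
    for m, xyz in enumerate(coords):
        model = gemmi.Model(m + 1)
        chain = gemmi.Chain("A")
        res_objs = {}
        for r, rname in enumerate(residues):
            res = gemmi.Residue()
            res.name = rname[:3]
            res.seqid = gemmi.SeqId(r + 1, " ")
            res_objs[rname] = res
        for i, a in enumerate(template.atoms):
            at = gemmi.Atom()
            at.name = name_map[a.name][1]
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*xyz[i])
            at.occ = float(occupancies[m]) if occupancies is not None else 1.0
            at.b_iso = 0.0
            res_objs[a.residue].add_atom(at)
        for rname in residues:
            chain.add_residue(res_objs[rname])
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)


def pdb_name_map(template):
    """Deterministic unique PDB atom names (<= 4 chars) per template atom."""
    used = set()
    out = {}
    for a in template.atoms:
        short = a.name
        if short.startswith(a.residue + "_"):
            short = short[len(a.residue) + 1 :]
        short = short.replace("p", "'")
        if len(short) > 4:
            short = short[0] + short[2:]  # e.g. HN111 -> H111
        short = short[:4]
        key = (a.residue[:3], short)
        k = 0
        while key in used:
            k += 1
            short = f"X{k:03d}"
            key = (a.residue[:3], short)
        used.add(key)
        out[a.name] = (a.residue[:3], short)
    return out


def read_pdb_coords(path, template):
    """Read a multi-model PDB written by :func:`write_pdb` back to (n, na, 3)."""
    import gemmi

    st = gemmi.read_pdb(str(path))
    name_map = pdb_name_map(template)
    lookup = {name_map[a.name]: i for i, a in enumerate(template.atoms)}
    out = np.full((len(st), len(template.atoms), 3), np.nan)
    for m, model in enumerate(st):
        for chain in model:
            for res in chain:
                for at in res:
                    key = (res.name, at.name)
                    if key in lookup:
                        out[m, lookup[key]] = [at.pos.x, at.pos.y, at.pos.z]
    if np.any(np.isnan(out)):
        raise InputError("PDB file does not cover every template atom")
    return out
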