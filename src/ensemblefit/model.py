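"""Per-bond torsional macrostate models and microstate ensemble sampling.

A rotatable bond is described by one to three *macrostates*, each a mean
torsion angle mu (deg), a libration spread sigma (deg) and an occupancy pi.
Bonds (and rings) may be tied into *coupling groups*: all members of a group
share one occupancy vector and select the same macrostate index in every
draw, while each member keeps its own per-index mu and sigma.  Sampling a
whole-molecule microstate selects an index per independent unit and draws
each torsion from a wrapped normal about the selected mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError, ValidationError
from .geometry import build_ensemble_coords, wrap_angle

__all__ = [
    "Macrostate",
    "BondModel",
    "RingModel",
    "DynamicModel",
    "ConformerEnsemble",
    "sample_ensemble",
    "enumerate_macrostates",
    "cluster_families",
    "circular_mean",
    "circular_std",
    "circular_distance",
]

_PI_TOL = 1e-9
MAX_ENUMERATION = 10**6


def circular_mean(angles_deg, axis=None):
    a = np.radians(np.asarray(angles_deg, float))
    return wrap_angle(
        np.degrees(np.arctan2(np.mean(np.sin(a), axis=axis), np.mean(np.cos(a), axis=axis)))
    )


def circular_std(angles_deg, axis=None):
    """Circular standard deviation in degrees, sqrt(-2 ln R)."""
    a = np.radians(np.asarray(angles_deg, float))
    R = np.hypot(np.mean(np.sin(a), axis=axis), np.mean(np.cos(a), axis=axis))
    R = np.clip(R, 1e-12, 1.0)
    return np.degrees(np.sqrt(-2.0 * np.log(R)))


def circular_distance(a, b):
    """Absolute circular distance in degrees, in [0, 180]."""
    return np.abs(wrap_angle(np.asarray(a, float) - np.asarray(b, float)))


@dataclass
class Macrostate:
    pi: float
    mu: float
    sigma: float
    fixed_mu: bool = False

    def validate(self):
        # tolerate float round-off from simplex arithmetic
        if -1e-9 < self.pi < 0.0:
            self.pi = 0.0
        elif 1.0 < self.pi < 1.0 + 1e-9:
            self.pi = 1.0
        if not (0.0 <= self.pi <= 1.0):
            raise ValidationError(f"occupancy pi={self.pi} outside [0, 1]")
        if self.sigma < 0:
            raise ValidationError(f"negative spread sigma={self.sigma}")
        self.mu = float(wrap_angle(self.mu))


@dataclass
class BondModel:
    torsion: str
    macrostates: list
    coupling_group: str | None = None

    @property
    def n_modes(self):
        return len(self.macrostates)

    def validate(self):
        if not 1 <= self.n_modes <= 3:
            raise ValidationError(
                f"bond {self.torsion}: {self.n_modes} macrostates (must be 1-3)"
            )
        for m in self.macrostates:
            m.validate()
        total = sum(m.pi for m in self.macrostates)
        if abs(total - 1.0) > _PI_TOL:
            raise ValidationError(
                f"bond {self.torsion}: occupancies sum to {total!r}, not 1 "
                "(no silent renormalization)"
            )

    @property
    def pis(self):
        return np.array([m.pi for m in self.macrostates])

    @property
    def mus(self):
        return np.array([m.mu for m in self.macrostates])

    @property
    def sigmas(self):
        return np.array([m.sigma for m in self.macrostates])


@dataclass
class RingModel:
    ring: str
    states: list  # pucker state names
    probs: list
    coupling_group: str | None = None

    @property
    def n_modes(self):
        return len(self.states)

    def validate(self):
        if len(self.states) != len(self.probs) or not self.states:
            raise ValidationError(f"ring {self.ring}: states/probs mismatch")
        if abs(sum(self.probs) - 1.0) > _PI_TOL:
            raise ValidationError(f"ring {self.ring}: probabilities do not sum to 1")


@dataclass
class DynamicModel:
    """One :class:`BondModel` per rotatable bond plus per-ring pucker models."""

    bonds: dict  # torsion name -> BondModel
    rings: dict = field(default_factory=dict)  # ring name -> RingModel

    def validate(self, template=None):
        for name, bm in self.bonds.items():
            if bm.torsion != name:
                raise ValidationError(f"bond model key {name!r} != torsion {bm.torsion!r}")
            bm.validate()
        for name, rm in self.rings.items():
            rm.validate()
        for gid, members in self.coupling_groups().items():
            counts = {m.n_modes for m in members}
            if len(counts) != 1:
                raise ValidationError(
                    f"coupling group {gid!r}: members have unequal macrostate counts"
                )
            ref = self._member_pis(members[0])
            for m in members[1:]:
                if np.max(np.abs(self._member_pis(m) - ref)) > 1e-6:
                    raise ValidationError(
                        f"coupling group {gid!r}: members carry different occupancies"
                    )
        if template is not None:
            missing = set(template.rotatable_bonds) - set(self.bonds)
            extra = set(self.bonds) - set(template.rotatable_bonds)
            if missing or extra:
                raise ValidationError(
                    f"bond models do not match template torsions "
                    f"(missing={sorted(missing)}, extra={sorted(extra)})"
                )
            for rname, rm in self.rings.items():
                if rname not in template.rings:
                    raise ValidationError(f"unknown ring {rname!r} in model")
                for s in rm.states:
                    if s not in template.rings[rname].states:
                        raise ValidationError(
                            f"ring {rname!r}: unknown pucker state {s!r}"
                        )

    @staticmethod
    def _member_pis(member):
        if isinstance(member, BondModel):
            return member.pis
        return np.asarray(member.probs, float)

    def coupling_groups(self):
        """Map group id -> list of member BondModel/RingModel objects."""
        groups = {}
        for bm in self.bonds.values():
            if bm.coupling_group:
                groups.setdefault(bm.coupling_group, []).append(bm)
        for rm in self.rings.values():
            if rm.coupling_group:
                groups.setdefault(rm.coupling_group, []).append(rm)
        return groups

    def units(self):
        """Independent selection units: (unit id, occupancies, members)."""
        out = []
        grouped = set()
        for gid, members in self.coupling_groups().items():
            out.append((gid, self._member_pis(members[0]), members))
            for m in members:
                grouped.add(id(m))
        for bm in self.bonds.values():
            if id(bm) not in grouped:
                out.append((bm.torsion, bm.pis, [bm]))
        for rm in self.rings.values():
            if id(rm) not in grouped:
                out.append((rm.ring, np.asarray(rm.probs, float), [rm]))
        return out

    def copy(self):
        return DynamicModel.from_json(self.to_json())

    # -- serialization -----------------------------------------------------
    def to_json(self):
        return {
            "bonds": {
                name: {
                    "macrostates": [
                        {"pi": m.pi, "mu": m.mu, "sigma": m.sigma, "fixed_mu": m.fixed_mu}
                        for m in bm.macrostates
                    ],
                    "coupling_group": bm.coupling_group,
                }
                for name, bm in self.bonds.items()
            },
            "rings": {
                name: {
                    "states": list(rm.states),
                    "probs": list(rm.probs),
                    "coupling_group": rm.coupling_group,
                }
                for name, rm in self.rings.items()
            },
        }

    @classmethod
    def from_json(cls, data):
        bonds = {
            name: BondModel(
                torsion=name,
                macrostates=[
                    Macrostate(m["pi"], m["mu"], m["sigma"], m.get("fixed_mu", False))
                    for m in b["macrostates"]
                ],
                coupling_group=b.get("coupling_group"),
            )
            for name, b in data["bonds"].items()
        }
        rings = {
            name: RingModel(
                ring=name,
                states=list(r["states"]),
                probs=list(r["probs"]),
                coupling_group=r.get("coupling_group"),
            )
            for name, r in data.get("rings", {}).items()
        }
        return cls(bonds=bonds, rings=rings)

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path):
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@dataclass
class DrawBase:
    """Pre-drawn random numbers reusable across model evaluations (CRN)."""

    n: int
    unit_u: dict  # unit id -> (n,) uniforms for macrostate selection
    bond_z: dict  # torsion name -> (n,) standard normals
    rotor_u: dict  # rotor name -> (n,) angles in [0, 360)


def make_draw_base(model, template, n, rng):
    """Draw the random-number base for ``n`` microstates."""
    unit_u = {uid: rng.random(n) for uid, _, _ in model.units()}
    bond_z = {name: rng.standard_normal(n) for name in model.bonds}
    rotor_u = {name: rng.random(n) * 360.0 for name in template.trivial_rotors}
    return DrawBase(n=n, unit_u=unit_u, bond_z=bond_z, rotor_u=rotor_u)


@dataclass
class ConformerEnsemble:
    """N whole-molecule microstates sampled from a DynamicModel."""

    template: object
    torsions: dict  # torsion/rotor name -> (n,) degrees
    ring_states: dict  # ring name -> (n,) state indices
    mode_indices: dict  # unit id -> (n,) selected macrostate indices
    _coords: np.ndarray | None = None

    @property
    def n(self):
        return next(iter(self.torsions.values())).shape[0]

    @property
    def coords(self):
        if self._coords is None:
            self._coords, _ = build_ensemble_coords(
                self.template, self.torsions, self.ring_states
            )
        return self._coords

    def assignments(self):
        """Iterate per-microstate torsion/pucker assignments (dicts)."""
        ring_names = {
            r: list(self.template.rings[r].states) for r in self.ring_states
        }
        for i in range(self.n):
            yield {
                "torsions": {k: float(v[i]) for k, v in self.torsions.items()},
                "puckers": {
                    r: ring_names[r][int(idx[i])] for r, idx in self.ring_states.items()
                },
                "mode_indices": {u: int(k[i]) for u, k in self.mode_indices.items()},
            }


def sample_ensemble(model, template, n=300, seed=None, rng=None, base=None):
    """Sample ``n`` microstates from the model.

    Macrostate index k is selected per independent unit with probability
    pi_k (jointly within a coupling group); each bond angle is then drawn
    from a wrapped normal about (mu_k, sigma_k).  Trivial rotors are sampled
    uniformly.  Deterministic given ``seed`` (or an explicit ``base``).
    """
    if n < 1:
        raise InputError("ensemble size must be >= 1")
    model.validate(template)
    if base is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        base = make_draw_base(model, template, n, rng)
    torsions = {}
    ring_states = {}
    mode_indices = {}
    for uid, pis, members in model.units():
        edges = np.cumsum(pis)
        k = np.searchsorted(edges, base.unit_u[uid], side="right")
        k = np.minimum(k, len(pis) - 1)
        mode_indices[uid] = k
        for m in members:
            if isinstance(m, BondModel):
                mus = m.mus[k]
                sigmas = m.sigmas[k]
                torsions[m.torsion] = wrap_angle(mus + sigmas * base.bond_z[m.torsion])
            else:
                state_idx = np.array(
                    [list(template.rings[m.ring].states).index(s) for s in m.states]
                )
                ring_states[m.ring] = state_idx[k]
    for rotor in template.trivial_rotors:
        torsions[rotor] = wrap_angle(base.rotor_u[rotor])
    for rname in template.rings:
        if rname not in ring_states:
            ring = template.rings[rname]
            ring_states[rname] = np.full(
                n, list(ring.states).index(ring.default_state), dtype=int
            )
    return ConformerEnsemble(template, torsions, ring_states, mode_indices)


# ---------------------------------------------------------------------------
# Macrostate enumeration and conformational families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MacrostateEntry:
    """One whole-molecule macrostate: per-unit mode indices + mean torsions."""

    mode_indices: tuple  # ((unit id, k), ...) in unit order
    torsions: tuple  # ((torsion name, mu), ...)
    puckers: tuple  # ((ring name, state name), ...)
    occupancy: float

    def mode_of(self, unit_id):
        return dict(self.mode_indices)[unit_id]


def enumerate_macrostates(model, template=None):
    """Cartesian product of macrostate indices over independent units.

    Trivial rotors are excluded (grouped); occupancy of each macrostate is
    the product of the selected pi values and the occupancies sum to 1.
    """
    if template is not None:
        model.validate(template)
    else:
        model.validate()
    units = model.units()
    sizes = [len(pis) for _, pis, _ in units]
    total = 1
    for s in sizes:
        total *= s
        if total > MAX_ENUMERATION:
            raise InputError(
                f"macrostate enumeration exceeds {MAX_ENUMERATION} states"
            )
    out = []
    grid = np.indices(sizes).reshape(len(sizes), -1).T if sizes else np.zeros((1, 0), int)
    for combo in grid:
        occ = 1.0
        tors = []
        pucks = []
        modes = []
        for (uid, pis, members), k in zip(units, combo):
            occ *= pis[k]
            modes.append((uid, int(k)))
            for m in members:
                if isinstance(m, BondModel):
                    tors.append((m.torsion, float(m.macrostates[k].mu)))
                else:
                    pucks.append((m.ring, m.states[k]))
        out.append(
            MacrostateEntry(
                mode_indices=tuple(modes),
                torsions=tuple(sorted(tors)),
                puckers=tuple(sorted(pucks)),
                occupancy=float(occ),
            )
        )
    return out


@dataclass(frozen=True)
class Family:
    family_id: tuple  # mode indices on the defining units
    members: tuple  # MacrostateEntry
    population: float


def cluster_families(macrostates, defining_bonds, model=None):
    """Group whole-molecule macrostates by the mode of the defining bonds.

    ``defining_bonds`` are torsion names; each must belong to some selection
    unit of the model that produced the macrostates.  Populations are the
    summed member occupancies and themselves sum to 1.
    """
    if not defining_bonds:
        raise InputError("defining_bonds must be non-empty")
    # map bond -> unit id using the first macrostate's bookkeeping
    if not macrostates:
        raise InputError("no macrostates to cluster")
    bond_to_unit = {}
    if model is not None:
        for uid, _, members in model.units():
            for m in members:
                if isinstance(m, BondModel):
                    bond_to_unit[m.torsion] = uid
    else:
        # units named after their bond, or resolvable as group ids
        unit_ids = {uid for uid, _ in macrostates[0].mode_indices}
        for b in defining_bonds:
            bond_to_unit[b] = b if b in unit_ids else None
    unit_key = []
    for b in defining_bonds:
        uid = bond_to_unit.get(b)
        if uid is None:
            raise InputError(f"defining bond {b!r} not found in the model's units")
        unit_key.append(uid)
    # deduplicate units (coupled bonds share one)
    seen = []
    for u in unit_key:
        if u not in seen:
            seen.append(u)
    buckets = {}
    for ms in macrostates:
        key = tuple(ms.mode_of(u) for u in seen)
        buckets.setdefault(key, []).append(ms)
    fams = [
        Family(family_id=key, members=tuple(v), population=sum(m.occupancy for m in v))
        for key, v in sorted(buckets.items())
    ]
    total = sum(f.population for f in fams)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"family populations sum to {total}, not 1")
    return sorted(fams, key=lambda f: -f.population)
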