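"""Built-in molecule templates and synthetic restraint generation.

Ships a streptomycin-like topology — streptidine (S1, a diguanidinated
cyclohexane), streptose (R2, a furanose carrying a hydrated gem-diol and a
methyl) and N-methyl-glucosamine (G3, a pyranose) joined by two glycosidic
linkages, giving nine named rotatable bonds and three saturated rings —
plus small toy molecules, the final fitted dynamic model of the study
system, and a generator that forward-simulates NOESY heights, <3J(HH)>
couplings and RDCs from any (template, model) pair with realistic
measurement noise.  Everything is generated in code; no downloads.

The template's internal geometry uses idealized sugar/guanidinium fragment
values with plausible stereochemistry; it is a synthetic stand-in suitable
for parameter-recovery experiments, not a crystallographic structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import InputError
from .geometry import (
    Atom,
    BisectorRow,
    MoleculeTemplate,
    RingSpec,
    TripodRow,
    ZRow,
    improper_offset,
    solve_ring_state,
)
from .model import BondModel, DynamicModel, Macrostate, RingModel, sample_ensemble
from .noe import SpinSystem, ensemble_r6, predict_noesy, relaxation_matrix
from .jcoupling import ensemble_j_many
from .rdc import alignment_tensors, predict_rdc
from .restraints import (
    DatasetSpec,
    JRestraint,
    KarplusSet,
    NOERestraint,
    RDCRestraint,
    RestraintSet,
    noe_error,
    nonoe_error,
)

__all__ = [
    "streptomycin_template",
    "ground_truth_model",
    "streptomycin_j_specs",
    "streptomycin_exchangeable_spins",
    "butane_template",
    "glycol_template",
    "ribose_template",
    "NoiseSpec",
    "simulate_restraints",
    "streptomycin_restraints",
    "default_karplus_sets",
    "FAMILY_BONDS",
]

# Bond lengths (A)
CC = 1.53
CO = 1.43
CO_ANOMERIC = 1.41
CN = 1.47
CN_SP2 = 1.33
CH = 1.09
NH = 1.01

FAMILY_BONDS = ("phi23", "psi23")  # linkage defining the conformational families


class _Builder:
    def __init__(self):
        self.atoms = []
        self.rows = []

    def z(self, name, el, res, parent=None, aref=None, dref=None, L=0.0, ang=0.0,
          dih=("fixed", 0.0)):
        self.atoms.append(Atom(name, el, res))
        self.rows.append(ZRow(name, parent, aref, dref, L, ang, dih))

    def bis(self, name, el, res, center, ref1, ref2, L, side, target=109.47):
        self.atoms.append(Atom(name, el, res))
        self.rows.append(BisectorRow(name, center, ref1, ref2, L, side, target))

    def tri(self, name, el, res, center, refs, L):
        self.atoms.append(Atom(name, el, res))
        self.rows.append(TripodRow(name, center, tuple(refs), L))


@lru_cache(maxsize=None)
def _chair_states_cached(lengths, angles, entry_index):
    base = np.array([56.0, -56.0, 56.0, -56.0, 56.0, -56.0])
    return {
        "4C1": solve_ring_state(lengths, angles, base, entry_index, label="4C1"),
        "1C4": solve_ring_state(lengths, angles, -base, entry_index, label="1C4"),
    }


def _chair_states(lengths, angles, entry_index=None):
    """The two chair states of a six-membered ring."""
    return _chair_states_cached(tuple(lengths), tuple(angles), entry_index)


def _furanose_states(lengths, angles, entry_index=None, amplitude=38.0, step=18):
    """Canonical pseudorotation grid at fixed amplitude.

    nu_j = amplitude * cos(P + 144 deg * j) about bond (path_j, path_j+1);
    states are named by phase, P000 ... P342.
    """
    return _furanose_states_cached(tuple(lengths), tuple(angles), entry_index,
                                   amplitude, step)


@lru_cache(maxsize=None)
def _furanose_states_cached(lengths, angles, entry_index, amplitude, step):
    states = {}
    for p in range(0, 360, step):
        tors = amplitude * np.cos(np.radians(p + 144.0 * np.arange(5)))
        states[f"P{p:03d}"] = solve_ring_state(
            lengths, angles, tors, entry_index, label=f"P{p:03d}"
        )
    return states


@lru_cache(maxsize=1)
def streptomycin_template():
    """Streptomycin-like topology with the nine rotatable bonds of the
    S1-R2-G3 trisaccharide (phi/psi of both glycosidic linkages plus five
    exocyclic torsions) and three saturated rings."""
    return _build_streptomycin()


def _build_streptomycin(r2_anomeric=-1, g3_anomeric=+1, s1_o4_side=+1, r2_o2_side=+1,
                        g3_n2_side=-1, gemdiol_swap=False, r2_c3p_side=-1, r2_c5_side=+1, coc23=117.0, n2_target=115.0,
                        r2_o2_target=114.0, c2p_ang=115.0, o2_c1_c2=113.0, o2_c1_o5=112.0):
    # The sign arguments select stereocenter faces at the two anomeric
    # carbons and the glycosidic attachment points; the defaults are the
    # fixture's documented stereochemistry.
    b = _Builder()

    # ---- S1 streptidine ring (cyclohexane chair) -------------------------
    b.z("S1_C1", "C", "S1")
    b.z("S1_C2", "C", "S1", parent="S1_C1", L=CC)
    b.z("S1_C3", "C", "S1", parent="S1_C2", aref="S1_C1", L=CC,
        ang=("ring", "S1ring", 1))
    for i, (slot,) in zip(range(4, 7), [(1,), (2,), (3,)]):
        b.z(f"S1_C{i}", "C", "S1", parent=f"S1_C{i-1}", aref=f"S1_C{i-2}",
            dref=f"S1_C{i-3}", L=CC, ang=("ring", "S1ring", i - 1),
            dih=("ring", "S1ring", i - 3))

    ringS1 = [f"S1_C{i}" for i in range(1, 7)]

    def neigh(i):
        return ringS1[(i - 2) % 6], ringS1[i % 6]

    # heavy substituents: guanidinium N at C1/C3, hydroxyls at C2/C5/C6,
    # glycosidic O4 at C4; H on the opposite face
    heavy = {
        1: ("S1_N1", "N", CN, -1),
        2: ("S1_O2", "O", CO, +1),
        3: ("S1_N3", "N", CN, -1),
        4: ("S1_O4", "O", CO_ANOMERIC, s1_o4_side),
        5: ("S1_O5", "O", CO, -1),
        6: ("S1_O6", "O", CO, +1),
    }
    for i, (name, el, L, side) in heavy.items():
        r1, r2 = neigh(i)
        b.bis(name, el, "S1", f"S1_C{i}", r1, r2, L, side)
        b.bis(f"S1_H{i}", "H", "S1", f"S1_C{i}", r1, r2, CH, -side)

    def guanidinium(n_at, c_at, torsion, aref, dref):
        """Planar guanidinium group on ring nitrogen ``n_at``."""
        cp = c_at  # e.g. S1_C1p
        b.z(cp, "C", "S1", parent=n_at, aref=aref, dref=dref, L=CN_SP2, ang=123.0,
            dih=("torsion", torsion, 0.0))
        b.z("S1_H" + n_at.split("_")[1], "H", "S1", parent=n_at, aref=aref,
            dref=dref, L=NH, ang=117.0, dih=("torsion", torsion, 180.0))
        for tag, dih0 in (("1", 0.0), ("2", 180.0)):
            nn = n_at + tag  # S1_N11, S1_N12
            b.z(nn, "N", "S1", parent=cp, aref=n_at, dref=aref, L=CN_SP2,
                ang=120.0, dih=("fixed", dih0))
            for htag, hd in (("1", 180.0), ("2", 0.0)):
                b.z("S1_H" + nn.split("_")[1] + htag, "H", "S1", parent=nn,
                    aref=cp, dref=n_at, L=NH, ang=120.0, dih=("fixed", hd))

    guanidinium("S1_N1", "S1_C1p", "chi1_S1", "S1_C1", "S1_C6")
    guanidinium("S1_N3", "S1_C3p", "chi3_S1", "S1_C3", "S1_C2")

    # ---- R2 streptose (furanose), entered through the S1-R2 linkage ------
    b.z("R2_C1", "C", "R2", parent="S1_O4", aref="S1_C4", dref="S1_C3",
        L=CO_ANOMERIC, ang=114.0, dih=("torsion", "psi12", 0.0))
    b.z("R2_O4", "O", "R2", parent="R2_C1", aref="S1_O4", dref="S1_C4",
        L=CO_ANOMERIC, ang=108.0, dih=("torsion", "phi12", 0.0))
    off_r2 = improper_offset(108.0, 109.5, 104.0)
    b.z("R2_C2", "C", "R2", parent="R2_C1", aref="S1_O4", dref="S1_C4",
        L=CC, ang=109.5, dih=("relative", "R2_O4", r2_anomeric * off_r2))
    b.z("R2_C3", "C", "R2", parent="R2_C2", aref="R2_C1", dref="R2_O4",
        L=CC, ang=("ring", "R2ring", 2), dih=("ring", "R2ring", 1))
    b.z("R2_C4", "C", "R2", parent="R2_C3", aref="R2_C2", dref="R2_C1",
        L=CC, ang=("ring", "R2ring", 3), dih=("ring", "R2ring", 2))

    b.tri("R2_H1", "H", "R2", "R2_C1", ("S1_O4", "R2_O4", "R2_C2"), CH)
    # C2 carries the R2-G3 glycosidic oxygen
    b.bis("R2_O2", "O", "R2", "R2_C2", "R2_C1", "R2_C3", CO_ANOMERIC, r2_o2_side,
          target=r2_o2_target)
    b.bis("R2_H2", "H", "R2", "R2_C2", "R2_C1", "R2_C3", CH, -r2_o2_side)
    # C3 quaternary: hydroxyl + gem-diol carbon
    b.bis("R2_O3", "O", "R2", "R2_C3", "R2_C2", "R2_C4", CO, -r2_c3p_side)
    b.bis("R2_C3p", "C", "R2", "R2_C3", "R2_C2", "R2_C4", CC, r2_c3p_side)
    _gd = (240.0, 120.0) if gemdiol_swap else (120.0, 240.0)
    for name, el, L, doff in (
        ("R2_O31", "O", 1.40, 0.0),
        ("R2_O32", "O", 1.40, _gd[0]),
        ("R2_H31", "H", CH, _gd[1]),
    ):
        b.z(name, el, "R2", parent="R2_C3p", aref="R2_C3", dref="R2_C2",
            L=L, ang=109.5, dih=("torsion", "chi3_R2", doff))
    # C4: methyl + H
    b.bis("R2_C5", "C", "R2", "R2_C4", "R2_C3", "R2_O4", CC, r2_c5_side)
    b.bis("R2_H4", "H", "R2", "R2_C4", "R2_C3", "R2_O4", CH, -r2_c5_side)
    for k in range(3):
        b.z(f"R2_H5{k+1}", "H", "R2", parent="R2_C5", aref="R2_C4", dref="R2_C3",
            L=CH, ang=109.5, dih=("torsion", "rot_R2_Me", 120.0 * k))

    # ---- G3 N-methyl-glucosamine (pyranose), entered through R2-G3 -------
    b.z("G3_C1", "C", "G3", parent="R2_O2", aref="R2_C2", dref="R2_C1",
        L=CO_ANOMERIC, ang=coc23, dih=("torsion", "psi23", 0.0))
    b.z("G3_O5", "O", "G3", parent="G3_C1", aref="R2_O2", dref="R2_C2",
        L=CO_ANOMERIC, ang=o2_c1_o5, dih=("torsion", "phi23", 0.0))
    off_g3 = improper_offset(o2_c1_o5, o2_c1_c2, 111.0)
    b.z("G3_C2", "C", "G3", parent="G3_C1", aref="R2_O2", dref="R2_C2",
        L=CC, ang=o2_c1_c2, dih=("relative", "G3_O5", g3_anomeric * off_g3))
    for i in range(3, 6):
        b.z(f"G3_C{i}", "C", "G3", parent=f"G3_C{i-1}", aref=f"G3_C{i-2}",
            dref=("G3_O5" if i == 3 else f"G3_C{i-3}"), L=CC,
            ang=("ring", "G3ring", i - 1), dih=("ring", "G3ring", i - 2))

    b.tri("G3_H1", "H", "G3", "G3_C1", ("R2_O2", "G3_O5", "G3_C2"), CH)
    b.bis("G3_N2", "N", "G3", "G3_C2", "G3_C1", "G3_C3", 1.50, g3_n2_side, target=n2_target)
    b.bis("G3_H2", "H", "G3", "G3_C2", "G3_C1", "G3_C3", CH, -g3_n2_side)
    for name, el, L, doff in (
        ("G3_C2p", "C", 1.49, 0.0),
        ("G3_HN21", "H", NH, 120.0),
        ("G3_HN22", "H", NH, 240.0),
    ):
        b.z(name, el, "G3", parent="G3_N2", aref="G3_C2", dref="G3_C1",
            L=L, ang=(c2p_ang if el == "C" else 109.0),
            dih=("torsion", "chi2_G3", doff))
    for k in range(3):
        b.z(f"G3_H2p{k+1}", "H", "G3", parent="G3_C2p", aref="G3_N2", dref="G3_C2",
            L=CH, ang=109.5, dih=("torsion", "rot_G3_NMe", 120.0 * k))
    b.bis("G3_O3", "O", "G3", "G3_C3", "G3_C2", "G3_C4", CO, -1)
    b.bis("G3_H3", "H", "G3", "G3_C3", "G3_C2", "G3_C4", CH, +1)
    b.bis("G3_O4", "O", "G3", "G3_C4", "G3_C3", "G3_C5", CO, +1)
    b.bis("G3_H4", "H", "G3", "G3_C4", "G3_C3", "G3_C5", CH, -1)
    b.bis("G3_C6", "C", "G3", "G3_C5", "G3_C4", "G3_O5", CC, -1)
    b.bis("G3_H5", "H", "G3", "G3_C5", "G3_C4", "G3_O5", CH, +1)
    for name, el, L, doff in (
        ("G3_O6", "O", CO, 0.0),
        ("G3_H61", "H", CH, 120.0),
        ("G3_H62", "H", CH, 240.0),
    ):
        b.z(name, el, "G3", parent="G3_C6", aref="G3_C5", dref="G3_C4",
            L=L, ang=109.5, dih=("torsion", "chi5_G3", doff))

    # ---- rings -----------------------------------------------------------
    rings = {
        "S1ring": RingSpec(
            "S1ring", tuple(ringS1),
            _chair_states([CC] * 6, [111.0] * 6), "4C1",
        ),
        "R2ring": RingSpec(
            "R2ring", ("R2_O4", "R2_C1", "R2_C2", "R2_C3", "R2_C4"),
            _furanose_states(
                [CO_ANOMERIC, CC, CC, CC, CO], [109.0, 104.0, 102.0, 102.0, 104.0],
                entry_index=1,
            ),
            "P144",
        ),
        "G3ring": RingSpec(
            "G3ring", ("G3_O5", "G3_C1", "G3_C2", "G3_C3", "G3_C4", "G3_C5"),
            _chair_states([CO_ANOMERIC, CC, CC, CC, CC, CO],
                          [112.0, 111.0, 111.0, 111.0, 111.0, 111.0],
                          entry_index=1),
            "4C1",
        ),
    }

    rotatable = {
        "phi12": ("R2_O4", "R2_C1", "S1_O4", "S1_C4"),
        "psi12": ("R2_C1", "S1_O4", "S1_C4", "S1_C3"),
        "phi23": ("G3_O5", "G3_C1", "R2_O2", "R2_C2"),
        "psi23": ("G3_C1", "R2_O2", "R2_C2", "R2_C1"),
        "chi1_S1": ("S1_C6", "S1_C1", "S1_N1", "S1_C1p"),
        "chi3_S1": ("S1_C2", "S1_C3", "S1_N3", "S1_C3p"),
        "chi3_R2": ("R2_C2", "R2_C3", "R2_C3p", "R2_O31"),
        "chi2_G3": ("G3_C1", "G3_C2", "G3_N2", "G3_C2p"),
        "chi5_G3": ("G3_C4", "G3_C5", "G3_C6", "G3_O6"),
    }
    rotors = {
        "rot_R2_Me": ("R2_C4", "R2_C3", "R2_C5", "R2_H51"),
        "rot_G3_NMe": ("G3_C2", "G3_N2", "G3_C2p", "G3_H2p1"),
    }
    equivalence = {
        "R2_Me": ["R2_H51", "R2_H52", "R2_H53"],
        "G3_NMe": ["G3_H2p1", "G3_H2p2", "G3_H2p3"],
        "S1_HN11g": ["S1_HN111", "S1_HN112"],
        "S1_HN12g": ["S1_HN121", "S1_HN122"],
        "S1_HN31g": ["S1_HN311", "S1_HN312"],
        "S1_HN32g": ["S1_HN321", "S1_HN322"],
    }
    prochiral = {"G3_H6": ("G3_H61", "G3_H62")}

    return MoleculeTemplate(
        atoms=b.atoms,
        rows=b.rows,
        rotatable_bonds=rotatable,
        rings=rings,
        trivial_rotors=rotors,
        equivalence_groups=equivalence,
        prochiral_pairs=prochiral,
        min_contact=2.4,
        name="streptomycin_like",
    )


def streptomycin_exchangeable_spins():
    """Spin names observable only in the H2O NOESY dataset."""
    return (
        "S1_HN1", "S1_HN11g", "S1_HN12g",
        "S1_HN3", "S1_HN31g", "S1_HN32g",
        "G3_HN21", "G3_HN22",
    )


def ground_truth_model():
    """The final fitted dynamic model of the study system.

    Nine bond models: the S1-R2 linkage is uni-modal, the R2-G3 linkage
    bi-modal with the hydroxymethyl chi5(G3) tied to it in one coupling
    group, the gem-diol chi3(R2) tri-modal on locked classic rotamers, the
    C1 guanidinium chi1(S1) bi-modal, and chi3(S1)/chi2(G3) uni-modal.
    Rings are single-state (furanose at phase 144 deg, both pyranose-type
    rings in their preferred chairs).  Enumeration yields 12 whole-molecule
    macrostates; clustering on the R2-G3 linkage gives families 0.62/0.38.
    """
    G = "R2G3"
    bonds = {
        "phi12": BondModel("phi12", [Macrostate(1.0, -75.0, 16.0)]),
        "psi12": BondModel("psi12", [Macrostate(1.0, -134.0, 22.0)]),
        "phi23": BondModel(
            "phi23",
            [Macrostate(0.62, -103.0, 6.0), Macrostate(0.38, 103.0, 10.0)],
            coupling_group=G,
        ),
        "psi23": BondModel(
            "psi23",
            [Macrostate(0.62, -81.0, 12.0), Macrostate(0.38, 173.0, 25.0)],
            coupling_group=G,
        ),
        "chi5_G3": BondModel(
            "chi5_G3",
            [Macrostate(0.62, -45.0, 25.0), Macrostate(0.38, -64.0, 25.0)],
            coupling_group=G,
        ),
        "chi1_S1": BondModel(
            "chi1_S1",
            [Macrostate(0.50, 78.0, 17.0), Macrostate(0.50, 162.0, 17.0)],
        ),
        "chi3_S1": BondModel("chi3_S1", [Macrostate(1.0, 128.0, 27.0)]),
        "chi3_R2": BondModel(
            "chi3_R2",
            [
                Macrostate(0.51, 180.0, 20.0, fixed_mu=True),
                Macrostate(0.45, -60.0, 20.0, fixed_mu=True),
                Macrostate(0.04, 60.0, 20.0, fixed_mu=True),
            ],
        ),
        "chi2_G3": BondModel("chi2_G3", [Macrostate(1.0, -103.0, 18.0)]),
    }
    rings = {
        "S1ring": RingModel("S1ring", ["4C1"], [1.0]),
        "R2ring": RingModel("R2ring", ["P144"], [1.0]),
        "G3ring": RingModel("G3ring", ["4C1"], [1.0]),
    }
    return DynamicModel(bonds=bonds, rings=rings)


def default_karplus_sets():
    return {
        "hh_sugar": KarplusSet("hh_sugar", 7.76, -1.10, 1.40),
        "hn_amine": KarplusSet("hn_amine", 6.40, -1.40, 1.90),
    }


def streptomycin_j_specs():
    """(quad, karplus_id) pairs for the fixture's scalar couplings."""
    sugar = [
        ("S1_H1", "S1_C1", "S1_C2", "S1_H2"),
        ("S1_H2", "S1_C2", "S1_C3", "S1_H3"),
        ("S1_H3", "S1_C3", "S1_C4", "S1_H4"),
        ("S1_H4", "S1_C4", "S1_C5", "S1_H5"),
        ("S1_H5", "S1_C5", "S1_C6", "S1_H6"),
        ("R2_H1", "R2_C1", "R2_C2", "R2_H2"),
        ("G3_H1", "G3_C1", "G3_C2", "G3_H2"),
        ("G3_H2", "G3_C2", "G3_C3", "G3_H3"),
        ("G3_H3", "G3_C3", "G3_C4", "G3_H4"),
        ("G3_H4", "G3_C4", "G3_C5", "G3_H5"),
        ("G3_H5", "G3_C5", "G3_C6", "G3_H61"),
        ("G3_H5", "G3_C5", "G3_C6", "G3_H62"),
    ]
    amine = [
        ("G3_H2", "G3_C2", "G3_N2", "G3_HN21"),
        ("G3_H2", "G3_C2", "G3_N2", "G3_HN22"),
    ]
    return [(q, "hh_sugar") for q in sugar] + [(q, "hn_amine") for q in amine]


# ---------------------------------------------------------------------------
# Toy templates
# ---------------------------------------------------------------------------

def butane_template():
    """Four-carbon chain with one torsion and a proton on each end carbon."""
    b = _Builder()
    b.z("C1", "C", "BUT")
    b.z("C2", "C", "BUT", parent="C1", L=CC)
    b.z("C3", "C", "BUT", parent="C2", aref="C1", L=CC, ang=111.0)
    b.z("C4", "C", "BUT", parent="C3", aref="C2", dref="C1", L=CC, ang=111.0,
        dih=("torsion", "tor", 0.0))
    b.z("H1", "H", "BUT", parent="C1", aref="C2", dref="C3", L=CH, ang=109.5,
        dih=("fixed", 180.0))
    b.z("H4", "H", "BUT", parent="C4", aref="C3", dref="C2", L=CH, ang=109.5,
        dih=("fixed", 180.0))
    return MoleculeTemplate(
        atoms=b.atoms, rows=b.rows,
        rotatable_bonds={"tor": ("C1", "C2", "C3", "C4")},
        name="butane_toy",
    )


def glycol_template():
    """HO-CH2-CH2-OH-like toy: one torsion, two prochiral proton pairs."""
    b = _Builder()
    b.z("O1", "O", "GLY")
    b.z("C1", "C", "GLY", parent="O1", L=CO)
    b.z("C2", "C", "GLY", parent="C1", aref="O1", L=CC, ang=109.5)
    b.z("O2", "O", "GLY", parent="C2", aref="C1", dref="O1", L=CO, ang=109.5,
        dih=("torsion", "chi", 0.0))
    b.z("H21", "H", "GLY", parent="C2", aref="C1", dref="O1", L=CH, ang=109.5,
        dih=("torsion", "chi", 120.0))
    b.z("H22", "H", "GLY", parent="C2", aref="C1", dref="O1", L=CH, ang=109.5,
        dih=("torsion", "chi", 240.0))
    b.z("H11", "H", "GLY", parent="C1", aref="C2", dref="O2", L=CH, ang=109.5,
        dih=("fixed", 120.0))
    b.z("H12", "H", "GLY", parent="C1", aref="C2", dref="O2", L=CH, ang=109.5,
        dih=("fixed", 240.0))
    return MoleculeTemplate(
        atoms=b.atoms, rows=b.rows,
        rotatable_bonds={"chi": ("O1", "C1", "C2", "O2")},
        prochiral_pairs={"H2pair": ("H21", "H22"), "H1pair": ("H11", "H12")},
        name="glycol_toy",
    )


def ribose_template():
    """Bare furanose ring for pucker scans: ring protons + two hydroxyls."""
    b = _Builder()
    b.z("C1", "C", "RIB")
    b.z("C2", "C", "RIB", parent="C1", L=CC)
    b.z("C3", "C", "RIB", parent="C2", aref="C1", L=CC, ang=("ring", "ring", 1))
    b.z("C4", "C", "RIB", parent="C3", aref="C2", dref="C1", L=CC,
        ang=("ring", "ring", 2), dih=("ring", "ring", 1))
    b.z("O4", "O", "RIB", parent="C4", aref="C3", dref="C2", L=CO,
        ang=("ring", "ring", 3), dih=("ring", "ring", 2))
    b.bis("O1", "O", "RIB", "C1", "O4", "C2", CO_ANOMERIC, +1)
    b.bis("H1", "H", "RIB", "C1", "O4", "C2", CH, -1)
    b.bis("O2", "O", "RIB", "C2", "C1", "C3", CO, -1)
    b.bis("H2", "H", "RIB", "C2", "C1", "C3", CH, +1)
    b.bis("O3", "O", "RIB", "C3", "C2", "C4", CO, +1)
    b.bis("H3", "H", "RIB", "C3", "C2", "C4", CH, -1)
    b.bis("H41", "H", "RIB", "C4", "C3", "O4", CH, +1)
    b.bis("H42", "H", "RIB", "C4", "C3", "O4", CH, -1)
    states = _furanose_states(
        [CC, CC, CC, CO, CO_ANOMERIC], [104.0, 102.0, 102.0, 104.0, 109.0]
    )
    return MoleculeTemplate(
        atoms=b.atoms, rows=b.rows,
        rotatable_bonds={},
        rings={"ring": RingSpec("ring", ("C1", "C2", "C3", "C4", "O4"), states, "P018")},
        name="ribose_toy",
    )


# ---------------------------------------------------------------------------
# Synthetic restraint generation
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Measurement-noise levels for the synthetic generator.

    Defaults mirror the study conditions: NOE errors at 40% of the height,
    Karplus-limited J errors of 1 Hz, RDC errors of 1.5 Hz, and a spectral
    noise floor below which cross peaks are recorded as no-NOEs.
    """

    noe_fraction: float = 0.40
    j_sigma: float = 1.0  # Hz
    rdc_sigma: float = 1.5  # Hz
    noise_floor: float = 0.003  # one-mole-equivalent height units
    nonoe_scaling_factor: float = 2.0  # multiplet factor used in the noise rule
    seed: int = 0

    def scaled(self, factor):
        """Noise spec with all random amplitudes multiplied by ``factor``."""
        return NoiseSpec(
            self.noe_fraction * factor, self.j_sigma * factor,
            self.rdc_sigma * factor, self.noise_floor,
            self.nonoe_scaling_factor, self.seed,
        )


def _default_datasets():
    return {
        "noesy_d2o": DatasetSpec("noesy_d2o", 0.700, 900.0, 278.0),
        "noesy_h2o": DatasetSpec("noesy_h2o", 0.600, 600.0, 278.0),
    }


def _stereospecific_ch_bonds(template):
    grouped = {a for atoms in template.equivalence_groups.values() for a in atoms}
    out = []
    for a, b2 in template.bonds():
        ea, eb = template.element(a), template.element(b2)
        if {ea, eb} == {"C", "H"}:
            c, h = (a, b2) if ea == "C" else (b2, a)
            if h not in grouped:
                out.append((c, h))
    return out


def simulate_restraints(
    template,
    model,
    noise=None,
    datasets=None,
    j_specs=(),
    karplus_sets=None,
    rdc_scales=None,
    exchangeable=(),
    tau_c=1.5e-9,
    ensemble_size=3000,
    leak_rate=0.0,
):
    """Forward-simulate a synthetic restraint set from a ground-truth model.

    NOESY heights are predicted by the package's own relaxation-matrix
    forward model at the given tau_c and acquisition settings, J couplings
    by Karplus averaging and RDCs by the shape-alignment model with the
    given per-medium magnitudes; Gaussian noise is then added per
    :class:`NoiseSpec` and cross peaks below the noise floor become no-NOEs
    with the noise/3 error rule.  Returns ``(RestraintSet, manifest)`` where
    the manifest records the noise-free true values and category counts.
    Deterministic given ``noise.seed``.
    """
    noise = noise or NoiseSpec()
    datasets = datasets or _default_datasets()
    karplus_sets = karplus_sets or default_karplus_sets()
    rdc_scales = rdc_scales or {"gel_4.5": 18.0, "gel_6": 27.0}
    # measurement noise uses its own child stream; the microstate ensemble is
    # drawn directly from noise.seed so that a forward prediction with the
    # same seed and ensemble size reproduces the noise-free data exactly
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 99]))

    ens = sample_ensemble(model, template, n=ensemble_size, seed=noise.seed)
    coords = ens.coords
    spins = SpinSystem.from_template(template)
    r6 = ensemble_r6(coords, spins)

    rs = RestraintSet(karplus_sets=dict(karplus_sets), datasets=dict(datasets))
    manifest = {
        "tau_c_s": tau_c,
        "ensemble_size": ensemble_size,
        "seed": noise.seed,
        "rdc_scales": dict(rdc_scales),
        "true": {"noe": {}, "j": {}, "rdc": {}},
    }

    exch = set(exchangeable)
    for a in exch:
        if a not in spins.names:
            raise InputError(f"exchangeable spin {a!r} is not a spin name")

    for ds_id, spec in datasets.items():
        R = relaxation_matrix(
            r6, tau_c, spec.field_mhz,
            multiplicity=spins.multiplicity, leak_rate=leak_rate,
        )
        H = predict_noesy(R, spec.mixing_time_s)
        for i in range(spins.n_spins):
            for j in range(i + 1, spins.n_spins):
                ni, nj = spins.names[i], spins.names[j]
                i_exch, j_exch = ni in exch, nj in exch
                if exch:
                    # D2O dataset: only non-exchangeable pairs; H2O dataset:
                    # pairs of one exchangeable and one non-exchangeable spin
                    if ds_id.endswith("h2o"):
                        if not (i_exch ^ j_exch):
                            continue
                    elif i_exch or j_exch:
                        continue
                h = float(abs(H[i, j]))
                manifest["true"]["noe"][f"{ds_id}:{ni}:{nj}"] = h
                if h < max(noise.noise_floor, 1e-12):
                    rs.noes.append(
                        NOERestraint(
                            ds_id, ni, nj, 0.0,
                            nonoe_error(noise.noise_floor, noise.nonoe_scaling_factor),
                            "noNOE",
                        )
                    )
                else:
                    # multiplicative lognormal intensity noise: keeps heights
                    # positive and is consistent with the fractional error rule
                    meas = h * float(np.exp(noise.noe_fraction * rng.standard_normal()))
                    rs.noes.append(
                        NOERestraint(ds_id, ni, nj, meas, noe_error(meas), "NOE")
                    )

    if j_specs:
        jr = [JRestraint(tuple(q), 0.0, max(noise.j_sigma, 1.0), kid)
              for q, kid in j_specs]
        true_j = ensemble_j_many(coords, template, jr, karplus_sets)
        for r, tj in zip(jr, true_j):
            r.observed = float(tj + noise.j_sigma * rng.standard_normal())
            manifest["true"]["j"]["-".join(r.atoms)] = float(tj)
        rs.jcouplings = jr

    ch = _stereospecific_ch_bonds(template)
    if ch and rdc_scales:
        from .geometry import VDW_RADII

        radii = np.array([VDW_RADII.get(a.element, 1.7) for a in template.atoms])
        tensors = alignment_tensors(coords, radii=radii)
        c_idx = np.array([template.index(c) for c, _ in ch])
        h_idx = np.array([template.index(h) for _, h in ch])
        proj = predict_rdc(coords, tensors, c_idx, h_idx, scale=1.0)
        err = max(noise.rdc_sigma, 1.0)
        for med, scale in rdc_scales.items():
            for (c, h), p in zip(ch, proj):
                true_d = scale * float(p)
                obs = true_d + noise.rdc_sigma * rng.standard_normal()
                rs.rdcs.append(RDCRestraint(med, c, h, float(obs), err))
                manifest["true"]["rdc"][f"{med}:{c}:{h}"] = true_d

    rs.validate(template)
    manifest["counts"] = rs.counts()
    manifest["counts"]["interresidue_noe"] = sum(
        1 for r in rs.noes
        if r.kind == "NOE" and r.proton_i.split("_")[0] != r.proton_j.split("_")[0]
    )
    manifest["counts"]["interresidue_nonoe"] = sum(
        1 for r in rs.noes
        if r.kind == "noNOE" and r.proton_i.split("_")[0] != r.proton_j.split("_")[0]
    )
    return rs, manifest


def streptomycin_restraints(noise=None, seed=None):
    """Synthetic restraint set for the streptomycin-like fixture.

    Two NOESY datasets (900 MHz / 700 ms in D2O and 600 MHz / 600 ms in
    H2O for the exchangeable protons), scalar couplings, and RDCs in two
    gel media.
    """
    noise = noise or NoiseSpec()
    if seed is not None:
        noise = NoiseSpec(
            noise.noe_fraction, noise.j_sigma, noise.rdc_sigma,
            noise.noise_floor, noise.nonoe_scaling_factor, seed,
        )
    template = streptomycin_template()
    model = ground_truth_model()
    rs, manifest = simulate_restraints(
        template, model, noise=noise,
        j_specs=streptomycin_j_specs(),
        exchangeable=streptomycin_exchangeable_spins(),
    )
    return template, model, rs, manifest
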