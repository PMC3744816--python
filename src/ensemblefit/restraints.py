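"""Restraint tables: NOE / no-NOE peak heights, 3J(HH) couplings, RDCs.

Heights are stored already normalized to one-mole-proton equivalence.  The
module also implements the measurement-side conventions used to assign
errors: NOE errors as a fixed fraction (default 40%) of the measured height,
no-NOE errors as one third of the largest peak height compatible with the
spectral noise (noise height times the largest multiplet scaling factor),
and multiplet component scaling factors from the Pascal-triangle convolution
of the coupling pattern.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

__all__ = [
    "NOERestraint",
    "JRestraint",
    "KarplusSet",
    "RDCRestraint",
    "DatasetSpec",
    "RestraintSet",
    "multiplet_scaling_factors",
    "nonoe_error",
    "noe_error",
    "parse_restraints",
    "write_restraints",
]

ERROR_FLOOR = 1e-6  # height units; chi-square needs strictly positive errors


@dataclass
class NOERestraint:
    dataset_id: str
    proton_i: str  # atom or equivalence-group name
    proton_j: str
    height: float  # one-mole-equivalent peak height (arbitrary units)
    error: float
    kind: str = "NOE"  # "NOE" | "noNOE"

    def validate(self):
        if self.kind not in ("NOE", "noNOE"):
            raise ValidationError(f"NOE kind must be NOE or noNOE, got {self.kind!r}")
        if self.error <= 0:
            raise ValidationError("NOE restraint error must be > 0")
        if self.kind == "noNOE" and self.height != 0:
            raise ValidationError("no-NOE restraints must have height 0")


@dataclass
class JRestraint:
    atoms: tuple  # four atom names defining the H-X-Y-H dihedral path
    observed: float  # Hz
    error: float  # Hz
    karplus_id: str

    def validate(self):
        if len(self.atoms) != 4:
            raise ValidationError("J restraint needs exactly four atoms")
        if self.error <= 0:
            raise ValidationError("J restraint error must be > 0")


@dataclass
class KarplusSet:
    """J(theta) = A cos^2(theta) + B cos(theta) + C, optionally with
    Haasnoot-Altona substituent corrections:

        J += sum_i dchi_i * (D + E cos^2(xi_i * theta + F * |dchi_i|))

    where dchi_i is the substituent electronegativity difference and
    xi_i = +1 or -1 its orientation sign.
    """

    id: str
    A: float
    B: float
    C: float
    D: float = 0.0
    E: float = 0.0
    F: float = 0.0
    substituents: list = field(default_factory=list)  # [(dchi, xi), ...]

    def validate(self):
        for v in (self.A, self.B, self.C, self.D, self.E, self.F):
            if not math.isfinite(v):
                raise ValidationError(f"Karplus set {self.id}: non-finite coefficient")


@dataclass
class RDCRestraint:
    medium_id: str
    atom_c: str
    atom_h: str
    observed: float  # Hz
    error: float  # Hz

    def validate(self):
        if self.error <= 0:
            raise ValidationError("RDC restraint error must be > 0")


@dataclass
class DatasetSpec:
    """Acquisition metadata for one NOESY dataset."""

    dataset_id: str
    mixing_time_s: float
    field_mhz: float
    temperature_k: float = 278.0


@dataclass
class RestraintSet:
    noes: list = field(default_factory=list)
    jcouplings: list = field(default_factory=list)
    rdcs: list = field(default_factory=list)
    karplus_sets: dict = field(default_factory=dict)
    datasets: dict = field(default_factory=dict)  # dataset_id -> DatasetSpec

    def validate(self, template=None):
        for r in self.noes + self.jcouplings + self.rdcs:
            r.validate()
        for k in self.karplus_sets.values():
            k.validate()
        for r in self.jcouplings:
            if r.karplus_id not in self.karplus_sets:
                raise ValidationError(f"unresolved karplus_id {r.karplus_id!r}")
        for r in self.noes:
            if r.dataset_id not in self.datasets:
                raise ValidationError(f"NOE references unknown dataset {r.dataset_id!r}")
        if template is not None:
            known = set(template.atom_names) | set(template.equivalence_groups)
            for r in self.noes:
                for p in (r.proton_i, r.proton_j):
                    if p not in known:
                        raise ValidationError(f"unknown proton/group {p!r} in NOE table")
            for r in self.jcouplings:
                for a in r.atoms:
                    if a not in template.atom_names:
                        raise ValidationError(f"unknown atom {a!r} in J table")
            for r in self.rdcs:
                for a in (r.atom_c, r.atom_h):
                    if a not in template.atom_names:
                        raise ValidationError(f"unknown atom {a!r} in RDC table")

    @property
    def noe_dataset_ids(self):
        seen = []
        for r in self.noes:
            if r.dataset_id not in seen:
                seen.append(r.dataset_id)
        return seen

    @property
    def rdc_medium_ids(self):
        seen = []
        for r in self.rdcs:
            if r.medium_id not in seen:
                seen.append(r.medium_id)
        return seen

    def counts(self):
        """Restraint census per category."""
        out = {}
        for ds in self.noe_dataset_ids:
            out[f"{ds}:NOE"] = sum(
                1 for r in self.noes if r.dataset_id == ds and r.kind == "NOE"
            )
            out[f"{ds}:noNOE"] = sum(
                1 for r in self.noes if r.dataset_id == ds and r.kind == "noNOE"
            )
        for med in self.rdc_medium_ids:
            out[f"rdc:{med}"] = sum(1 for r in self.rdcs if r.medium_id == med)
        out["jcouplings"] = len(self.jcouplings)
        out["total"] = len(self.noes) + len(self.jcouplings) + len(self.rdcs)
        return out


# ---------------------------------------------------------------------------
# Measurement-side rules
# ---------------------------------------------------------------------------

def multiplet_scaling_factors(couplings):
    """Per-component scaling factors for a 1H multiplet.

    The multiplet pattern is the Pascal-triangle convolution of one doublet
    per coupling; each component's relative intensity is its share of the
    total, and its scaling factor is the reciprocal (a doublet gives [2, 2];
    a triplet from two equal couplings gives [4, 2, 4]).
    """
    couplings = [float(c) for c in couplings]
    if any(c < 0 for c in couplings):
        raise InputError("couplings must be >= 0")
    # positions (Hz offsets) -> intensity, built by convolution
    comps = {0.0: 1.0}
    for c in couplings:
        nxt = {}
        for pos, w in comps.items():
            for s in (-0.5, 0.5):
                p = round(pos + s * c, 9)
                nxt[p] = nxt.get(p, 0.0) + 0.5 * w
        comps = nxt
    total = sum(comps.values())
    factors = [total / w for _, w in sorted(comps.items())]
    return factors


def nonoe_error(noise_height, max_scaling_factor=1.0):
    """Error for a no-NOE: a third of the largest plausible peak height.

    The noise height is treated as though it could be the top of a peak from
    the most intense multiplet component within three standard deviations:
    error = noise_height * max_scaling_factor / 3.
    """
    if noise_height <= 0:
        raise ValidationError("noise height must be > 0")
    if max_scaling_factor < 1:
        raise ValidationError("scaling factor must be >= 1")
    return noise_height * max_scaling_factor / 3.0


def noe_error(height, fraction=0.40):
    """NOE cross-peak error as a fraction (default 40%) of the height."""
    if height <= 0:
        raise ValidationError("NOE height must be > 0")
    return fraction * height


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------
#
# noe.tsv:      dataset_id  atom_i  atom_j  height  error  kind
# j.tsv:        atom1 atom2 atom3 atom4  observed_hz  error_hz  karplus_id
# karplus.tsv:  id  A  B  C  corrections   (corrections: JSON or empty)
# rdc.tsv:      medium_id  atom_c  atom_h  observed_hz  error_hz
# datasets.tsv: dataset_id  mixing_time_s  field_mhz  temperature_k

_FILES = ("noe.tsv", "j.tsv", "karplus.tsv", "rdc.tsv", "datasets.tsv")


def _require_columns(df, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")


def parse_restraints(directory, template=None):
    """Read a restraint directory of TSV tables into a validated RestraintSet.

    Per-line problems (unknown atoms, non-positive errors) are reported with
    their file and line number.
    """
    d = Path(directory)
    rs = RestraintSet()
    problems = []
    known = None
    if template is not None:
        known = set(template.atom_names) | set(template.equivalence_groups)

    p = d / "datasets.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t", dtype={"dataset_id": str}, float_precision="round_trip")
        _require_columns(df, ["dataset_id", "mixing_time_s", "field_mhz"], p)
        for _, row in df.iterrows():
            rs.datasets[row.dataset_id] = DatasetSpec(
                row.dataset_id,
                float(row.mixing_time_s),
                float(row.field_mhz),
                float(row.get("temperature_k", 278.0)),
            )

    p = d / "karplus.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t", dtype={"id": str}, float_precision="round_trip")
        _require_columns(df, ["id", "A", "B", "C"], p)
        for _, row in df.iterrows():
            corr = row.get("corrections")
            kw = {}
            if isinstance(corr, str) and corr.strip():
                cj = json.loads(corr)
                kw = {
                    "D": cj.get("D", 0.0),
                    "E": cj.get("E", 0.0),
                    "F": cj.get("F", 0.0),
                    "substituents": [tuple(s) for s in cj.get("substituents", [])],
                }
            rs.karplus_sets[row.id] = KarplusSet(
                row.id, float(row.A), float(row.B), float(row.C), **kw
            )

    p = d / "noe.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t", float_precision="round_trip")
        _require_columns(df, ["dataset_id", "atom_i", "atom_j", "height", "error", "kind"], p)
        for ln, row in enumerate(df.itertuples(index=False), start=2):
            if known is not None and (row.atom_i not in known or row.atom_j not in known):
                problems.append(f"{p}:{ln}: unknown proton {row.atom_i!r} or {row.atom_j!r}")
                continue
            if row.error <= 0:
                problems.append(f"{p}:{ln}: non-positive error {row.error!r}")
                continue
            rs.noes.append(
                NOERestraint(
                    str(row.dataset_id), row.atom_i, row.atom_j,
                    float(row.height), float(row.error), row.kind,
                )
            )

    p = d / "j.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t", dtype={"karplus_id": str}, float_precision="round_trip")
        _require_columns(
            df, ["atom1", "atom2", "atom3", "atom4", "observed_hz", "error_hz", "karplus_id"], p
        )
        for ln, row in enumerate(df.itertuples(index=False), start=2):
            atoms = (row.atom1, row.atom2, row.atom3, row.atom4)
            if known is not None and any(a not in known for a in atoms):
                problems.append(f"{p}:{ln}: unknown atom in {atoms}")
                continue
            if row.error_hz <= 0:
                problems.append(f"{p}:{ln}: non-positive error {row.error_hz!r}")
                continue
            rs.jcouplings.append(
                JRestraint(atoms, float(row.observed_hz), float(row.error_hz), row.karplus_id)
            )

    p = d / "rdc.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t", dtype={"medium_id": str}, float_precision="round_trip")
        _require_columns(df, ["medium_id", "atom_c", "atom_h", "observed_hz", "error_hz"], p)
        for ln, row in enumerate(df.itertuples(index=False), start=2):
            if known is not None and (row.atom_c not in known or row.atom_h not in known):
                problems.append(f"{p}:{ln}: unknown atom {row.atom_c!r}/{row.atom_h!r}")
                continue
            if row.error_hz <= 0:
                problems.append(f"{p}:{ln}: non-positive error {row.error_hz!r}")
                continue
            rs.rdcs.append(
                RDCRestraint(row.medium_id, row.atom_c, row.atom_h,
                             float(row.observed_hz), float(row.error_hz))
            )

    if problems:
        raise InputError("restraint parsing failed:\n" + "\n".join(problems))
    rs.validate(template)
    return rs


def write_restraints(rs, directory):
    """Write a RestraintSet as the TSV tables read by :func:`parse_restraints`."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "atom_i": r.proton_i,
                "atom_j": r.proton_j,
                "height": repr(r.height),
                "error": repr(r.error),
                "kind": r.kind,
            }
            for r in rs.noes
        ],
        columns=["dataset_id", "atom_i", "atom_j", "height", "error", "kind"],
    ).to_csv(d / "noe.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "atom1": r.atoms[0], "atom2": r.atoms[1],
                "atom3": r.atoms[2], "atom4": r.atoms[3],
                "observed_hz": repr(r.observed), "error_hz": repr(r.error),
                "karplus_id": r.karplus_id,
            }
            for r in rs.jcouplings
        ],
        columns=["atom1", "atom2", "atom3", "atom4", "observed_hz", "error_hz", "karplus_id"],
    ).to_csv(d / "j.tsv", sep="\t", index=False)
    krows = []
    for k in rs.karplus_sets.values():
        corr = ""
        if k.substituents or k.D or k.E or k.F:
            corr = json.dumps(
                {"D": k.D, "E": k.E, "F": k.F, "substituents": [list(s) for s in k.substituents]}
            )
        krows.append({"id": k.id, "A": repr(k.A), "B": repr(k.B), "C": repr(k.C),
                      "corrections": corr})
    pd.DataFrame(krows, columns=["id", "A", "B", "C", "corrections"]).to_csv(
        d / "karplus.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "medium_id": r.medium_id, "atom_c": r.atom_c, "atom_h": r.atom_h,
                "observed_hz": repr(r.observed), "error_hz": repr(r.error),
            }
            for r in rs.rdcs
        ],
        columns=["medium_id", "atom_c", "atom_h", "observed_hz", "error_hz"],
    ).to_csv(d / "rdc.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "dataset_id": ds.dataset_id,
                "mixing_time_s": repr(ds.mixing_time_s),
                "field_mhz": repr(ds.field_mhz),
                "temperature_k": repr(ds.temperature_k),
            }
            for ds in rs.datasets.values()
        ],
        columns=["dataset_id", "mixing_time_s", "field_mhz", "temperature_k"],
    ).to_csv(d / "datasets.tsv", sep="\t", index=False)
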