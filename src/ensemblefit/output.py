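"""Final coordinate sets, clash trimming, torsion histograms, measurements.

Two structure sets summarize a refined dynamic model: a fixed-size ensemble
of clash-free microstates (libration included) and the degenerate set of
whole-molecule macrostates at the mode means (libration removed, trivial
rotations grouped) carrying their occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError
from .geometry import (
    angle_from_coords,
    build_ensemble_coords,
    clash_mask,
    dihedral_from_coords,
    wrap_angle,
    write_pdb,
)
from .model import enumerate_macrostates, sample_ensemble

__all__ = [
    "OutputBundle",
    "emit_microstates",
    "emit_macrostates",
    "torsion_histogram",
    "measure_geometry",
    "write_output_bundle",
]


def emit_microstates(model, template, n=250, min_dist=None, seed=0, max_batches=200):
    """Sample exactly ``n`` clash-free microstates from the model.

    Conformers containing heavy-atom contacts below the allowed minimum are
    trimmed and replaced by further draws from the same model; the trimming
    log records how many draws were rejected.  ``min_dist = 0`` disables
    trimming.  An overall acceptance rate below 1% raises an error
    suggesting the model or contact threshold be reviewed.

    Returns ``(coords (n, natoms, 3), ensemble-like dict of torsions, log)``.
    """
    model.validate(template)
    rng = np.random.default_rng(seed)
    kept_coords = []
    kept_tors = {name: [] for name in list(template.rotatable_bonds) + list(template.trivial_rotors)}
    kept_rings = {r: [] for r in template.rings}
    n_drawn = 0
    n_rejected = 0
    batch = max(n, 50)
    for _ in range(max_batches):
        ens = sample_ensemble(model, template, n=batch, rng=rng)
        coords = ens.coords
        if min_dist == 0:
            bad = np.zeros(batch, dtype=bool)
        else:
            bad = clash_mask(template, coords, min_dist)
        n_drawn += batch
        n_rejected += int(bad.sum())
        good = ~bad
        kept_coords.append(coords[good])
        for k in kept_tors:
            kept_tors[k].append(ens.torsions[k][good])
        for r in kept_rings:
            kept_rings[r].append(ens.ring_states[r][good])
        if sum(c.shape[0] for c in kept_coords) >= n:
            break
        if n_drawn >= 20 * n and (n_drawn - n_rejected) < 0.01 * n_drawn:
            raise GeometryError(
                f"microstate acceptance rate {(n_drawn - n_rejected) / n_drawn:.3%} "
                "is below 1%; review the dynamic model or the contact threshold"
            )
    total_kept = sum(c.shape[0] for c in kept_coords)
    if total_kept < n:
        raise GeometryError(
            f"could not collect {n} clash-free microstates "
            f"({total_kept} accepted from {n_drawn} draws)"
        )
    coords = np.concatenate(kept_coords)[:n]
    torsions = {k: np.concatenate(v)[:n] for k, v in kept_tors.items()}
    ring_states = {r: np.concatenate(v)[:n] for r, v in kept_rings.items()}
    log = {"drawn": n_drawn, "rejected": n_rejected, "kept": n}
    return coords, {"torsions": torsions, "ring_states": ring_states}, log


def emit_macrostates(model, template):
    """Mean-state conformers (sigma ignored, trivial rotors at 180 deg).

    Returns ``(coords (m, natoms, 3), occupancies (m,), entries)`` where the
    occupancies are exactly those of :func:`enumerate_macrostates`.
    """
    entries = enumerate_macrostates(model, template)
    m = len(entries)
    tors = {name: np.empty(m) for name in template.rotatable_bonds}
    rings = {r: np.empty(m, dtype=int) for r in template.rings}
    for i, e in enumerate(entries):
        td = dict(e.torsions)
        for name in template.rotatable_bonds:
            tors[name][i] = td[name]
        pd_ = dict(e.puckers)
        for r in template.rings:
            state = pd_.get(r, template.rings[r].default_state)
            rings[r][i] = list(template.rings[r].states).index(state)
    coords, _ = build_ensemble_coords(template, tors, rings)
    occ = np.array([e.occupancy for e in entries])
    return coords, occ, entries


def torsion_histogram(angles_deg, bin_width=15.0, counts_only=True):
    """Circular histogram binned at ``bin_width`` intervals.

    Bin k is centered on k * bin_width, with bin 0 centered on 0 deg (north)
    and bins proceeding clockwise; edges are half-open, [center - w/2,
    center + w/2), so an angle exactly on an edge belongs to the higher bin.
    Counts conserve the number of angles.
    """
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise InputError("bin width must evenly divide 360 degrees")
    nbins = int(round(360.0 / bin_width))
    a = np.mod(np.asarray(angles_deg, float), 360.0)
    idx = np.floor(a / bin_width + 0.5).astype(int) % nbins
    counts = np.bincount(idx, minlength=nbins)
    if counts_only:
        return counts
    centers = np.arange(nbins) * bin_width
    return counts, centers


def measure_geometry(coords, template, queries):
    """Distances / angles / dihedrals over a conformer set.

    ``queries`` is a list of tuples ("distance", a, b), ("angle", a, b, c)
    or ("dihedral", a, b, c, d) with atom names.  Returns a DataFrame with
    per-query ensemble mean, standard deviation, min and max (circular mean
    for dihedrals).
    """
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    from .model import circular_mean, circular_std

    rows = []
    for q in queries:
        kind, atoms = q[0], q[1:]
        idx = [template.index(a) for a in atoms]
        pts = [coords[:, i] for i in idx]
        if kind == "distance":
            if len(atoms) != 2:
                raise InputError("distance query needs two atoms")
            v = np.linalg.norm(pts[0] - pts[1], axis=-1)
            mean = float(v.mean())
            spread = float(v.std())
        elif kind == "angle":
            if len(atoms) != 3:
                raise InputError("angle query needs three atoms")
            v = angle_from_coords(*pts)
            mean = float(np.mean(v))
            spread = float(np.std(v))
        elif kind == "dihedral":
            if len(atoms) != 4:
                raise InputError("dihedral query needs four atoms")
            v = dihedral_from_coords(*pts)
            mean = float(circular_mean(v))
            spread = float(circular_std(v))
        else:
            raise InputError(f"unknown query kind {kind!r}")
        v = np.atleast_1d(v)
        rows.append(
            {
                "kind": kind,
                "atoms": "-".join(atoms),
                "mean": mean,
                "spread": spread,
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class OutputBundle:
    microstate_coords: np.ndarray
    macrostate_coords: np.ndarray
    macrostate_occupancies: np.ndarray
    families: list
    histograms: dict  # torsion -> counts
    trim_log: dict


def write_output_bundle(
    model,
    template,
    out_dir,
    n_microstates=250,
    min_dist=None,
    seed=0,
    family_bonds=None,
    measurement_queries=None,
):
    """Emit microstates.pdb, macrostates.pdb, families.json, histograms and
    measurement tables for a refined model."""
    import json

    from .model import cluster_families

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    micro_coords, micro_sample, log = emit_microstates(
        model, template, n=n_microstates, min_dist=min_dist, seed=seed
    )
    write_pdb(out / "microstates.pdb", template, micro_coords)
    macro_coords, occ, entries = emit_macrostates(model, template)
    write_pdb(out / "macrostates.pdb", template, macro_coords, occupancies=occ)

    families = []
    if family_bonds:
        fams = cluster_families(entries, family_bonds, model=model)
        families = [
            {
                "family": i + 1,
                "mode_indices": list(f.family_id),
                "population": f.population,
                "n_members": len(f.members),
            }
            for i, f in enumerate(fams)
        ]
        with open(out / "families.json", "w", encoding="utf-8") as fh:
            json.dump({"defining_bonds": list(family_bonds), "families": families}, fh, indent=1)

    hists = {}
    rows = []
    for name in template.rotatable_bonds:
        counts = torsion_histogram(micro_sample["torsions"][name])
        hists[name] = counts
        for k, c in enumerate(counts):
            rows.append({"torsion": name, "bin_center_deg": 15 * k, "count": int(c)})
    pd.DataFrame(rows).to_csv(out / "torsion_histograms.tsv", sep="\t", index=False)

    if measurement_queries:
        measure_geometry(micro_coords, template, measurement_queries).to_csv(
            out / "measurements.tsv", sep="\t", index=False
        )
    return OutputBundle(
        microstate_coords=micro_coords,
        macrostate_coords=macro_coords,
        macrostate_occupancies=occ,
        families=families,
        histograms=hists,
        trim_log=log,
    )
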