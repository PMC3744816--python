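"""Chi-square scoring and Metropolis Monte-Carlo refinement of dynamic models.

The goodness of fit is the sum over restraints of squared prediction errors
divided by squared measurement errors.  Nuisance parameters (per-dataset
NOESY intensity scale, per-medium RDC magnitude, overall tumbling time
tau_c) are solved deterministically inside every evaluation.  Macrostate
parameters (mu, sigma, pi) are refined by a random-walk Metropolis sampler
at fixed temperature on the chi-square scale, typically restarted from many
random configurations; model selection (modality, ring pucker, prochiral
assignment) compares parsimony-adjusted chi-square between refits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .forward import DEFAULT_TAU_BRACKET, Predictor
from .model import (
    BondModel,
    DynamicModel,
    Macrostate,
    RingModel,
    circular_distance,
    circular_mean,
    make_draw_base,
    sample_ensemble,
)
from .geometry import wrap_angle

__all__ = [
    "FitConfig",
    "ChiSquareReport",
    "FitResult",
    "chi_square",
    "solve_nuisances",
    "metropolis_fit",
    "multistart_fit",
    "modality_scan",
    "assign_prochiral",
    "scan_ring_puckers",
]

CLASSIC_ROTAMERS = (60.0, 180.0, -60.0)  # 60, 180, 300 deg


@dataclass
class FitConfig:
    steps: int = 10000
    ensemble_size: int = 300
    temperature: float = 1.0
    anneal: tuple | None = None  # (T_start, T_end) geometric schedule; None = fixed T
    mu_step: float = 5.0
    sigma_step: float = 2.0
    pi_step: float = 0.05
    big_move_prob: float = 0.1  # occasional independence move for mu
    sigma_min: float = 0.0
    sigma_max: float = 45.0
    tau_bracket: tuple = DEFAULT_TAU_BRACKET
    tau_refit_every: int = 100
    leak_rate: float = 0.0
    rdc_model_fraction: float = 0.1
    ensemble_mode: str | None = None  # "fresh" | "crn"; None = context default
    # (metropolis_fit defaults to "fresh", multistart_fit to "crn")
    crn_refresh: int = 1000  # redraw the CRN base every N steps (0 = never)
    polish_sweeps: int = 8  # greedy coordinate-descent sweeps after the MC
    polish_ensemble: int = 600
    final_eval_size: int = 3000
    parsimony_margin: float = 1.0  # chi2 per added parameter
    occupancy_floor: float = 0.02
    merge_use_sigma: bool = True
    rotamer_lock_tol: float = 10.0
    tie_tolerance: float = 2.0
    runs: int = 96
    top_fraction: float = 0.10
    start_sigma_range: tuple = (5.0, 30.0)
    prescreen_draws: int = 24  # random starts screened per run; best one is used


# ---------------------------------------------------------------------------
# Chi-square report
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareReport:
    total: float
    groups: list  # (label, n restraints, chi2)
    per_restraint: dict  # label -> contribution array

    def __post_init__(self):
        s = sum(float(np.sum(v)) for v in self.per_restraint.values())
        if abs(s - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise ValidationError(
                f"chi-square bookkeeping broken: total {self.total} != sum {s}"
            )

    @property
    def n_restraints(self):
        return sum(n for _, n, _ in self.groups)

    @property
    def per_restraint_ratio(self):
        return self.total / self.n_restraints if self.n_restraints else math.nan

    def to_frame(self):
        rows = [
            {
                "dataset": label,
                "n_restraints": n,
                "total_chi2": round(c, 1),
                "chi2_per_restraint": round(c / n, 1) if n else math.nan,
            }
            for label, n, c in self.groups
        ]
        rows.append(
            {
                "dataset": "Total",
                "n_restraints": self.n_restraints,
                "total_chi2": round(self.total, 1),
                "chi2_per_restraint": round(self.per_restraint_ratio, 1),
            }
        )
        return pd.DataFrame(rows)

    @classmethod
    def from_evaluation(cls, ev):
        groups = sorted(
            [(label, n, c) for label, (n, c) in ev.chi2_parts.items()]
        )
        return cls(total=ev.chi2_total, groups=groups, per_restraint=dict(ev.per_restraint))


def chi_square(predictions, restraints, rdc_errors=None):
    """Score supplied predictions against a restraint set.

    ``predictions`` maps group labels to arrays aligned with the restraint
    tables: one array per NOESY dataset id (in table order), ``"jcouplings"``
    and ``"rdc:<medium>"``.  No-NOEs are scored against zero with their
    noise-derived errors.  Missing or misaligned predictions raise
    :class:`InputError` listing the offending group.
    """
    groups = []
    per = {}
    total = 0.0

    def add(label, pred, obs, err, split_mask=None, split_names=None):
        nonlocal total
        pred = np.asarray(pred, float)
        if pred.shape != obs.shape:
            raise InputError(
                f"prediction for {label!r} has {pred.shape[0] if pred.ndim else 0} "
                f"entries, expected {obs.shape[0]}"
            )
        contrib = ((pred - obs) / err) ** 2
        per[label] = contrib
        if split_mask is not None:
            for name, mask in zip(split_names, (split_mask, ~split_mask)):
                if np.any(mask):
                    groups.append((f"{label}:{name}", int(mask.sum()), float(contrib[mask].sum())))
        else:
            groups.append((label, len(obs), float(contrib.sum())))
        total += float(contrib.sum())

    missing = []
    for ds in restraints.noe_dataset_ids:
        rows = [r for r in restraints.noes if r.dataset_id == ds]
        if ds not in predictions:
            missing.append(ds)
            continue
        add(
            ds,
            predictions[ds],
            np.array([r.height for r in rows]),
            np.array([r.error for r in rows]),
            split_mask=np.array([r.kind == "NOE" for r in rows]),
            split_names=("NOE", "noNOE"),
        )
    if restraints.jcouplings:
        if "jcouplings" not in predictions:
            missing.append("jcouplings")
        else:
            add(
                "jcouplings",
                predictions["jcouplings"],
                np.array([r.observed for r in restraints.jcouplings]),
                np.array([r.error for r in restraints.jcouplings]),
            )
    for med in restraints.rdc_medium_ids:
        label = f"rdc:{med}"
        rows = [r for r in restraints.rdcs if r.medium_id == med]
        if label not in predictions:
            missing.append(label)
            continue
        err = np.array([r.error for r in rows])
        if rdc_errors and label in rdc_errors:
            err = np.asarray(rdc_errors[label], float)
        add(label, predictions[label], np.array([r.observed for r in rows]), err)
    if missing:
        raise InputError(f"missing predictions for: {missing}")
    return ChiSquareReport(total=total, groups=sorted(groups), per_restraint=per)


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: DynamicModel
    tau_c: float
    noesy_scales: dict
    rdc_scales: dict
    chi2: ChiSquareReport
    seed: int | None
    trace: np.ndarray  # best-so-far chi2 per step (monotone non-increasing)
    acceptance_ratio: float

    def to_json(self):
        return {
            "model": self.model.to_json(),
            "tau_c_s": self.tau_c,
            "noesy_scales": self.noesy_scales,
            "rdc_scales": self.rdc_scales,
            "chi2_total": self.chi2.total,
            "chi2_groups": [
                {"dataset": l, "n": n, "chi2": c} for l, n, c in self.chi2.groups
            ],
            "seed": self.seed,
            "acceptance_ratio": self.acceptance_ratio,
            "trace": [float(x) for x in self.trace],
        }

    def save(self, path):
        import json

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1)


# ---------------------------------------------------------------------------
# Nuisance solving
# ---------------------------------------------------------------------------

def solve_nuisances(model, template, restraints, n=300, seed=0, config=None):
    """Closed-form scales and bounded-bracket tau_c for a model's ensemble."""
    cfg = config or FitConfig()
    pred = Predictor(
        template, restraints,
        leak_rate=cfg.leak_rate, rdc_model_fraction=cfg.rdc_model_fraction,
        tau_bracket=cfg.tau_bracket,
    )
    ens = sample_ensemble(model, template, n=n, seed=seed)
    ev = pred.evaluate(ens.coords, optimize_tau=True)
    return ev.tau_c, ev.noesy_scales, ev.rdc_scales


# ---------------------------------------------------------------------------
# Metropolis Monte-Carlo
# ---------------------------------------------------------------------------

def _build_moves(model):
    moves = []
    for uid, pis, members in model.units():
        if len(pis) > 1:
            moves.append(("pi", uid, None))
            # joint re-draw of one whole mode of a multi-bond unit: lets a
            # collapsed mode escape as a unit instead of one torsion at a time
            free_bonds = [
                m for m in members
                if isinstance(m, BondModel)
                and not all(ms.fixed_mu for ms in m.macrostates)
            ]
            if len(free_bonds) > 1:
                for k in range(len(pis)):
                    moves.append(("jump", uid, k))
        for m in members:
            if isinstance(m, BondModel):
                for k, ms in enumerate(m.macrostates):
                    if not ms.fixed_mu:
                        moves.append(("mu", m.torsion, k))
                    moves.append(("sigma", m.torsion, k))
    return moves


def _set_unit_pis(model, uid, new_pis):
    for cur_uid, _, members in model.units():
        if cur_uid != uid:
            continue
        for m in members:
            if isinstance(m, BondModel):
                for k, ms in enumerate(m.macrostates):
                    ms.pi = float(new_pis[k])
            else:
                m.probs = [float(p) for p in new_pis]
        return
    raise InputError(f"unknown selection unit {uid!r}")


def _unit_pis(model, uid):
    for cur_uid, pis, _ in model.units():
        if cur_uid == uid:
            return np.array(pis, float)
    raise InputError(f"unknown selection unit {uid!r}")


def _polish(model, tau_c, pred, template, cfg, rng):
    """Greedy coordinate descent into the bottom of the current basin.

    Uses one fixed common-random-numbers base so the objective is
    deterministic; tries shrinking +/- steps per parameter and keeps only
    improvements.  Runs after the Metropolis phase.
    """
    model = model.copy()
    base = make_draw_base(model, template, cfg.polish_ensemble, rng)

    def score(tc, opt=False):
        ens = sample_ensemble(model, template, cfg.polish_ensemble, base=base)
        ev = pred.evaluate(ens.coords, tau_c=tc, optimize_tau=opt)
        return ev

    ev = score(tau_c, opt=True)
    tau_c = ev.tau_c
    current = ev.chi2_total
    moves = _build_moves(model)
    for sweep in range(cfg.polish_sweeps):
        shrink = 0.5**sweep
        improved = False
        for kind, target, k in moves:
            if kind == "jump":
                continue
            if kind == "pi":
                old = _unit_pis(model, target)
                nm = len(old)
                candidates = []
                for a in range(nm):
                    for b in range(nm):
                        if a != b:
                            d = min(cfg.pi_step * shrink, old[a])
                            if d > 0:
                                new = old.copy()
                                new[a] -= d
                                new[b] += d
                                candidates.append(np.clip(new, 0.0, 1.0))
                for new in candidates:
                    new[np.argmax(new)] += 1.0 - new.sum()
                    _set_unit_pis(model, target, new)
                    trial = score(tau_c).chi2_total
                    if trial < current - 1e-10:
                        current = trial
                        old = new
                        improved = True
                    else:
                        _set_unit_pis(model, target, old)
            else:
                ms = model.bonds[target].macrostates[k]
                step = (cfg.mu_step if kind == "mu" else cfg.sigma_step) * shrink
                for delta in (step, -step):
                    if kind == "mu":
                        old_v = ms.mu
                        ms.mu = float(wrap_angle(old_v + delta))
                    else:
                        old_v = ms.sigma
                        ms.sigma = float(
                            np.clip(old_v + delta, cfg.sigma_min, cfg.sigma_max)
                        )
                    trial = score(tau_c).chi2_total
                    if trial < current - 1e-10:
                        current = trial
                        improved = True
                    else:
                        if kind == "mu":
                            ms.mu = old_v
                        else:
                            ms.sigma = old_v
        ev = score(tau_c, opt=True)
        tau_c = ev.tau_c
        current = ev.chi2_total
        if not improved and sweep >= 1:
            break
    return model, tau_c


def metropolis_fit(model0, template, restraints, config=None, seed=0, predictor=None):
    """Minimize chi-square over macrostate parameters by Metropolis MC.

    One randomly chosen parameter (a mode mean, a mode spread, or a unit's
    occupancy simplex) is perturbed per step; moves are accepted with
    probability min(1, exp(-dchi2 / T)).  A fresh microstate ensemble is
    drawn per evaluation (or one common-random-number base is held fixed,
    ``config.ensemble_mode = "crn"``).  The best-visited model is returned,
    re-scored with a larger ensemble; fully reproducible given ``seed``.
    """
    cfg = config or FitConfig()
    if cfg.ensemble_mode is None:
        cfg = replace(cfg, ensemble_mode="fresh")
    if cfg.steps < 1:
        raise InputError("steps must be >= 1")
    model = model0.copy()
    model.validate(template)
    pred = predictor or Predictor(
        template, restraints,
        leak_rate=cfg.leak_rate, rdc_model_fraction=cfg.rdc_model_fraction,
        tau_bracket=cfg.tau_bracket,
    )
    ss = np.random.SeedSequence(seed)
    rng_prop, rng_ens, rng_eval = (np.random.default_rng(s) for s in ss.spawn(3))

    moves = _build_moves(model)

    base = None
    if cfg.ensemble_mode == "crn":
        base = make_draw_base(model, template, cfg.ensemble_size, rng_ens)

    def draw_coords():
        if cfg.ensemble_mode == "crn":
            ens = sample_ensemble(model, template, cfg.ensemble_size, base=base)
        else:
            ens = sample_ensemble(
                model, template, cfg.ensemble_size, rng=rng_ens
            )
        return ens.coords

    tau_c = None
    ev = pred.evaluate(draw_coords(), tau_c=tau_c, optimize_tau=True)
    tau_c = ev.tau_c
    current = ev.chi2_total

    if not moves:
        # nothing to optimize (e.g. a single fixed ring state): score only
        final_ens = sample_ensemble(model, template, cfg.final_eval_size, rng=rng_eval)
        final = pred.evaluate(final_ens.coords, tau_c=tau_c, optimize_tau=True)
        return FitResult(
            model=model, tau_c=final.tau_c, noesy_scales=final.noesy_scales,
            rdc_scales=final.rdc_scales,
            chi2=ChiSquareReport.from_evaluation(final), seed=seed,
            trace=np.full(cfg.steps + 1, current), acceptance_ratio=0.0,
        )
    best_chi2 = current
    best_model = model.copy()
    best_tau = tau_c
    trace = np.empty(cfg.steps + 1)
    trace[0] = best_chi2
    n_accept = 0

    for step in range(1, cfg.steps + 1):
        if cfg.ensemble_mode == "crn" and cfg.crn_refresh and step % cfg.crn_refresh == 0:
            base = make_draw_base(model, template, cfg.ensemble_size, rng_ens)
            ev = pred.evaluate(draw_coords(), tau_c=tau_c)
            current = ev.chi2_total

        kind, target, k = moves[rng_prop.integers(len(moves))]
        if kind == "jump":
            old = {}
            for uid, _, members in model.units():
                if uid != target:
                    continue
                for m in members:
                    if isinstance(m, BondModel) and not m.macrostates[k].fixed_mu:
                        old[m.torsion] = m.macrostates[k].mu
                        m.macrostates[k].mu = float(
                            wrap_angle(rng_prop.uniform(-180.0, 180.0))
                        )
        elif kind == "mu":
            ms = model.bonds[target].macrostates[k]
            old = ms.mu
            if rng_prop.random() < cfg.big_move_prob:
                ms.mu = float(wrap_angle(rng_prop.uniform(-180.0, 180.0)))
            else:
                ms.mu = float(wrap_angle(old + rng_prop.uniform(-cfg.mu_step, cfg.mu_step)))
        elif kind == "sigma":
            ms = model.bonds[target].macrostates[k]
            old = ms.sigma
            v = old + rng_prop.uniform(-cfg.sigma_step, cfg.sigma_step)
            if v < cfg.sigma_min:
                v = 2 * cfg.sigma_min - v
            if v > cfg.sigma_max:
                v = 2 * cfg.sigma_max - v
            ms.sigma = float(np.clip(v, cfg.sigma_min, cfg.sigma_max))
        else:  # pi simplex transfer
            old = _unit_pis(model, target)
            nm = len(old)
            a, b = rng_prop.choice(nm, size=2, replace=False)
            delta = min(rng_prop.uniform(0.0, cfg.pi_step), old[a])
            new = np.clip(old.copy(), 0.0, 1.0)
            new[a] -= delta
            new[b] += delta
            new = np.clip(new, 0.0, 1.0)
            new[a] += 1.0 - new.sum()  # keep the simplex closed exactly
            if new[a] < 0.0:
                new[a] = 0.0
                new /= new.sum()
            _set_unit_pis(model, target, new)

        optimize_tau = cfg.tau_refit_every and step % cfg.tau_refit_every == 0
        ev = pred.evaluate(draw_coords(), tau_c=tau_c, optimize_tau=optimize_tau)
        d = ev.chi2_total - current
        if cfg.anneal is None:
            temp = cfg.temperature
        else:
            t0, t1 = cfg.anneal
            temp = t0 * (t1 / t0) ** (step / cfg.steps)
        if d <= 0 or rng_prop.random() < math.exp(-d / temp):
            current = ev.chi2_total
            tau_c = ev.tau_c
            n_accept += 1
            if current < best_chi2:
                best_chi2 = current
                best_model = model.copy()
                best_tau = tau_c
        else:  # revert
            if kind == "jump":
                for tname, mu in old.items():
                    model.bonds[tname].macrostates[k].mu = mu
            elif kind == "mu":
                model.bonds[target].macrostates[k].mu = old
            elif kind == "sigma":
                model.bonds[target].macrostates[k].sigma = old
            else:
                _set_unit_pis(model, target, old)
        trace[step] = best_chi2

    if cfg.polish_sweeps:
        best_model, best_tau = _polish(
            best_model, best_tau, pred, template, cfg, rng_eval
        )

    # final deterministic re-evaluation with a larger ensemble
    final_ens = sample_ensemble(
        best_model, template, cfg.final_eval_size, rng=rng_eval
    )
    final = pred.evaluate(final_ens.coords, tau_c=best_tau, optimize_tau=True)
    return FitResult(
        model=best_model,
        tau_c=final.tau_c,
        noesy_scales=final.noesy_scales,
        rdc_scales=final.rdc_scales,
        chi2=ChiSquareReport.from_evaluation(final),
        seed=seed,
        trace=trace,
        acceptance_ratio=n_accept / cfg.steps,
    )


# ---------------------------------------------------------------------------
# Multistart
# ---------------------------------------------------------------------------

def randomize_start(model0, rng, config=None):
    """Random starting configuration preserving the model's structure."""
    cfg = config or FitConfig()
    model = model0.copy()
    lo, hi = cfg.start_sigma_range
    for uid, pis, members in model.units():
        if len(pis) > 1:
            _set_unit_pis(model, uid, rng.dirichlet(np.ones(len(pis))))
        for m in members:
            if isinstance(m, BondModel):
                for ms in m.macrostates:
                    if not ms.fixed_mu:
                        ms.mu = float(wrap_angle(rng.uniform(-180.0, 180.0)))
                    ms.sigma = float(rng.uniform(lo, hi))
    return model


def _match_modes(ref_bond, other_bond):
    """Permutation of other's modes best matching ref's means (circular)."""
    from itertools import permutations

    n = ref_bond.n_modes
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(n)):
        cost = sum(
            circular_distance(
                ref_bond.macrostates[i].mu, other_bond.macrostates[perm[i]].mu
            )
            for i in range(n)
        )
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return best_perm


def multistart_fit(
    model0,
    template,
    restraints,
    config=None,
    seed=0,
    runs=None,
    top_fraction=None,
    progress=False,
):
    """Independent seeded Metropolis runs from randomized starts.

    Returns the lowest-chi-square run plus a convergence report comparing
    macrostate means (circular distance, threshold 10 deg) and occupancies
    (threshold 0.1) across the top ``ceil(fraction * runs)`` runs.

    Runs use the common-random-numbers ensemble mode by default so each
    run's chi-square landscape is deterministic; run-to-run scatter then
    reflects both start dispersion and finite-ensemble noise.
    """
    cfg = config or FitConfig()
    if cfg.ensemble_mode is None:
        cfg = replace(cfg, ensemble_mode="crn")
    runs = runs if runs is not None else cfg.runs
    top_fraction = top_fraction if top_fraction is not None else cfg.top_fraction
    if runs < 1:
        raise InputError("runs must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(runs + 1)
    pred = Predictor(
        template, restraints,
        leak_rate=cfg.leak_rate, rdc_model_fraction=cfg.rdc_model_fraction,
        tau_bracket=cfg.tau_bracket,
    )
    results = []
    for r in range(runs):
        rng_start = np.random.default_rng(children[r])
        start = randomize_start(model0, rng_start, cfg)
        if cfg.prescreen_draws > 1:
            base = make_draw_base(model0, template, cfg.ensemble_size, rng_start)
            best_start, best_sc = start, np.inf
            cand = start
            for _ in range(cfg.prescreen_draws):
                ens = sample_ensemble(cand, template, cfg.ensemble_size, base=base)
                sc = pred.evaluate(ens.coords).chi2_total
                if sc < best_sc:
                    best_sc, best_start = sc, cand
                cand = randomize_start(model0, rng_start, cfg)
            start = best_start
        run_seed = int(children[r].generate_state(1)[0] % (2**31 - 1))
        res = metropolis_fit(
            start, template, restraints, config=cfg, seed=run_seed, predictor=pred
        )
        results.append(res)
        if progress:
            print(f"  run {r + 1}/{runs}: chi2 = {res.chi2.total:.1f}")

    order = np.argsort([r.chi2.total for r in results])
    n_top = math.ceil(top_fraction * runs)
    top = [results[i] for i in order[:n_top]]
    best = top[0]

    divergent = []
    for other in top[1:]:
        for bond in best.model.bonds:
            rb, ob = best.model.bonds[bond], other.model.bonds[bond]
            perm = _match_modes(rb, ob)
            for i in range(rb.n_modes):
                dmu = float(
                    circular_distance(rb.macrostates[i].mu, ob.macrostates[perm[i]].mu)
                )
                dpi = abs(rb.macrostates[i].pi - ob.macrostates[perm[i]].pi)
                if dmu > 10.0 or dpi > 0.1:
                    divergent.append(
                        {"bond": bond, "mode": i, "dmu_deg": dmu, "dpi": float(dpi)}
                    )
    report = {
        "runs": runs,
        "n_compared": n_top,
        "chi2_top": [float(r.chi2.total) for r in top],
        "chi2_all": [float(r.chi2.total) for r in results],
        "divergent": divergent,
        "converged": not divergent,
    }
    return best, report


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _lock_rotamers(bond_model, tol):
    for ms in bond_model.macrostates:
        for rot in CLASSIC_ROTAMERS:
            if circular_distance(ms.mu, rot) <= tol:
                ms.mu = rot
                ms.fixed_mu = True
                break


def _reduce_bond(bond_model, cfg):
    """Merge overlapping modes and drop negligible occupancies."""
    modes = list(bond_model.macrostates)
    changed = True
    while changed and len(modes) > 1:
        changed = False
        for i in range(len(modes)):
            for j in range(i + 1, len(modes)):
                a, b = modes[i], modes[j]
                if circular_distance(a.mu, b.mu) < (a.sigma + b.sigma):
                    w = a.pi + b.pi
                    frac = b.pi / w if w > 0 else 0.5
                    mu = wrap_angle(a.mu + frac * wrap_angle(b.mu - a.mu))
                    merged = Macrostate(
                        pi=w, mu=float(mu), sigma=max(a.sigma, b.sigma),
                        fixed_mu=a.fixed_mu or b.fixed_mu,
                    )
                    modes = [m for k, m in enumerate(modes) if k not in (i, j)]
                    modes.append(merged)
                    changed = True
                    break
            if changed:
                break
    modes = [m for m in modes if m.pi >= cfg.occupancy_floor] or [max(modes, key=lambda m: m.pi)]
    total = sum(m.pi for m in modes)
    for m in modes:
        m.pi /= total
    modes.sort(key=lambda m: -m.pi)
    return BondModel(bond_model.torsion, modes, bond_model.coupling_group)


def modality_scan(model, template, restraints, bond, config=None, seed=0):
    """Select the uni/bi/tri-modal variant of one (uncoupled) bond.

    Each variant is refit; a variant must beat the simpler one by the
    parsimony margin (default 1 chi-square unit per added parameter, 3 per
    mode) to be kept.  Merged/negligible modes reduce the modality, and
    means settling on classic rotamer angles are locked.
    """
    cfg = config or FitConfig()
    if bond not in model.bonds:
        raise InputError(f"unknown bond {bond!r}")
    if model.bonds[bond].coupling_group:
        raise InputError("modality_scan operates on uncoupled bonds")
    ss = np.random.SeedSequence(seed)
    details = {}
    fits = {}
    for m, child in zip((1, 2, 3), ss.spawn(3)):
        variant = model.copy()
        mu0 = model.bonds[bond].macrostates[0].mu
        variant.bonds[bond] = BondModel(
            bond,
            [
                Macrostate(pi=1.0 / m, mu=wrap_angle(mu0 + 120.0 * k), sigma=15.0)
                for k in range(m)
            ],
        )
        res = metropolis_fit(
            variant, template, restraints, config=cfg,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        fits[m] = res
        details[m] = {"chi2": res.chi2.total, "n_params": 3 * (m - 1)}
    n_restraints = fits[1].chi2.n_restraints
    best_m = 1
    for m in (2, 3):
        # parsimony margin per added parameter, scaled to the current fit
        # quality so that near-noise-free data still resolve modality by
        # relative improvement
        scale = max(fits[best_m].chi2.total / max(n_restraints, 1), 0.01)
        needed = cfg.parsimony_margin * 3 * (m - best_m) * scale
        if fits[m].chi2.total < fits[best_m].chi2.total - needed:
            best_m = m
    chosen = _reduce_bond(fits[best_m].model.bonds[bond], cfg)
    _lock_rotamers(chosen, cfg.rotamer_lock_tol)
    return chosen, {"selected_modality": best_m, "variants": details, "fit": fits[best_m]}


def _swap_restraints(restraints, pair):
    """Relabel the two prochiral protons throughout the restraint tables."""
    from dataclasses import replace as drep

    a, b = pair
    swap = {a: b, b: a}
    out = type(restraints)(
        noes=[
            drep(r, proton_i=swap.get(r.proton_i, r.proton_i),
                 proton_j=swap.get(r.proton_j, r.proton_j))
            for r in restraints.noes
        ],
        jcouplings=[
            drep(r, atoms=tuple(swap.get(x, x) for x in r.atoms))
            for r in restraints.jcouplings
        ],
        rdcs=[
            drep(r, atom_h=swap.get(r.atom_h, r.atom_h),
                 atom_c=swap.get(r.atom_c, r.atom_c))
            for r in restraints.rdcs
        ],
        karplus_sets=dict(restraints.karplus_sets),
        datasets=dict(restraints.datasets),
    )
    return out


@dataclass
class ProchiralResult:
    assignment: str  # "original" | "swapped" | "undetermined"
    delta_chi2: float  # chi2(swapped) - chi2(original)
    original: FitResult
    swapped: FitResult


def assign_prochiral(model, template, restraints, pair, config=None, seed=0):
    """Fit under both NMR-degenerate label assignments of a prochiral pair.

    The lower-chi-square assignment is selected; differences below the tie
    tolerance are flagged undetermined.
    """
    cfg = config or FitConfig()
    if pair not in template.prochiral_pairs:
        raise InputError(f"prochiral pair {pair!r} not declared in template")
    atoms = template.prochiral_pairs[pair]
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))
    res_orig = metropolis_fit(model, template, restraints, config=cfg, seed=s1)
    res_swap = metropolis_fit(
        model, template, _swap_restraints(restraints, atoms), config=cfg, seed=s2
    )
    d = res_swap.chi2.total - res_orig.chi2.total
    if abs(d) < cfg.tie_tolerance:
        pick = "undetermined"
    else:
        pick = "original" if d > 0 else "swapped"
    return ProchiralResult(pick, float(d), res_orig, res_swap)


@dataclass
class PuckerScanResult:
    ring_model: RingModel
    chi2: float
    degenerate_with: list  # states within the tie tolerance of the best
    table: pd.DataFrame
    fit: FitResult


def scan_ring_puckers(
    model, template, restraints, ring, config=None, seed=0,
    states=None, max_modality=2, top_k=3,
):
    """Test canonical pucker states (and bi-modal combinations) of a ring.

    Every candidate state is fit individually; the ``top_k`` best are also
    combined pairwise into bi-modal ring models whose state probabilities
    are fit.  The best parsimony-adjusted chi-square wins; near-ties are
    reported with a degeneracy flag.
    """
    cfg = config or FitConfig()
    if ring not in template.rings:
        raise InputError(f"unknown ring {ring!r}")
    cand = list(states or template.rings[ring].states)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(cand) + top_k * (top_k - 1) // 2))
    rows = []
    fits = {}
    for s in cand:
        variant = model.copy()
        variant.rings[ring] = RingModel(ring, [s], [1.0])
        res = metropolis_fit(
            variant, template, restraints, config=cfg,
            seed=int(next(children).generate_state(1)[0] % (2**31 - 1)),
        )
        fits[(s,)] = res
        rows.append({"states": s, "chi2": res.chi2.total, "adjusted": res.chi2.total})
    order = sorted(fits, key=lambda k: fits[k].chi2.total)
    if max_modality >= 2 and len(order) >= 2:
        top = [k[0] for k in order[:top_k]]
        for i in range(len(top)):
            for j in range(i + 1, len(top)):
                variant = model.copy()
                variant.rings[ring] = RingModel(ring, [top[i], top[j]], [0.5, 0.5])
                res = metropolis_fit(
                    variant, template, restraints, config=cfg,
                    seed=int(next(children).generate_state(1)[0] % (2**31 - 1)),
                )
                fits[(top[i], top[j])] = res
                rows.append(
                    {
                        "states": f"{top[i]}+{top[j]}",
                        "chi2": res.chi2.total,
                        "adjusted": res.chi2.total + cfg.parsimony_margin,
                    }
                )
    best_key = min(fits, key=lambda k: fits[k].chi2.total + cfg.parsimony_margin * (len(k) - 1))
    best = fits[best_key]
    best_adj = best.chi2.total + cfg.parsimony_margin * (len(best_key) - 1)
    degenerate = [
        "+".join(k)
        for k in fits
        if k != best_key
        and abs(fits[k].chi2.total + cfg.parsimony_margin * (len(k) - 1) - best_adj)
        < cfg.tie_tolerance
    ]
    return PuckerScanResult(
        ring_model=best.model.rings[ring],
        chi2=best.chi2.total,
        degenerate_with=degenerate,
        table=pd.DataFrame(rows).sort_values("adjusted").reset_index(drop=True),
        fit=best,
    )
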