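"""Fitting microscopic rates of photocycle schemes to apparent kinetics.

A scheme topology fixes which states exist, which transitions connect them and
which rates are free.  Fitting adjusts the free microscopic rates so that the
eigenvalues of the kinetic matrix reproduce the apparent rates of the global
exponential fit and the model b-spectra (bs = E x W, degenerate eigenvector
columns combined) reproduce the measured ones.  Because the conductive and
nonconductive cycles complement each other, the b-spectra targeted when
fitting the nonconductive cycle are bsf = bs - E x W_cy1, i.e. the measured
b-spectra minus the contribution of the already-fixed conductive cycle.

Rates fixed by convention rather than by the fit -- the spectrally silent
channel-opening rate (taken from the current rise) and the late-ms recovery
rate assigned to all slow branches -- enter as fixed slots.  Equality
constraints between rates are expressed by transitions sharing one slot.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (BSpectra, EigenSolution, KineticScheme, Transition,
                       build_kinetic_matrix, compute_b_spectra, eigen_solve)
from .spectral import SpectralBasis

__all__ = [
    "SchemeTopology",
    "FitResult",
    "topology_catalog",
    "load_topology",
    "instantiate_scheme",
    "cycle2_target_b",
    "fit_scheme_rates",
    "classify_equilibrium_vs_branching",
    "EquilibriumBranchingReport",
]

#: A successful fit must match every target apparent rate this closely.
RATE_MATCH_RTOL = 5e-3
#: Model b-spectrum groups below this relative norm are spectrally silent.
SILENT_NORM_RTOL = 1e-10


@dataclass(frozen=True)
class SchemeTopology:
    """A scheme template with named rate slots.

    Transitions sharing a slot name are constrained to the same rate; slots in
    ``fixed_slots`` must be supplied at fit time (convention-fixed rates), the
    remaining slots are free parameters.
    """

    name: str
    scheme_class: str  # "equilibrium" | "branching" | "chain"
    cycle: str
    states: tuple[str, ...]
    transitions: tuple[tuple[str, str, str], ...]  # (from, to, slot)
    conductive: tuple[str, ...]
    state_to_form: dict[str, str]
    fixed_slots: tuple[str, ...]
    description: str = ""

    @property
    def slots(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, _, s in self.transitions:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    @property
    def free_slots(self) -> tuple[str, ...]:
        return tuple(s for s in self.slots if s not in self.fixed_slots)

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name, "class": self.scheme_class, "cycle": self.cycle,
            "states": list(self.states),
            "transitions": [list(t) for t in self.transitions],
            "conductive": list(self.conductive),
            "state_to_form": self.state_to_form,
            "fixed_slots": list(self.fixed_slots),
            "description": self.description,
        }, indent=2)


def _catalog_doc() -> dict:
    with importlib.resources.files("acrcycles.data").joinpath(
            "topologies.json").open() as f:
        return json.load(f)


def _from_doc(d: dict) -> SchemeTopology:
    return SchemeTopology(
        name=d["name"], scheme_class=d["class"], cycle=d["cycle"],
        states=tuple(d["states"]),
        transitions=tuple(tuple(t) for t in d["transitions"]),
        conductive=tuple(d["conductive"]),
        state_to_form=dict(d["state_to_form"]),
        fixed_slots=tuple(d["fixed_slots"]),
        description=d.get("description", ""),
    )


def load_topology(name: str) -> SchemeTopology:
    doc = _catalog_doc()
    if name not in doc["topologies"]:
        raise KeyError(f"unknown topology {name!r}")
    return _from_doc(doc["topologies"][name])


def topology_catalog(protein_condition: str = "generic") -> list[SchemeTopology]:
    """Scheme templates applicable to a protein/pH condition.

    Known labels: wt_ph55, wt_ph74, wt_ph85, a75e_ph74, d234n_ph74,
    d234n_ph45, s97e_ph74, s97e_ph56, generic.  Unknown labels fall back to
    the generic catalog with a warning.
    """
    doc = _catalog_doc()
    cond = doc["conditions"]
    if protein_condition not in cond:
        warnings.warn(f"unknown condition {protein_condition!r}; "
                      "returning the generic catalog")
        protein_condition = "generic"
    return [_from_doc(doc["topologies"][n]) for n in cond[protein_condition]]


def instantiate_scheme(topology: SchemeTopology, rates: dict[str, float],
                       initial: dict[str, float]) -> KineticScheme:
    """Bind slot rates and initial populations into a concrete scheme."""
    missing = [s for s in topology.slots if s not in rates]
    if missing:
        raise ValueError(f"missing rates for slots {missing}")
    trans = tuple(Transition(a, b, float(rates[slot]))
                  for a, b, slot in topology.transitions)
    return KineticScheme(states=topology.states, transitions=trans,
                         conductive={s: True for s in topology.conductive},
                         initial=dict(initial))


def _structured_starts(topology: SchemeTopology, free: list[str],
                       targets_desc: np.ndarray, cap: int = 24) -> list[np.ndarray]:
    """Deterministic starts assigning slot groups to target apparent rates.

    Reversible pairs of slots (forward/backward between the same two states)
    act as fast pre-equilibria: each pair is seeded at half of one of the
    fastest target rates, over permutations of that assignment.  The remaining
    free slots are grouped by source state (a branching step shares one
    apparent rate among its branches) and each group is seeded at one of the
    remaining target rates, again over permutations.  Enumerating these
    assignments covers the discrete labeling modes that arise when isospectral
    states exchange kinetic roles, which trap purely local fits.
    """
    import itertools

    trans_map = {(a, b): s for a, b, s in topology.transitions}
    pairs, seen = [], set()
    for (a, b), s in trans_map.items():
        if (a, b) in seen:
            continue
        s2 = trans_map.get((b, a))
        if s2 is not None and s in free and s2 in free:
            pairs.append((s, s2))
            seen.update([(a, b), (b, a)])
    paired = {s for p in pairs for s in p}
    groups: dict[str, list[str]] = {}
    group_order: list[str] = []
    for a, _, s in topology.transitions:
        if s in free and s not in paired:
            if a not in groups:
                groups[a] = []
                group_order.append(a)
            groups[a].append(s)
    npair = len(pairs)
    if (npair == 0 and not group_order) or npair > targets_desc.size:
        return []
    rest = targets_desc[npair:]
    if 0 < len(group_order) <= rest.size:
        group_perms = list(itertools.permutations(range(rest.size),
                                                  len(group_order)))
    else:
        group_perms = [None]
    starts = []
    for pperm in (itertools.permutations(range(npair)) if npair else [()]):
        for gperm in group_perms:
            if len(starts) >= cap:
                return starts
            x0 = {}
            for (sf, sb), ti in zip(pairs, pperm):
                x0[sf] = x0[sb] = targets_desc[ti] / 2.0
            if gperm is None:
                pool = rest if rest.size else targets_desc
                gm = float(np.exp(np.mean(np.log(pool))))
                for a in group_order:
                    for s in groups[a]:
                        x0[s] = gm
            else:
                for a, ti in zip(group_order, gperm):
                    for s in groups[a]:
                        x0[s] = rest[ti] / len(groups[a])
            starts.append(np.log10(np.array([x0[s] for s in free])))
    return starts


def _match_groups(target_eigs: np.ndarray, model_eigs: np.ndarray,
                  scale: float) -> list[int]:
    """Index of the model group closest (in log magnitude) to each target."""
    out = []
    for lam in target_eigs:
        if abs(lam) < 1e-9 * scale:
            zero = np.where(np.abs(model_eigs) < 1e-9 * scale)[0]
            if zero.size == 0:
                raise ValueError("target has a non-decaying component but the "
                                 "model has no zero eigenvalue")
            out.append(int(zero[0]))
        else:
            nz = np.abs(model_eigs) > 1e-9 * scale
            if not nz.any():
                raise ValueError("model has no decaying eigencomponent")
            d = np.abs(np.log(np.abs(model_eigs[nz])) - np.log(abs(lam)))
            out.append(int(np.flatnonzero(nz)[np.argmin(d)]))
    return out


def cycle2_target_b(bs_total: BSpectra, cycle1_solution: EigenSolution,
                    basis: SpectralBasis, state_to_form: dict[str, str],
                    rate_rtol: float = 1e-6,
                    unmatched_tol: float = 0.05) -> BSpectra:
    """Target b-spectra for the nonconductive cycle: bsf = bs - E x W_cy1.

    Every non-silent degeneracy group of the conductive-cycle solution must
    match (within ``rate_rtol``) one of the target eigenvalues; its spectrum
    is subtracted from that group's column.  A group that matches no target
    rate is skipped with a warning if its norm is below ``unmatched_tol``
    times the data norm: the spectrally-silent channel-opening step leaks a
    small amplitude into downstream states (the products formed during the
    opening), which the apparent-rate fit never resolves.  Larger unmatched
    groups raise an error.
    """
    b1 = compute_b_spectra(basis, cycle1_solution, state_to_form)
    out = bs_total.spectra.copy()
    data_norm = float(np.linalg.norm(bs_total.spectra))
    scale = max(np.max(np.abs(bs_total.eigenvalues)),
                np.max(np.abs(b1.eigenvalues)), 1.0)
    for k, lam in enumerate(b1.eigenvalues):
        col = b1.spectra[:, k]
        norm = float(np.linalg.norm(col))
        if norm <= SILENT_NORM_RTOL * max(data_norm, 1e-300):
            continue  # spectrally silent component (e.g. the K->O step)
        if abs(lam) < 1e-9 * scale:
            cand = np.where(np.abs(bs_total.eigenvalues) < 1e-9 * scale)[0]
        else:
            rel = np.abs(bs_total.eigenvalues - lam) / abs(lam)
            cand = np.where(rel < rate_rtol)[0]
        if cand.size == 0 and norm <= unmatched_tol * max(data_norm, 1e-300):
            warnings.warn(
                f"conductive-cycle eigenvalue {lam:.6g} s^-1 matches no "
                f"target rate; its small spectrum (relative norm "
                f"{norm / data_norm:.2e}) is dropped")
            continue
        if cand.size != 1:
            raise ValueError(
                f"degeneracy-group mismatch: conductive-cycle eigenvalue "
                f"{lam:.6g} s^-1 matches {cand.size} target rates")
        out[:, int(cand[0])] -= col
    return BSpectra(eigenvalues=bs_total.eigenvalues.copy(), spectra=out)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a microscopic-rate fit for one topology."""

    topology_name: str
    scheme_class: str
    rates: dict[str, float]
    eigenvalues: np.ndarray
    b_spectra: BSpectra | None
    objective: float
    success: bool
    per_target_rel_err: np.ndarray
    b_residual_rms: float = np.inf
    non_identifiable: bool = False
    null_directions: np.ndarray | None = None
    message: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "topology": self.topology_name, "class": self.scheme_class,
            "rates": self.rates, "objective": self.objective,
            "success": self.success,
            "per_target_rel_err": list(map(float, self.per_target_rel_err)),
            "non_identifiable": self.non_identifiable,
            "message": self.message,
        }, indent=2)


def fit_scheme_rates(topology: SchemeTopology, target_rates, target_b: BSpectra,
                     basis: SpectralBasis, initial: dict[str, float],
                     fixed_rates: dict[str, float] | None = None,
                     state_to_form: dict[str, str] | None = None,
                     n_starts: int = 16, seed: int = 0,
                     rate_weight: float | None = None,
                     b_residual_tol: float | None = None,
                     n_hops: int = 12, max_nfev: int = 400) -> FitResult:
    """Fit the free microscopic rates of a topology.

    Minimizes a weighted sum of squared relative eigenvalue errors (one term
    per target apparent rate) and b-spectra residuals, over log-rates with
    deterministic multi-start.  Ties (objective within 1e-9 relative) are
    broken by the smaller rate-vector norm.  The Jacobian at the optimum is
    inspected for flat directions (non-identifiable rate combinations).
    """
    fixed_rates = dict(fixed_rates or {})
    mapping = dict(state_to_form or topology.state_to_form)
    target_rates = np.asarray(target_rates, dtype=float)
    if not np.all(np.isfinite(target_rates)) or np.any(target_rates <= 0):
        raise ValueError("target rates must be positive and finite")
    free = [s for s in topology.free_slots if s not in fixed_rates]
    missing = [s for s in topology.fixed_slots if s not in fixed_rates]
    if missing:
        raise ValueError(f"fixed slots {missing} need values")
    n_b = target_b.spectra.size
    n_r = target_rates.size
    # balance: equal contribution per term at equal relative error
    if rate_weight is None:
        rate_weight = np.sqrt(n_b / n_r)
    b_scale = max(float(np.max(np.abs(target_b.spectra))), 1e-300)
    n_res = n_r + n_b
    scale = float(np.max(np.abs(target_b.eigenvalues)))

    # targets sorted fastest first (zero / non-decaying column last), the same
    # order eigen_solve produces, so groups pair positionally when counts agree
    t_order = np.argsort(-target_rates)
    rates_sorted = target_rates[t_order]

    def evaluate(logk):
        rates = dict(fixed_rates)
        rates.update({s: 10.0 ** v for s, v in zip(free, logk)})
        scheme = instantiate_scheme(topology, rates, initial)
        sol = eigen_solve(build_kinetic_matrix(scheme), scheme.c0())
        bs = compute_b_spectra(basis, sol, mapping)
        model_nz = bs.eigenvalues[np.abs(bs.eigenvalues) > 1e-9 * scale]
        if model_nz.size == rates_sorted.size:
            matched = np.abs(model_nz[np.argsort(-np.abs(model_nz))])
        else:
            idx = _match_groups(-rates_sorted, bs.eigenvalues, scale)
            matched = np.abs(bs.eigenvalues[idx])
        rate_res = (matched - rates_sorted) / rates_sorted
        if bs.n_groups == target_b.n_groups:
            b_cols = np.arange(bs.n_groups)
        else:
            b_cols = np.asarray(
                _match_groups(target_b.eigenvalues, bs.eigenvalues, scale))
        b_res = (bs.spectra[:, b_cols] - target_b.spectra) / b_scale
        return rates, sol, bs, rate_res, b_res

    def residual(logk):
        try:
            _, _, _, rate_res, b_res = evaluate(logk)
        except (ValueError, np.linalg.LinAlgError):
            return np.full(n_res, 1e3)
        return np.concatenate([rate_weight * rate_res, b_res.ravel()])

    lo = np.log10(target_rates.min()) - 1.5
    hi = np.log10(target_rates.max()) + 1.5
    rng = np.random.default_rng(seed)
    log_targets = np.log10(rates_sorted)
    structured = ([np.clip(x, lo, hi) for x in
                   _structured_starts(topology, free, rates_sorted)]
                  if len(free) > 0 else [])
    best, best_norm = None, np.inf
    for k in range(max(1, len(structured) + n_starts)):
        if len(free) == 0:
            x0 = np.zeros(0)
        elif k < len(structured):
            x0 = structured[k]
        elif k == len(structured):
            x0 = np.full(len(free), 0.5 * (lo + hi))
        else:
            # microscopic rates are of the magnitude of the apparent rates:
            # seed each slot near a randomly chosen target rate
            x0 = np.clip(rng.choice(log_targets, len(free))
                         + rng.uniform(-0.7, 0.7, len(free)), lo, hi)
        try:
            sol = least_squares(residual, x0, method="trf", bounds=(lo, hi),
                                max_nfev=max_nfev)
        except Exception:
            continue
        norm = float(np.linalg.norm(sol.x))
        better = best is None or sol.cost < best.cost * (1 - 1e-9)
        tie = best is not None and abs(sol.cost - best.cost) <= 1e-9 * max(
            best.cost, 1e-300) and norm < best_norm
        if better or tie:
            best, best_norm = sol, norm
        if len(free) == 0:
            break
    if best is None:
        raise RuntimeError(f"no fit converged for topology {topology.name}")

    # basin-hop polish: restart from the best point with pair swaps (exchange
    # both rates of two reversible pairs at once -- the move between labeling
    # modes of isospectral states, which create discrete near-equivalent
    # minima), coordinate transpositions, or random perturbations
    trans_map = {(a, b): s for a, b, s in topology.transitions}
    pair_idx = []
    seen_pairs = set()
    for (a, b), s in trans_map.items():
        s2 = trans_map.get((b, a))
        if s2 is not None and (b, a) not in seen_pairs and s in free and s2 in free:
            pair_idx.append((free.index(s), free.index(s2)))
            seen_pairs.update([(a, b), (b, a)])
    if len(free) >= 2:
        for h in range(n_hops):
            x0 = best.x.copy()
            mode = h % 3
            if mode == 0 and len(pair_idx) >= 2:
                ks = rng.choice(len(pair_idx), 2, replace=False)
                (i1, j1), (i2, j2) = pair_idx[ks[0]], pair_idx[ks[1]]
                x0[i1], x0[i2] = x0[i2], x0[i1]
                x0[j1], x0[j2] = x0[j2], x0[j1]
            elif mode <= 1:
                i, j = rng.choice(len(free), 2, replace=False)
                x0[i], x0[j] = x0[j], x0[i]
            else:
                x0 = np.clip(x0 + rng.normal(0, 0.6, len(free)), lo, hi)
            try:
                sol = least_squares(residual, x0, method="trf",
                                    bounds=(lo, hi), max_nfev=max_nfev)
            except Exception:
                continue
            norm = float(np.linalg.norm(sol.x))
            if (sol.cost < best.cost * (1 - 1e-9)
                    or (abs(sol.cost - best.cost) <= 1e-9 * max(best.cost, 1e-300)
                        and norm < best_norm)):
                best, best_norm = sol, norm

    try:
        rates, eig_sol, bs, rate_res, b_res = evaluate(best.x)
        eigenvalues = eig_sol.eigenvalues
    except (ValueError, np.linalg.LinAlgError) as exc:
        return FitResult(topology.name, topology.scheme_class,
                         dict(fixed_rates), np.array([]), None,
                         float(2 * best.cost), False,
                         np.full(n_r, np.inf), message=f"evaluation failed: {exc}")

    per_target = np.abs(rate_res)
    b_rms = float(np.sqrt(np.mean(b_res ** 2))) * b_scale
    if b_residual_tol is None:
        b_residual_tol = 0.01 * b_scale
    success = bool(np.all(per_target < RATE_MATCH_RTOL)
                   and b_rms <= b_residual_tol)
    # flat directions of the objective => non-identifiable rate combinations
    non_ident, null_dirs, msg = False, None, ""
    if len(free) > 0:
        sv = np.linalg.svd(best.jac, compute_uv=False)
        _, _, vt = np.linalg.svd(best.jac)
        flat = sv < 1e-8 * max(sv.max(), 1e-300)
        if flat.any():
            non_ident = True
            null_dirs = vt[flat.size - int(flat.sum()):]
            msg = ("flat objective directions: some rates (e.g. spectrally "
                   "silent steps) are not determined by the spectra")
    at_bound = len(free) > 0 and bool(
        np.any(np.isclose(best.x, lo)) or np.any(np.isclose(best.x, hi)))
    if success and at_bound:
        success = False
        msg = (msg + "; " if msg else "") + "fitted rate at optimizer bound"
    return FitResult(topology_name=topology.name,
                     scheme_class=topology.scheme_class,
                     rates={k: float(v) for k, v in rates.items()},
                     eigenvalues=eigenvalues, b_spectra=bs,
                     objective=float(2 * best.cost), success=success,
                     per_target_rel_err=per_target, b_residual_rms=b_rms,
                     non_identifiable=non_ident, null_directions=null_dirs,
                     message=msg)


@dataclass(frozen=True)
class EquilibriumBranchingReport:
    """Bookkeeping comparison of equilibrium vs branching fits.

    Both classes can describe the apparent kinetics equally well (the data do
    not distinguish them); equilibrium schemes between open and closed channel
    states are nevertheless rejected on mechanistic grounds -- repeated
    opening/closing within one reaction chain is physically unrealistic.  This
    is a classification, not a statistical test.
    """

    best_objective: dict[str, float]
    kinetically_equivalent: bool
    mechanistically_rejected: str
    notes: tuple[str, ...] = field(default_factory=tuple)


def classify_equilibrium_vs_branching(fit_results) -> EquilibriumBranchingReport:
    results = list(fit_results)
    if not results:
        raise ValueError("no fit results supplied")
    by_class: dict[str, list[FitResult]] = {}
    for r in results:
        cls = "branching" if r.scheme_class in ("branching", "chain") else r.scheme_class
        by_class.setdefault(cls, []).append(r)
    best = {cls: min(r.objective for r in rs) for cls, rs in by_class.items()}
    notes = []
    if "equilibrium" in best and "branching" in best:
        lo, hi = sorted([best["equilibrium"], best["branching"]])
        equivalent = hi <= 2 * max(lo, 1e-300)
    else:
        equivalent = False
        missing = {"equilibrium", "branching"} - set(best)
        notes.append(f"missing comparison class(es): {sorted(missing)}")
    notes.append("equilibrium schemes rejected as channel mechanism: "
                 "open/closed equilibria imply repeated reopening of the "
                 "channel within one reaction chain")
    return EquilibriumBranchingReport(best_objective=best,
                                      kinetically_equivalent=equivalent,
                                      mechanistically_rejected="equilibrium",
                                      notes=tuple(notes))
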