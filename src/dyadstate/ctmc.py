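"""Likelihood, MLE and Wald tests for the 4-state dyad transition model.

The joint cover/exposure process is a continuous-time Markov chain on
states 1-4 with intensities only on the 8 single-fish-move edges.  Each
intensity is log-linear in session-level covariates,

    q_ij(z) = q0_ij * exp(sum_c beta_c,ij * z_c),

so with fully observed trajectories the log-likelihood is

    sum over completed sojourns [ -Lambda_i(z) * t + ln q_ij(z) ]
    + the right-censored final term  -Lambda_i(z) * t_last,

with Lambda_i(z) the exit rate of state i.  On the working scale
(log q0_ij, untransformed coefficients) this separates into eight
independent concave problems, one per edge, each formally a Poisson
regression of the edge's event count on its covariates with the
originating state's sojourn time as exposure.  We solve each by Newton's
method with analytic gradient and Hessian; standard errors come from the
inverse observed information, and 95% intervals are computed on the
working scale and mapped back (exponentiated for baselines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .eventlog import PERMITTED_EDGES, STATES, PairTrajectory
from .metrics import SufficientStats, sufficient_statistics

__all__ = [
    "Edge",
    "IntensityModel",
    "FitResult",
    "WaldResult",
    "log_likelihood",
    "closed_form_intensities",
    "fit_mle",
    "wald_test_coefficient",
    "wald_test_intensity_contrast",
]

Edge = tuple[int, int]

EDGE_INDEX: dict[Edge, int] = {e: k for k, e in enumerate(PERMITTED_EDGES)}

#: floor used for edges with no observed events (kept out of the information matrix)
DEGENERATE_RATE_FLOOR = 1e-8

_Z975 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class IntensityModel:
    """Baseline intensities plus log-linear covariate effects on each edge.

    ``baseline[(i, j)]`` is q0_ij in 1/second; ``effects[name][(i, j)]`` is the
    dimensionless coefficient of covariate ``name`` on edge (i, j).  Edges
    absent from an effect map have coefficient 0.
    """

    baseline: dict[Edge, float]
    effects: dict[str, dict[Edge, float]] = field(default_factory=dict)

    def __post_init__(self):
        for e, q in self.baseline.items():
            if e not in EDGE_INDEX:
                raise ValueError(f"not a permitted edge: {e}")
            if not (q > 0) or not math.isfinite(q):
                raise ValueError(f"baseline intensity for {e} must be finite > 0")
        for name, coefs in self.effects.items():
            for e in coefs:
                if e not in EDGE_INDEX:
                    raise ValueError(f"not a permitted edge: {e} (effect {name})")

    def intensity(self, edge: Edge, covariates: Mapping[str, float] | None = None) -> float:
        """q_ij at the given covariate values (missing covariate -> error)."""
        q = self.baseline.get(edge, 0.0)
        if q == 0.0:
            return 0.0
        log_q = math.log(q)
        covariates = covariates or {}
        for name, coefs in self.effects.items():
            beta = coefs.get(edge, 0.0)
            if beta != 0.0 and name not in covariates:
                raise KeyError(f"missing covariate {name!r}")
            log_q += beta * float(covariates.get(name, 0.0))
        value = math.exp(log_q)
        if not math.isfinite(value):
            raise ValueError(f"non-finite intensity on edge {edge}")
        return value

    def rates(self, covariates: Mapping[str, float] | None = None) -> dict[Edge, float]:
        """All permitted-edge intensities at the given covariates."""
        return {
            e: self.intensity(e, covariates) for e in self.baseline
        }

    def exit_rate(self, state: int, covariates: Mapping[str, float] | None = None) -> float:
        """Lambda_i: total rate of leaving ``state``."""
        return sum(
            self.intensity(e, covariates) for e in self.baseline if e[0] == state
        )


def log_likelihood(
    model: IntensityModel,
    trajectory: PairTrajectory,
    covariates: Mapping[str, float] | None = None,
) -> float:
    """Exact log-likelihood of one fully observed trajectory.

    Sums ``-Lambda_i * t + ln q_ij`` over completed sojourns plus the
    censored final term ``-Lambda_i * t_last``.
    """
    covariates = covariates or {}
    q = {e: model.intensity(e, covariates) for e in PERMITTED_EDGES if e in model.baseline}
    lam = {s: sum(v for e, v in q.items() if e[0] == s) for s in STATES}
    ll = 0.0
    state = trajectory.initial_state
    prev = 0.0
    for ev in trajectory.events:
        rate = q.get(ev.edge, 0.0)
        if rate <= 0.0:
            return -math.inf
        ll += -lam[state] * (ev.time - prev) + math.log(rate)
        state = ev.to_state
        prev = ev.time
    ll += -lam[state] * (trajectory.duration - prev)
    return ll


def closed_form_intensities(
    stats: SufficientStats,
) -> dict[Edge, float | None]:
    """Covariate-free MLE: q_ij = N_ij / T_i.

    States never visited (T_i == 0) yield ``None`` entries for their outgoing
    edges; N_ij > 0 with T_i == 0 is inconsistent and raises.
    """
    out: dict[Edge, float | None] = {}
    for e in PERMITTED_EDGES:
        n = stats.counts[e]
        t = stats.sojourn[e[0]]
        if t <= 0.0:
            if n > 0:
                raise ValueError(
                    f"inconsistent statistics: N{e}={n} with zero sojourn in {e[0]}"
                )
            out[e] = None
        else:
            out[e] = n / t
    return out


@dataclass
class WaldResult:
    """Two-sided Wald test on the working scale."""

    estimate: float
    se: float
    z: float
    p: float
    null_value: float = 0.0

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    @property
    def direction(self) -> int:
        """Sign of (estimate - null): -1, 0 or +1."""
        d = self.estimate - self.null_value
        return (d > 0) - (d < 0)


@dataclass
class FitResult:
    """MLE output: estimates, working-scale uncertainty, and diagnostics.

    ``params`` lists the free working-scale parameters in order as
    ``("baseline", edge)`` / ``(covariate, edge)`` keys; ``cov`` is their
    covariance matrix from the inverse observed information.  ``centering``
    records the value subtracted from each covariate before fitting, so the
    baselines refer to a session at those covariate values.
    """

    estimates: IntensityModel
    design: dict[str, tuple[Edge, ...]]
    params: list[tuple[str, Edge]]
    working: np.ndarray
    cov: np.ndarray
    log_lik: float
    converged: bool
    n_iter: int
    unidentifiable: set[tuple[str, Edge]] = field(default_factory=set)
    degenerate_edges: set[Edge] = field(default_factory=set)
    centering: dict[str, float] = field(default_factory=dict)
    grad_norm: float = float("nan")

    def _index(self, key: tuple[str, Edge]) -> int:
        try:
            return self.params.index(key)
        except ValueError:
            raise KeyError(f"parameter {key} not free (unidentifiable or degenerate)")

    def se_working(self, name: str, edge: Edge) -> float:
        k = self._index((name, edge))
        return math.sqrt(self.cov[k, k])

    def estimate_working(self, name: str, edge: Edge) -> float:
        return float(self.working[self._index((name, edge))])

    def ci95(self, name: str, edge: Edge) -> tuple[float, float]:
        """95% CI on the natural scale (rates for baselines, raw coefficients)."""
        est = self.estimate_working(name, edge)
        se = self.se_working(name, edge)
        lo, hi = est - _Z975 * se, est + _Z975 * se
        if name == "baseline":
            return math.exp(lo), math.exp(hi)
        return lo, hi

    def is_identifiable(self, name: str, edge: Edge) -> bool:
        return (name, edge) in set(self.params)

    def to_records(self, category: str = "") -> list[dict]:
        """Flatten to CSV-ready records (one per parameter, incl. fixed ones)."""
        rows = []
        keys = [("baseline", e) for e in PERMITTED_EDGES]
        for name in self.design:
            keys += [(name, e) for e in self.design[name]]
        for name, e in keys:
            ident = self.is_identifiable(name, e)
            if ident:
                est_w = self.estimate_working(name, e)
                se = self.se_working(name, e)
                lo, hi = self.ci95(name, e)
                est = math.exp(est_w) if name == "baseline" else est_w
                p = wald_test_coefficient(self, name, e).p if name != "baseline" else float("nan")
            else:
                est = self.estimates.baseline.get(e, 0.0) if name == "baseline" else 0.0
                se = lo = hi = p = float("nan")
            rows.append(
                {
                    "category": category,
                    "parameter": name,
                    "edge": f"{e[0]}->{e[1]}",
                    "estimate": est,
                    "se_working": se,
                    "ci95_lo": lo,
                    "ci95_hi": hi,
                    "p_value": p,
                    "identifiable": ident,
                }
            )
        return rows


def _aggregate_conditions(
    trajectories: Sequence[PairTrajectory],
    covariates: Sequence[Mapping[str, float]],
    names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool sufficient statistics by distinct covariate vector.

    Returns (X, N, T): covariate matrix (n_cond, n_names), event counts
    (n_cond, 8) and sojourn totals (n_cond, 4).
    """
    pooled: dict[tuple[float, ...], tuple[np.ndarray, np.ndarray]] = {}
    for traj, cov in zip(trajectories, covariates):
        missing = [n for n in names if n not in cov]
        if missing:
            raise KeyError(
                f"trajectory {traj.pair_id}/{traj.session} missing covariates {missing}"
            )
        key = tuple(float(cov[n]) for n in names)
        stats = sufficient_statistics(traj)
        n_vec = np.array([stats.counts[e] for e in PERMITTED_EDGES], dtype=float)
        t_vec = np.array([stats.sojourn[s] for s in STATES], dtype=float)
        if key in pooled:
            pooled[key] = (pooled[key][0] + n_vec, pooled[key][1] + t_vec)
        else:
            pooled[key] = (n_vec, t_vec)
    keys = list(pooled)
    X = np.array(keys, dtype=float).reshape(len(keys), len(names))
    N = np.stack([pooled[k][0] for k in keys])
    T = np.stack([pooled[k][1] for k in keys])
    return X, N, T


def _edge_identifiable(x: np.ndarray, n: np.ndarray, t: np.ndarray) -> bool:
    """Can a coefficient with condition-level values ``x`` be estimated on
    an edge with counts ``n`` and exposures ``t``?

    Binary covariates need events at both levels; continuous covariates need
    variation among exposed conditions.
    """
    exposed = t > 0
    vals = x[exposed]
    if vals.size == 0 or np.ptp(vals) == 0.0:
        return False
    if set(np.unique(x)) <= {0.0, 1.0}:
        return n[exposed & (x == 0.0)].sum() > 0 and n[exposed & (x == 1.0)].sum() > 0
    return True


def fit_mle(
    trajectories: Sequence[PairTrajectory],
    covariates: Sequence[Mapping[str, float]] | None = None,
    design: Mapping[str, Sequence[Edge]] | None = None,
    center: Sequence[str] = (),
    gtol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """Maximize the pooled log-likelihood over (log q0_ij, coefficients).

    Parameters
    ----------
    trajectories:
        Fully observed pair-session trajectories (pooled into one fit).
    covariates:
        One mapping per trajectory supplying every covariate the design
        references (e.g. ``{"satiated": 1}``).  Defaults to all-empty.
    design:
        Which covariates act on which edges, e.g.
        ``{"satiated": PERMITTED_EDGES}``.  Defaults to no covariates.
    center:
        Covariate names to centre at their trajectory-weighted sample mean
        before fitting (recorded in ``FitResult.centering``).

    Edges with no events anywhere are fixed at a floor rate and flagged;
    coefficients that the data cannot identify (an edge with no events at one
    level of a binary covariate, or no covariate variation) are fixed at 0,
    flagged, and excluded from the information matrix.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    if covariates is None:
        covariates = [{} for _ in trajectories]
    if len(covariates) != len(trajectories):
        raise ValueError("covariates must match trajectories one-to-one")
    design = {name: tuple(edges) for name, edges in (design or {}).items()}
    for name, edges in design.items():
        for e in edges:
            if e not in EDGE_INDEX:
                raise ValueError(f"design references forbidden edge {e} ({name})")
    names = list(design)

    X, N, T = _aggregate_conditions(trajectories, covariates, names)
    centering: dict[str, float] = {}
    for name in center:
        if name not in design:
            raise ValueError(f"cannot centre {name!r}: not in design")
        j = names.index(name)
        w = T.sum(axis=1)
        mean = float(np.average(X[:, j], weights=w))
        X[:, j] -= mean
        centering[name] = mean

    total_n = N.sum(axis=0)
    params: list[tuple[str, Edge]] = []
    unident: set[tuple[str, Edge]] = set()
    degenerate: set[Edge] = set()

    # per-edge design: list of (param_key, condition_values) columns
    edge_cols: dict[Edge, list[tuple[tuple[str, Edge], np.ndarray]]] = {}
    ones = np.ones(X.shape[0])
    for k, e in enumerate(PERMITTED_EDGES):
        t_e = T[:, e[0] - 1]
        if total_n[k] == 0:
            degenerate.add(e)
            for name in names:
                if e in design[name]:
                    unident.add((name, e))
            continue
        cols = [(("baseline", e), ones)]
        for j, name in enumerate(names):
            if e not in design[name]:
                continue
            if _edge_identifiable(X[:, j], N[:, k], t_e):
                cols.append(((name, e), X[:, j]))
            else:
                unident.add((name, e))
        edge_cols[e] = cols
        params.extend(key for key, _ in cols)

    # independent concave Newton solve per edge
    working = np.zeros(len(params))
    cov = np.zeros((len(params), len(params)))
    offset = 0
    converged = True
    n_iter_total = 0
    grad_norm_max = 0.0
    for k, e in enumerate(PERMITTED_EDGES):
        if e not in edge_cols:
            continue
        cols = edge_cols[e]
        Xe = np.column_stack([c for _, c in cols])
        n_e = N[:, k]
        t_e = T[:, e[0] - 1]
        keep = t_e > 0
        Xe, n_e, t_e = Xe[keep], n_e[keep], t_e[keep]
        crude = max(n_e.sum() / t_e.sum(), 1e-6)
        theta = np.zeros(Xe.shape[1])
        theta[0] = math.log(crude)

        def loglik(th: np.ndarray) -> float:
            eta = Xe @ th
            return float(n_e @ eta - t_e @ np.exp(eta))

        ll = loglik(theta)
        it = 0
        gnorm = math.inf
        for it in range(1, max_iter + 1):
            mu = t_e * np.exp(Xe @ theta)
            grad = Xe.T @ (n_e - mu)
            gnorm = float(np.max(np.abs(grad)))
            if gnorm <= gtol:
                break
            info = (Xe.T * mu) @ Xe
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            gain = float(grad @ step)  # predicted ascent, >= 0 by concavity
            if gain <= 1e-12 * max(1.0, abs(ll)):
                # predicted improvement below objective float resolution:
                # take the pure Newton step (locally convergent, concave)
                theta = theta + step
                ll = loglik(theta)
                continue
            # Armijo backtracking for globalization of large steps
            scale = 1.0
            while scale > 1e-10:
                cand = theta + scale * step
                ll_new = loglik(cand)
                if ll_new >= ll + 1e-4 * scale * gain - 1e-12 * max(1.0, abs(ll)):
                    theta, ll = cand, ll_new
                    break
                scale *= 0.5
            else:
                break
        n_iter_total = max(n_iter_total, it)
        grad_norm_max = max(grad_norm_max, gnorm)
        if gnorm > gtol:
            converged = False
        mu = t_e * np.exp(Xe @ theta)
        info = (Xe.T * mu) @ Xe
        try:
            block_cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            block_cov = np.linalg.pinv(info)
            converged = False
        kdim = Xe.shape[1]
        working[offset : offset + kdim] = theta
        cov[offset : offset + kdim, offset : offset + kdim] = block_cov
        offset += kdim

    # assemble the natural-scale estimates
    baseline: dict[Edge, float] = {}
    effects: dict[str, dict[Edge, float]] = {name: {} for name in names}
    for key, value in zip(params, working):
        name, e = key
        if name == "baseline":
            baseline[e] = math.exp(value)
        else:
            effects[name][e] = float(value)
    for e in degenerate:
        baseline[e] = DEGENERATE_RATE_FLOOR
    model = IntensityModel(baseline=baseline, effects=effects)

    # pooled log-likelihood at the MLE (excluding floor-rate edges' sojourn
    # contribution would be wrong -- they contribute via Lambda, tiny)
    ll_total = 0.0
    for traj, covs in zip(trajectories, covariates):
        z = {n: float(covs.get(n, 0.0)) - centering.get(n, 0.0) for n in names}
        ll_total += log_likelihood(model, traj, z)

    return FitResult(
        estimates=model,
        design=design,
        params=params,
        working=working,
        cov=cov,
        log_lik=ll_total,
        converged=converged,
        n_iter=n_iter_total,
        unidentifiable=unident,
        degenerate_edges=degenerate,
        centering=centering,
        grad_norm=grad_norm_max,
    )


def _two_sided_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def wald_test_coefficient(
    fit: FitResult, covariate: str, edge: Edge, null_value: float = 0.0
) -> WaldResult:
    """Two-sided Wald test of a covariate coefficient against ``null_value``."""
    if (covariate, edge) in fit.unidentifiable:
        raise ValueError(f"parameter ({covariate}, {edge}) is unidentifiable")
    est = fit.estimate_working(covariate, edge)
    se = fit.se_working(covariate, edge)
    z = (est - null_value) / se
    return WaldResult(estimate=est, se=se, z=z, p=_two_sided_p(z), null_value=null_value)


def wald_test_intensity_contrast(
    fit: FitResult, edge_a: Edge, edge_b: Edge
) -> WaldResult:
    """Delta-method Wald test of log q0(edge_a) - log q0(edge_b) = 0.

    The reported estimate is the log-rate difference; its sign indicates the
    direction (negative means q_a < q_b).
    """
    for e in (edge_a, edge_b):
        if e in fit.degenerate_edges or not fit.is_identifiable("baseline", e):
            raise ValueError(f"edge {e} baseline is unidentifiable")
    ia = fit._index(("baseline", edge_a))
    ib = fit._index(("baseline", edge_b))
    diff = float(fit.working[ia] - fit.working[ib])
    var = float(fit.cov[ia, ia] + fit.cov[ib, ib] - 2.0 * fit.cov[ia, ib])
    se = math.sqrt(var)
    z = diff / se
    return WaldResult(estimate=diff, se=se, z=z, p=_two_sided_p(z))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
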