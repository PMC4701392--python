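"""Equilibrium unfolding models under the linear extrapolation method (LEM).

Implements the two-state Santoro–Bolen model and its sequential multi-state
generalisation (here up to four states, N <-> I1 <-> I2 <-> U), evaluation of
Boltzmann state populations, and bounded trust-region global fitting with
seeded multi-start.  Free energies are in kcal/mol, m-values in
kcal mol^-1 M^-1, so that midpoints dG/m come out in molar denaturant.

Under LEM the free energy of each transition varies linearly with denaturant
concentration D: dG_i(D) = dG_i^0 - m_i * D.  The observed signal is the
population-weighted mean of the state signals; end states may carry linear
baselines (the classic folded/unfolded baseline slopes), intermediates are
taken as flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, special, stats

from .errors import (
    ConvergenceError,
    InvalidMValueError,
    ModelSelectionError,
    NonIdentifiableError,
    StateOrderingError,
)
from .spectra import DenaturationCurve

__all__ = [
    "ThermoConstants",
    "TwoStateParams",
    "ThreeStateParams",
    "FourStateParams",
    "FitOptions",
    "FitResult",
    "ModelSelection",
    "eval_two_state",
    "eval_three_state",
    "eval_four_state",
    "state_fractions",
    "fit_two_state",
    "fit_three_state",
    "fit_four_state",
    "midpoints",
    "total_free_energy",
    "model_select",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987e-3


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature entering RT (kcal/mol)."""

    R: float = R_KCAL
    T: float = 298.15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class TwoStateParams:
    """Santoro–Bolen two-state parameters.

    dG0 is the unfolding free energy at zero denaturant, m its denaturant
    dependence; yn/yu are the native/unfolded signal intercepts and mf/mu
    the corresponding baseline slopes (signal units per M).
    """

    dG0: float
    m: float
    yn: float
    yu: float
    mf: float = 0.0
    mu: float = 0.0

    @property
    def dGs(self) -> tuple[float, ...]:
        return (self.dG0,)

    @property
    def ms(self) -> tuple[float, ...]:
        return (self.m,)


@dataclass
class ThreeStateParams:
    """Sequential three-state (N <-> I <-> U) parameters; intermediate flat."""

    dG1: float
    dG2: float
    m1: float
    m2: float
    yN: float
    yI: float
    yU: float
    sN: float = 0.0
    sU: float = 0.0

    @property
    def dGs(self) -> tuple[float, ...]:
        return (self.dG1, self.dG2)

    @property
    def ms(self) -> tuple[float, ...]:
        return (self.m1, self.m2)

    @property
    def signals(self) -> tuple[float, ...]:
        return (self.yN, self.yI, self.yU)


@dataclass
class FourStateParams:
    """Sequential four-state (N <-> I1 <-> I2 <-> U) parameters.

    Cumulative free energies dG1, dG1+dG2, dG1+dG2+dG3 weight the I1, I2
    and U states.  Intermediate signals are flat; optional sN/sU baseline
    slopes apply to the end states only.
    """

    dG1: float
    dG2: float
    dG3: float
    m1: float
    m2: float
    m3: float
    yN: float
    yI1: float
    yI2: float
    yU: float
    sN: float = 0.0
    sU: float = 0.0

    @property
    def dGs(self) -> tuple[float, ...]:
        return (self.dG1, self.dG2, self.dG3)

    @property
    def ms(self) -> tuple[float, ...]:
        return (self.m1, self.m2, self.m3)

    @property
    def signals(self) -> tuple[float, ...]:
        return (self.yN, self.yI1, self.yI2, self.yU)


AnyParams = Union[TwoStateParams, ThreeStateParams, FourStateParams]


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _sequential_fractions(
    dGs: Sequence[float], ms: Sequence[float], D, RT: float
) -> np.ndarray:
    """Boltzmann fractions of the n+1 states of a sequential n-transition model.

    Returns an array of shape (n_states, *shape(D)).  Computed by a shifted
    softmax over the cumulative exponents so large free energies do not
    overflow.
    """
    D = np.asarray(D, dtype=float)
    cum = np.zeros((len(dGs) + 1,) + D.shape)
    g = np.zeros_like(D)
    for i, (dg, m) in enumerate(zip(dGs, ms), start=1):
        g = g + (dg - m * D) / RT
        cum[i] = -g
    cum -= cum.max(axis=0, keepdims=True)
    w = np.exp(cum)
    return w / w.sum(axis=0, keepdims=True)


def state_fractions(
    p: FourStateParams, D, k: ThermoConstants = ThermoConstants()
) -> np.ndarray:
    """Population fractions (fN, fI1, fI2, fU) at denaturant concentration D.

    Non-negative and summing to 1 for any D; the observed signal equals
    sum(f_i * y_i).
    """
    return _sequential_fractions(p.dGs, p.ms, D, k.RT)


def eval_two_state(p: TwoStateParams, D, k: ThermoConstants = ThermoConstants()):
    """Observed signal of the two-state model at denaturant concentration D.

    Evaluated through a logistic in the transition free energy, which is
    numerically stable for any dG0, m.
    """
    D = np.asarray(D, dtype=float)
    a = (p.dG0 - p.m * D) / k.RT
    fu = special.expit(-a)
    y = (p.yn + p.mf * D) * (1.0 - fu) + (p.yu + p.mu * D) * fu
    return y if y.ndim else float(y)


def _eval_sequential(p, D, k: ThermoConstants):
    D = np.asarray(D, dtype=float)
    f = _sequential_fractions(p.dGs, p.ms, D, k.RT)
    ys = list(p.signals)
    y = f[0] * (ys[0] + p.sN * D)
    for i in range(1, len(ys) - 1):
        y = y + f[i] * ys[i]
    y = y + f[-1] * (ys[-1] + p.sU * D)
    return y if y.ndim else float(y)


def eval_three_state(p: ThreeStateParams, D, k: ThermoConstants = ThermoConstants()):
    """Observed signal of the sequential three-state model."""
    return _eval_sequential(p, D, k)


def eval_four_state(p: FourStateParams, D, k: ThermoConstants = ThermoConstants()):
    """Observed signal of the sequential four-state model.

    The Boltzmann-weighted mean of the four state signals, with cumulative
    free energies dG1, dG1+dG2, dG1+dG2+dG3 weighting I1, I2, U.
    """
    return _eval_sequential(p, D, k)


def midpoints(p: AnyParams) -> list[float]:
    """Transition midpoints [D]_1/2 = dG_i^0 / m_i, one per transition (M)."""
    out = []
    for dg, m in zip(p.dGs, p.ms):
        if m <= 0:
            raise InvalidMValueError(f"invalid m-value: {m}")
        out.append(dg / m)
    return out


def total_free_energy(p: FourStateParams) -> float:
    """Total unfolding free energy dG1 + dG2 + dG3 (kcal/mol)."""
    return float(p.dG1 + p.dG2 + p.dG3)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Knobs for the multi-start trust-region fits."""

    n_starts: int = 20
    seed: int = 0
    max_nfev: int = 2000
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    fit_baseline_slopes: bool = True  # two-state mf/mu; multi-state sN/sU off by default
    fit_end_slopes: bool = False
    weights: Optional[Sequence[float]] = None  # one sigma per curve


@dataclass
class FitResult:
    """Outcome of a (global) unfolding fit.

    ``estimates`` maps parameter names to values — shared thermodynamic
    parameters plus ``yn[i]``-style per-curve signal parameters.
    ``midpoints_M`` are dG_i/m_i of the shared estimates.
    """

    model: str
    estimates: dict
    standard_errors: dict
    covariance: np.ndarray
    param_names: list
    residuals: np.ndarray
    converged: bool
    midpoints_M: list
    n_starts_used: int
    rss: float
    n_obs: int
    aicc: float
    flags: list = field(default_factory=list)
    seed: int = 0

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def params_for_curve(self, i: int = 0) -> AnyParams:
        """Reassemble a parameter object for curve ``i`` of the global fit."""
        e = self.estimates
        if self.model == "two_state":
            return TwoStateParams(
                dG0=e["dG0"], m=e["m"],
                yn=e[f"yn[{i}]"], yu=e[f"yu[{i}]"],
                mf=e.get(f"mf[{i}]", 0.0), mu=e.get(f"mu[{i}]", 0.0),
            )
        if self.model == "three_state":
            return ThreeStateParams(
                dG1=e["dG1"], dG2=e["dG2"], m1=e["m1"], m2=e["m2"],
                yN=e[f"yN[{i}]"], yI=e[f"yI[{i}]"], yU=e[f"yU[{i}]"],
                sN=e.get(f"sN[{i}]", 0.0), sU=e.get(f"sU[{i}]", 0.0),
            )
        return FourStateParams(
            dG1=e["dG1"], dG2=e["dG2"], dG3=e["dG3"],
            m1=e["m1"], m2=e["m2"], m3=e["m3"],
            yN=e[f"yN[{i}]"], yI1=e[f"yI1[{i}]"], yI2=e[f"yI2[{i}]"],
            yU=e[f"yU[{i}]"],
            sN=e.get(f"sN[{i}]", 0.0), sU=e.get(f"sU[{i}]", 0.0),
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "midpoints_M": [float(m) for m in self.midpoints_M],
            "rss": float(self.rss),
            "aicc": float(self.aicc),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "flags": list(self.flags),
            "seed": self.seed,
        }


def _as_curve_list(curves) -> list[DenaturationCurve]:
    if isinstance(curves, DenaturationCurve):
        return [curves]
    return list(curves)


def _aicc(rss: float, n: int, kparams: int) -> float:
    if rss <= 0:
        rss = np.finfo(float).tiny
    aic = n * np.log(rss / n) + 2 * kparams
    denom = n - kparams - 1
    if denom <= 0:
        return np.inf
    return aic + 2 * kparams * (kparams + 1) / denom


def _check_identifiable(curves: list[DenaturationCurve], min_pts: int) -> None:
    n = sum(len(c) for c in curves)
    if n < min_pts:
        raise NonIdentifiableError(
            f"non-identifiable fit: {n} points < {min_pts} required"
        )
    spans = [np.ptp(c.values) for c in curves]
    if all(s == 0 for s in spans):
        raise NonIdentifiableError("non-identifiable fit: flat signal")


def _mean_profile(c: DenaturationCurve):
    """Unique concentrations with replicate-averaged signals.

    Curves may carry repeated concentrations (pooled replicate points);
    the start-guess heuristics need a single-valued profile.
    """
    d, inverse = np.unique(c.concentrations_M, return_inverse=True)
    y = np.bincount(inverse, weights=c.values) / np.bincount(inverse)
    return d, y


def _transition_guess(c: DenaturationCurve) -> float:
    """Denaturant concentration of the steepest signal change."""
    d, y = _mean_profile(c)
    dy = np.abs(np.gradient(y, d))
    return float(d[np.argmax(dy)])


def _jac_sparsity(curves, n_shared: int, per: int):
    """Occupancy pattern of the global-fit Jacobian.

    Shared thermodynamic columns touch every residual; per-curve signal
    columns only touch that curve's rows.  Declaring this lets the finite
    differencer group columns, which matters once dozens of replicate
    curves are fitted jointly.
    """
    from scipy import sparse

    n_obs = sum(len(c) for c in curves)
    pat = sparse.lil_matrix((n_obs, n_shared + per * len(curves)), dtype=int)
    pat[:, :n_shared] = 1
    row = 0
    for i, c in enumerate(curves):
        base = n_shared + per * i
        pat[row:row + len(c), base:base + per] = 1
        row += len(c)
    return pat.tocsr()


def _covariance(res, n: int, p: int):
    """Gauss–Newton covariance at the optimum, scaled by the residual variance."""
    jac = res.jac.toarray() if hasattr(res.jac, "toarray") else res.jac
    _, s, vt = np.linalg.svd(jac, full_matrices=False)
    tol = np.finfo(float).eps * max(res.jac.shape) * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < p:
        return None
    s2 = np.sum(res.fun**2) / max(n - p, 1)
    cov = (vt.T / s**2) @ vt * s2
    return cov


def _run_multistart(residual_fn, starts, bounds, opts: FitOptions,
                    jac_sparsity=None):
    """Run bounded trust-region least squares from each start; keep the best."""
    extra = {}
    if jac_sparsity is not None:
        extra = {"jac_sparsity": jac_sparsity, "tr_solver": "lsmr"}
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            res = optimize.least_squares(
                residual_fn, x0, bounds=bounds, method="trf",
                ftol=opts.ftol, xtol=opts.xtol, gtol=opts.gtol,
                max_nfev=opts.max_nfev, **extra,
            )
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res, rss)
        # noiseless round-trips hit machine precision on the first start
        if rss < 1e-16 * max(1, res.fun.size):
            break
    return best, n_used


def fit_two_state(
    curves,
    k: ThermoConstants = ThermoConstants(),
    opts: FitOptions = None,
) -> FitResult:
    """Globally fit the two-state model to one or more curves.

    dG0 and m are shared across curves; yn, yu (and baseline slopes, unless
    ``opts.fit_baseline_slopes`` is False) are per curve.  Starts are drawn
    around data-driven heuristics: baselines from the first/last quartiles,
    midpoint from the steepest signal change.
    """
    opts = opts or FitOptions()
    curves = _as_curve_list(curves)
    _check_identifiable(curves, min_pts=6)
    nc = len(curves)
    slopes = opts.fit_baseline_slopes
    per = 4 if slopes else 2

    names = ["dG0", "m"]
    for i in range(nc):
        names += [f"yn[{i}]", f"yu[{i}]"] + ([f"mf[{i}]", f"mu[{i}]"] if slopes else [])

    sig = np.array(
        [opts.weights[i] if opts.weights is not None else 1.0 for i in range(nc)],
        dtype=float,
    )

    def residual(x):
        dG0, m = x[0], x[1]
        out = []
        for i, c in enumerate(curves):
            base = 2 + per * i
            yn, yu = x[base], x[base + 1]
            mf, mu = (x[base + 2], x[base + 3]) if slopes else (0.0, 0.0)
            p = TwoStateParams(dG0, m, yn, yu, mf, mu)
            out.append((eval_two_state(p, c.concentrations_M, k) - c.values) / sig[i])
        return np.concatenate(out)

    lo = np.full(2 + per * nc, -np.inf)
    hi = np.full(2 + per * nc, np.inf)
    lo[0], hi[0] = 1e-6, 100.0   # dG0
    lo[1], hi[1] = 1e-3, 50.0    # m

    # heuristic centre
    mids = [_transition_guess(c) for c in curves]
    mid0 = float(np.mean(mids))
    m0 = 2.0
    centre = [m0 * max(mid0, 0.1), m0]
    for c in curves:
        d = c.concentrations_M
        q1, q3 = np.quantile(d, [0.25, 0.75])
        yn0 = float(np.mean(c.values[d <= q1]))
        yu0 = float(np.mean(c.values[d >= q3]))
        centre += [yn0, yu0] + ([0.0, 0.0] if slopes else [])
    centre = np.array(centre)

    rng = np.random.default_rng(opts.seed)
    starts = [centre]
    for _ in range(opts.n_starts - 1):
        x = centre.copy()
        m_try = m0 * np.exp(rng.normal(0, 0.7))
        mid_try = max(mid0 + rng.normal(0, 0.5), 0.05)
        x[1] = m_try
        x[0] = m_try * mid_try
        x[2:] *= 1 + rng.normal(0, 0.02, size=x.size - 2)
        starts.append(x)

    sparsity = _jac_sparsity(curves, 2, per) if nc >= 4 else None
    best, n_used = _run_multistart(residual, starts, (lo, hi), opts,
                                   jac_sparsity=sparsity)
    if best is None:
        raise ConvergenceError("did not converge")
    res, rss = best
    n = res.fun.size
    p = len(names)
    cov = _covariance(res, n, p)
    if cov is None:
        raise NonIdentifiableError("non-identifiable fit: singular information matrix")
    est = dict(zip(names, res.x))
    se = dict(zip(names, np.sqrt(np.diag(cov))))
    mids_fit = [est["dG0"] / est["m"]]
    return FitResult(
        model="two_state", estimates=est, standard_errors=se, covariance=cov,
        param_names=names, residuals=res.fun, converged=True,
        midpoints_M=mids_fit, n_starts_used=n_used, rss=rss, n_obs=n,
        aicc=_aicc(rss, n, p), seed=opts.seed,
    )


def _fit_sequential(curves, k, opts, n_trans: int) -> FitResult:
    """Shared machinery for the three- and four-state global fits.

    Internally the thermodynamic block is parametrised as
    (mid1, delta2, ..., m1, ..., mn) with positive lower bounds on the
    midpoint increments, so the ordering mid1 < mid2 < ... is enforced
    during optimisation rather than checked afterwards.  Estimates and
    covariance are transformed back to (dG1..n, m1..n) for reporting.
    """
    curves = _as_curve_list(curves)
    min_pts = 9 if n_trans == 2 else 12
    _check_identifiable(curves, min_pts=min_pts)
    nc = len(curves)
    n_states = n_trans + 1
    slopes = opts.fit_end_slopes
    per = n_states + (2 if slopes else 0)

    model = "three_state" if n_trans == 2 else "four_state"
    sig_names = (["yN", "yI", "yU"] if n_trans == 2
                 else ["yN", "yI1", "yI2", "yU"])
    names = [f"dG{j+1}" for j in range(n_trans)] + [f"m{j+1}" for j in range(n_trans)]
    for i in range(nc):
        names += [f"{s}[{i}]" for s in sig_names]
        if slopes:
            names += [f"sN[{i}]", f"sU[{i}]"]

    sig = np.array(
        [opts.weights[i] if opts.weights is not None else 1.0 for i in range(nc)],
        dtype=float,
    )
    cls = ThreeStateParams if n_trans == 2 else FourStateParams

    def _mids(x):
        return np.cumsum(x[:n_trans])

    def residual(x):
        mids, ms = _mids(x), x[n_trans:2 * n_trans]
        dGs = mids * ms
        out = []
        for i, c in enumerate(curves):
            base = 2 * n_trans + per * i
            ys = x[base:base + n_states]
            sN, sU = (x[base + n_states], x[base + n_states + 1]) if slopes else (0.0, 0.0)
            p = cls(*dGs, *ms, *ys, sN, sU)
            out.append((_eval_sequential(p, c.concentrations_M, k) - c.values) / sig[i])
        return np.concatenate(out)

    d_all = np.concatenate([c.concentrations_M for c in curves])
    d_max = float(d_all.max())
    delta_lo = 0.05  # transitions closer than 0.05 M are not resolvable
    npar = 2 * n_trans + per * nc
    lo = np.full(npar, -np.inf)
    hi = np.full(npar, np.inf)
    lo[0], hi[0] = 0.01, d_max
    lo[1:n_trans], hi[1:n_trans] = delta_lo, d_max
    lo[n_trans:2 * n_trans], hi[n_trans:2 * n_trans] = 0.1, 20.0

    # heuristic centre: midpoints at the D where the normalised signal change
    # crosses spread levels; end signals from trace edges
    d, y = _mean_profile(curves[0])
    yN0, yU0 = float(y[0]), float(y[-1])
    span = yU0 - yN0 if yU0 != yN0 else 1.0
    f = np.clip((y - yN0) / span, 0.0, 1.0)
    levels = ([0.3, 0.75] if n_trans == 2 else [0.25, 0.5, 0.8])
    mids0 = []
    for lev in levels:
        idx = np.argmax(f >= lev) if np.any(f >= lev) else len(d) - 1
        mids0.append(float(d[max(idx, 1)]))
    mids0 = np.maximum.accumulate(np.array(mids0))
    for j in range(1, n_trans):
        if mids0[j] <= mids0[j - 1]:
            mids0[j] = mids0[j - 1] + max(0.2, float(np.mean(np.diff(d))))
    m0 = np.full(n_trans, 2.0)

    def _increments(mids):
        return np.concatenate([[mids[0]], np.diff(mids)])

    centre = list(_increments(np.maximum(mids0, 0.05))) + list(m0)
    for c in curves:
        _, yc = _mean_profile(c)
        centre += list(np.linspace(float(yc[0]), float(yc[-1]), n_states))
        if slopes:
            centre += [0.0, 0.0]
    centre = np.array(centre)

    rng = np.random.default_rng(opts.seed)
    starts = [centre]
    for _ in range(opts.n_starts - 1):
        x = centre.copy()
        mid_try = np.sort(np.maximum(mids0 + rng.normal(0, 0.4, size=n_trans), 0.05))
        incr = _increments(mid_try)
        incr[1:] = np.maximum(incr[1:], 2 * delta_lo)
        x[:n_trans] = incr
        x[n_trans:2 * n_trans] = m0 * np.exp(rng.normal(0, 0.6, size=n_trans))
        x[2 * n_trans:] *= 1 + rng.normal(0, 0.02, size=x.size - 2 * n_trans)
        starts.append(x)

    sparsity = _jac_sparsity(curves, 2 * n_trans, per) if nc >= 4 else None
    best, n_used = _run_multistart(residual, starts, (lo, hi), opts,
                                   jac_sparsity=sparsity)
    if best is None:
        raise ConvergenceError("did not converge")
    res, rss = best

    flags = []
    incr_fit = res.x[1:n_trans]
    collapsed = incr_fit <= delta_lo * 1.05

    n = res.fun.size
    p = len(names)
    # transform internal (increments, m, signals) -> (dG, m, signals)
    mids_x = _mids(res.x)
    ms_x = res.x[n_trans:2 * n_trans]
    G = np.eye(p)
    for i in range(n_trans):
        for j in range(i + 1):
            G[i, j] = ms_x[i]          # d dG_i / d delta_j
        G[i, n_trans + i] = mids_x[i]  # d dG_i / d m_i
    cov_int = _covariance(res, n, p)
    est_vec = res.x.copy()
    est_vec[:n_trans] = mids_x * ms_x
    est = dict(zip(names, est_vec))
    if cov_int is None:
        cov = np.full((p, p), np.nan)
        se = dict(zip(names, [np.nan] * p))
        flags.append("degenerate parameters: singular information matrix")
    else:
        cov = G @ cov_int @ G.T
        se = dict(zip(names, np.sqrt(np.diag(cov))))
    mids_fit = list(mids_x)

    # a midpoint increment pinned at its lower bound means the data could
    # not separate two adjacent transitions; the estimate is kept (ordering
    # held by construction) but flagged
    for j, bad in enumerate(collapsed, start=1):
        if bad:
            flags.append(f"transitions {j} and {j+1} not separated")

    # flag intermediates indistinguishable from their neighbours
    for i in range(nc):
        ys = [est[f"{s}[{i}]"] for s in sig_names]
        span = abs(ys[-1] - ys[0]) or 1.0
        for j in range(1, n_states - 1):
            gap = min(abs(ys[j] - ys[j - 1]), abs(ys[j] - ys[j + 1]))
            se_y = se.get(f"{sig_names[j]}[{i}]", np.nan)
            if gap < 0.02 * span or (np.isfinite(se_y) and gap < 2 * se_y):
                flags.append(f"degenerate intermediate signal {sig_names[j]}[{i}]")
    return FitResult(
        model=model, estimates=est, standard_errors=se, covariance=cov,
        param_names=names, residuals=res.fun, converged=True,
        midpoints_M=mids_fit, n_starts_used=n_used, rss=rss, n_obs=n,
        aicc=_aicc(rss, n, p), flags=flags, seed=opts.seed,
    )


def fit_three_state(curves, k: ThermoConstants = ThermoConstants(),
                    opts: FitOptions = None) -> FitResult:
    """Globally fit the sequential three-state model (one intermediate)."""
    return _fit_sequential(curves, k, opts or FitOptions(), n_trans=2)


def fit_four_state(curves, k: ThermoConstants = ThermoConstants(),
                   opts: FitOptions = None) -> FitResult:
    """Globally fit the sequential four-state model (two intermediates).

    Thermodynamic parameters (dG1..3, m1..3) are shared across curves;
    state signals are per curve.  The midpoint ordering
    dG1/m1 < dG2/m2 < dG3/m3 is required of the reported optimum.
    """
    return _fit_sequential(curves, k, opts or FitOptions(), n_trans=3)


@dataclass
class ModelSelection:
    """Outcome of comparing 2-, 3- and 4-state fits on one curve."""

    chosen_states: int
    aicc: dict
    fits: dict
    f_tests: dict
    errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chosen_states": self.chosen_states,
            "aicc": {k: float(v) for k, v in self.aicc.items()},
            "f_tests": self.f_tests,
            "errors": {k: str(v) for k, v in self.errors.items()},
        }


def model_select(curve: DenaturationCurve, k: ThermoConstants = ThermoConstants(),
                 opts: FitOptions = None) -> ModelSelection:
    """Fit 2-, 3- and 4-state sequential models and pick by AICc.

    Ties (within 1e-9 AICc) go to the model with fewer states.  F-tests of
    each model against the next-simpler nested one are reported alongside.
    """
    opts = opts or FitOptions()
    fitters = {2: fit_two_state, 3: fit_three_state, 4: fit_four_state}
    fits, aicc, errors = {}, {}, {}
    for ns, fn in fitters.items():
        try:
            fits[ns] = fn(curve, k, opts)
            aicc[ns] = fits[ns].aicc
        except Exception as exc:  # noqa: BLE001 - candidates fail independently
            errors[ns] = exc
    if not fits:
        raise ModelSelectionError("no model fits")
    f_tests = {}
    for lo_ns, hi_ns in ((2, 3), (3, 4)):
        if lo_ns in fits and hi_ns in fits:
            f0, f1 = fits[lo_ns], fits[hi_ns]
            df1 = f1.n_params - f0.n_params
            df2 = f1.n_obs - f1.n_params
            if df1 > 0 and df2 > 0 and f1.rss > 0:
                F = ((f0.rss - f1.rss) / df1) / (f1.rss / df2)
                f_tests[f"{lo_ns}v{hi_ns}"] = {
                    "F": float(F),
                    "p": float(stats.f.sf(max(F, 0.0), df1, df2)),
                }
    chosen = min(sorted(aicc), key=lambda ns: (round(aicc[ns], 9), ns))
    return ModelSelection(chosen_states=chosen, aicc=aicc, fits=fits,
                          f_tests=f_tests, errors=errors)
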