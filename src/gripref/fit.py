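"""Penalized-likelihood LMS fitting: smooth L(t), M(t), S(t) curves over age.

Fits the three BCCG parameter curves for one sex by maximizing the penalized
log-likelihood

    l_p(theta) = sum_i log f_BCCG(y_i; lam(t_i), mu(t_i), sigma(t_i))
                 - 1/2 sum_j tau_j * theta_j' K_j theta_j

where each curve is parameterized by its values at the distinct cohort ages
(the knots) on its link scale — identity for lam, log for mu and sigma (the
log links guarantee mu > 0 and sigma > 0 at any age).  K_j is a difference
penalty and tau_j is calibrated so that the penalized hat matrix has the
requested effective degrees of freedom (edf).  Optimization is
block-coordinate ascent across (lam, mu, sigma), each block maximized by
L-BFGS-B; the penalized deviance is therefore non-increasing across outer
iterations.

Between knots the fitted curves are evaluated by monotone piecewise-cubic
(PCHIP) interpolation on the link scale, which preserves the monotonicity of
the knot values and keeps predicted triples valid everywhere in the age
domain.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, minimize

from .bccg import LAMBDA_EPS, LMSTriple

__all__ = ["FitConfig", "LMSCurveModel", "fit_lms", "predict_lms", "select_edf"]

_PARAMS = ("lam", "mu", "sigma")
_LINKS = {"lam": "identity", "mu": "log", "sigma": "log"}
# Optimization bounds on the link scale.
_BOUNDS = {
    "lam": (-5.0, 5.0),
    "mu": (math.log(1e-3), math.log(1e4)),
    "sigma": (math.log(1e-4), math.log(2.0)),
}
_SIGMA_FLOOR = 1e-4  # lower bound on sigma; hit only by zero-variance data
# inner (per-block) optimizer tolerances; tight so the outer loop, not the
# inner one, decides convergence
_LBFGS_OPTS = {"ftol": 1e-12, "gtol": 1e-8, "maxiter": 200}
_MIN_PER_AGE = 30


@dataclass(frozen=True)
class FitConfig:
    """Smoothing and convergence settings for :func:`fit_lms`.

    edf values are effective degrees of freedom per curve (1 = constant,
    number-of-ages = unpenalized one-value-per-age).  ``fix_lambda`` freezes
    the skewness power at a known value instead of estimating it.
    """

    edf_lambda: float = 2.0
    edf_mu: float = 3.0
    edf_sigma: float = 2.0
    max_outer_iter: int = 50
    tol: float = 1e-6
    edf_selection: str = "fixed"
    fix_lambda: float | None = None

    def __post_init__(self) -> None:
        for name in ("edf_lambda", "edf_mu", "edf_sigma"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    @property
    def total_edf(self) -> float:
        lam_edf = 0.0 if self.fix_lambda is not None else self.edf_lambda
        return lam_edf + self.edf_mu + self.edf_sigma


@dataclass
class LMSCurveModel:
    """Fitted age-dependent LMS curves for one sex."""

    sex: str
    age_domain: tuple[float, float]
    knot_ages: np.ndarray
    basis_spec: dict[str, dict]
    coef: dict[str, np.ndarray]  # link-scale values at the knots
    link: dict[str, str] = field(default_factory=lambda: dict(_LINKS))
    fit_stats: dict = field(default_factory=dict)

    def _curve(self, param: str, ages: np.ndarray) -> np.ndarray:
        theta = self.coef[param]
        if len(self.knot_ages) == 1 or np.ptp(theta) == 0.0:
            vals = np.full_like(ages, theta[0], dtype=float)
        else:
            vals = PchipInterpolator(self.knot_ages, theta, extrapolate=True)(ages)
        if self.link[param] == "log":
            vals = np.exp(vals)
        return vals

    def predict(self, age: float) -> LMSTriple:
        return predict_lms(self, age)

    def predict_many(self, ages: Sequence[float]) -> list[LMSTriple]:
        a = np.asarray(ages, dtype=float)
        lam = self._curve("lam", a)
        mu = self._curve("mu", a)
        sigma = self._curve("sigma", a)
        return [LMSTriple(float(l), float(m), float(s)) for l, m, s in zip(lam, mu, sigma)]

    # -- serialization (flat key/value text, round-trips to 1e-12) ---------

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("format: gripref-lms-model v1\n")
        buf.write(f"sex: {self.sex}\n")
        buf.write(f"age_domain: {self.age_domain[0]!r} {self.age_domain[1]!r}\n")
        buf.write("knot_ages: " + " ".join(repr(float(a)) for a in self.knot_ages) + "\n")
        for p in _PARAMS:
            spec = self.basis_spec.get(p, {})
            buf.write(f"basis_{p}: edf={spec.get('edf', 'na')} tau={spec.get('tau', 'na')}\n")
            buf.write(f"link_{p}: {self.link[p]}\n")
            buf.write(f"coef_{p}: " + " ".join(repr(float(c)) for c in self.coef[p]) + "\n")
        fs = self.fit_stats
        buf.write(f"converged: {fs.get('converged', True)}\n")
        buf.write(f"iterations: {fs.get('iterations', 0)}\n")
        buf.write(f"penalized_deviance: {fs.get('penalized_deviance', float('nan'))!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "LMSCurveModel":
        kv: dict[str, str] = {}
        for line in text.strip().splitlines():
            key, _, val = line.partition(":")
            kv[key.strip()] = val.strip()
        if kv.get("format") != "gripref-lms-model v1":
            raise ValueError("unrecognized model file format")
        lo, hi = (float(x) for x in kv["age_domain"].split())
        knots = np.array([float(x) for x in kv["knot_ages"].split()])
        coef, basis, link = {}, {}, {}
        for p in _PARAMS:
            coef[p] = np.array([float(x) for x in kv[f"coef_{p}"].split()])
            link[p] = kv[f"link_{p}"]
            parts = dict(item.split("=") for item in kv[f"basis_{p}"].split())
            basis[p] = {
                k: (None if v == "na" else float(v)) for k, v in parts.items()
            }
        stats = {
            "converged": kv["converged"] == "True",
            "iterations": int(kv["iterations"]),
            "penalized_deviance": float(kv["penalized_deviance"]),
        }
        return cls(
            sex=kv["sex"], age_domain=(lo, hi), knot_ages=knots,
            basis_spec=basis, coef=coef, link=link, fit_stats=stats,
        )


# ---------------------------------------------------------------------------
# penalty calibration


def _diff_penalty(m: int, order: int) -> np.ndarray:
    d = np.diff(np.eye(m), n=order, axis=0)
    return d.T @ d


def _edf_trace(counts: np.ndarray, k: np.ndarray, tau: float) -> float:
    w = np.diag(counts.astype(float))
    h = np.linalg.solve(w + tau * k, w)
    return float(np.trace(h))


def _calibrate_tau(counts: np.ndarray, edf: float) -> tuple[float, np.ndarray]:
    """Penalty multiplier tau and matrix K giving the requested edf.

    Second-difference penalty (shrinks toward a linear-in-age curve) for
    edf > 2; first-difference (shrinks toward a constant) for edf in (1, 2).
    Integer edf 1 and 2 are handled upstream as exact null-space fits
    (constant / linear), which avoids the tau -> infinity limit.
    """
    m = len(counts)
    if edf >= m:
        return 0.0, np.zeros((m, m))
    order = 2 if edf > 2 else 1
    k = _diff_penalty(m, order)
    lo, hi = -10.0, 16.0
    g = lambda log_tau: _edf_trace(counts, k, 10.0 ** log_tau) - edf
    if g(hi) > 0:  # requested edf at (or below) the null-space dimension
        return 10.0 ** hi, k
    log_tau = brentq(g, lo, hi, xtol=1e-10)
    return 10.0 ** log_tau, k


# ---------------------------------------------------------------------------
# likelihood


def _neg2_loglik(y: np.ndarray, lam: np.ndarray, mu: np.ndarray,
                 sigma: np.ndarray) -> float:
    """-2 * BCCG log-likelihood, vectorized over records."""
    logr = np.log(y / mu)
    z = np.where(
        np.abs(lam) < LAMBDA_EPS,
        logr / sigma,
        (np.exp(np.clip(lam * logr, -700, 700)) - 1.0)
        / (np.where(np.abs(lam) < LAMBDA_EPS, 1.0, lam) * sigma),
    )
    ll = (lam - 1.0) * logr - np.log(mu * sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z
    return -2.0 * float(np.sum(ll))


class _FitState:
    """Per-fit precomputation: block modes, penalties, likelihood plumbing.

    Each curve block is handled in the parametrization its edf implies:
    ``fixed`` (lam frozen), ``const`` (edf <= 1), ``linear`` (edf == 2, the
    exact null space of the curvature penalty), or ``penalized`` (edf > 2,
    knot values with a difference penalty whose multiplier is calibrated to
    the edf; tau = 0 when edf >= number of knots).  Keeping the integer null
    space cases exact avoids the tau -> infinity ridge limit.
    """

    def __init__(self, y: np.ndarray, idx: np.ndarray, knots: np.ndarray,
                 counts: np.ndarray, config: FitConfig,
                 sigma0: np.ndarray | None = None):
        self.y, self.idx, self.knots, self.counts = y, idx, knots, counts
        self.config = config
        m = len(knots)
        # standardized age for the linear blocks (conditioning)
        self.xs = (knots - knots.mean()) / (0.5 * np.ptp(knots)) if m > 1 else np.zeros(1)
        if sigma0 is None:
            sigma0 = np.full(m, 0.3)
        # Per-record expected Fisher information on each link scale (evaluated
        # at the initial sigma): lam ~ 1.75*sigma^2, log mu ~ 1/sigma^2,
        # log sigma ~ 2.  The edf -> tau calibration must use these weights,
        # not raw counts, for the trace of the penalized hat matrix to match
        # the likelihood geometry.
        # factor 2: the penalty tau*theta'K theta is added to -2*loglik,
        # whose curvature is twice the information
        info = {
            "lam": 2.0 * 1.75 * sigma0**2,
            "mu": 2.0 / sigma0**2,
            "sigma": np.full(m, 4.0),
        }
        edfs = {"lam": config.edf_lambda, "mu": config.edf_mu, "sigma": config.edf_sigma}
        self.mode: dict[str, str] = {}
        self.tau: dict[str, float] = {}
        self.K: dict[str, np.ndarray] = {}
        for p in _PARAMS:
            edf = edfs[p]
            if p == "lam" and config.fix_lambda is not None:
                self.mode[p] = "fixed"
            elif m == 1 or edf <= 1.0:
                self.mode[p] = "const"
            elif edf == 2.0 and m > 2:
                self.mode[p] = "linear"
            else:
                self.mode[p] = "penalized"
            self.tau[p], self.K[p] = (
                _calibrate_tau(counts * info[p], edf) if self.mode[p] == "penalized"
                else (0.0, np.zeros((m, m)))
            )

    def penalty(self, theta: dict[str, np.ndarray]) -> float:
        return sum(
            self.tau[p] * float(theta[p] @ self.K[p] @ theta[p]) for p in _PARAMS
        )

    def pen_deviance(self, theta: dict[str, np.ndarray]) -> float:
        lam = theta["lam"][self.idx]
        mu = np.exp(theta["mu"][self.idx])
        sigma = np.exp(theta["sigma"][self.idx])
        return _neg2_loglik(self.y, lam, mu, sigma) + self.penalty(theta)

    def optimize_block(self, theta: dict[str, np.ndarray], p: str) -> None:
        mode = self.mode[p]
        if mode == "fixed":
            return
        m = len(self.knots)
        lo, hi = _BOUNDS[p]
        if mode == "const":
            def obj(x: np.ndarray) -> float:
                trial = dict(theta)
                trial[p] = np.full(m, x[0])
                return self.pen_deviance(trial)
            res = minimize(obj, np.array([theta[p][0]]), method="L-BFGS-B",
                           bounds=[(lo, hi)], options=_LBFGS_OPTS)
            theta[p] = np.full(m, res.x[0])
        elif mode == "linear":
            xs = self.xs
            # start from the least-squares line through the current knot values
            b0, a0 = np.polyfit(xs, theta[p], 1)

            def obj(x: np.ndarray) -> float:
                trial = dict(theta)
                trial[p] = np.clip(x[0] + x[1] * xs, lo, hi)
                return self.pen_deviance(trial)
            res = minimize(obj, np.array([a0, b0]), method="L-BFGS-B",
                           bounds=[(lo, hi), (-(hi - lo), hi - lo)],
                           options=_LBFGS_OPTS)
            theta[p] = np.clip(res.x[0] + res.x[1] * xs, lo, hi)
        else:
            def obj(x: np.ndarray) -> float:
                trial = dict(theta)
                trial[p] = x
                return self.pen_deviance(trial)
            res = minimize(obj, theta[p].copy(), method="L-BFGS-B",
                           bounds=[(lo, hi)] * m, options=_LBFGS_OPTS)
            theta[p] = res.x


def _extract_arrays(cohort: Iterable) -> tuple[np.ndarray, np.ndarray, str]:
    ages, values, sexes = [], [], set()
    for rec in cohort:
        ages.append(float(rec.age))
        values.append(float(rec.hgs_abs))
        sexes.add(getattr(rec, "sex", ""))
    if not ages:
        raise ValueError("empty cohort")
    sexes.discard("")
    if len(sexes) > 1:
        raise ValueError(f"fit_lms expects a single-sex cohort, got sexes {sorted(sexes)}")
    sex = sexes.pop() if sexes else "unspecified"
    return np.asarray(ages), np.asarray(values), sex


def fit_lms(cohort: Iterable, config: FitConfig | None = None) -> LMSCurveModel:
    """Fit smooth LMS curves to a single-sex cohort.

    Parameters
    ----------
    cohort:
        Records exposing ``age`` (years) and ``hgs_abs`` (kg, > 0); typically
        a list of :class:`~gripref.cohort.CohortRecord` for one sex.
    config:
        Smoothing/convergence settings; defaults to
        ``FitConfig(edf_lambda=2, edf_mu=3, edf_sigma=2)``.

    Returns
    -------
    LMSCurveModel
        With ``fit_stats['converged']`` False (plus a warning) if the outer
        loop exhausted ``max_outer_iter``.  A single-age cohort is fitted
        with constant triples (no smoothing possible).
    """
    config = config or FitConfig()
    ages, y, sex = _extract_arrays(cohort)
    if np.any(y <= 0):
        raise ValueError("all HGS values must be > 0")

    knots, idx = np.unique(ages, return_inverse=True)
    counts = np.bincount(idx)
    if np.any(counts < _MIN_PER_AGE):
        thin = knots[counts < _MIN_PER_AGE]
        warnings.warn(
            f"fewer than {_MIN_PER_AGE} records at age(s) {thin.tolist()}; "
            "parameter estimates there may be unstable"
        )
    if len(knots) == 1:
        config = replace(config, edf_lambda=1.0, edf_mu=1.0, edf_sigma=1.0)

    # Initialization: lam = 1, mu = per-age medians, sigma = IQR-based CV.
    med = np.array([np.median(y[idx == j]) for j in range(len(knots))])
    iqr = np.array([np.subtract(*np.percentile(y[idx == j], [75, 25]))
                    for j in range(len(knots))])
    sigma0 = np.clip(iqr / (1.349 * med), 2 * _SIGMA_FLOOR, 1.0)

    state = _FitState(y, idx, knots, counts, config, sigma0=sigma0)
    lam0 = config.fix_lambda if config.fix_lambda is not None else 1.0
    theta = {
        "lam": np.full(len(knots), float(lam0)),
        "mu": np.log(med),
        "sigma": np.log(sigma0),
    }

    dev = state.pen_deviance(theta)
    path = [dev]
    converged = False
    iters = 0
    for iters in range(1, config.max_outer_iter + 1):
        for p in ("mu", "sigma", "lam"):
            state.optimize_block(theta, p)
        new_dev = state.pen_deviance(theta)
        path.append(new_dev)
        if abs(dev - new_dev) < config.tol:
            converged = True
            dev = new_dev
            break
        dev = new_dev
    if not converged:
        warnings.warn(
            f"fit_lms did not converge in {config.max_outer_iter} outer iterations "
            f"(last deviance change {abs(path[-2] - path[-1]):.3g})"
        )

    lam_c = theta["lam"][idx]
    edfs = {"lam": config.edf_lambda, "mu": config.edf_mu, "sigma": config.edf_sigma}
    basis = {
        p: {"edf": (1.0 if state.mode[p] in ("const", "fixed") else edfs[p]),
            "tau": state.tau[p]}
        for p in _PARAMS
    }
    deviance = _neg2_loglik(y, lam_c, np.exp(theta["mu"][idx]),
                            np.exp(theta["sigma"][idx]))
    return LMSCurveModel(
        sex=sex,
        age_domain=(float(knots[0]), float(knots[-1])),
        knot_ages=knots,
        basis_spec=basis,
        coef={p: theta[p].copy() for p in _PARAMS},
        fit_stats={
            "converged": converged,
            "iterations": iters,
            "penalized_deviance": float(path[-1]),
            "deviance": float(deviance),
            "deviance_path": [float(d) for d in path],
            "n": int(len(y)),
        },
    )


def predict_lms(model: LMSCurveModel, age: float) -> LMSTriple:
    """Predicted LMS triple at an age; warns (not errors) on extrapolation."""
    lo, hi = model.age_domain
    if not lo <= age <= hi:
        warnings.warn(f"age {age} outside fitted domain [{lo}, {hi}]; extrapolating")
    a = np.array([float(age)])
    return LMSTriple(
        lam=float(model._curve("lam", a)[0]),
        mu=float(model._curve("mu", a)[0]),
        sigma=float(model._curve("sigma", a)[0]),
    )


def select_edf(cohort: Iterable, candidate_grid: Sequence[FitConfig]) -> FitConfig:
    """Pick the candidate config minimizing a BIC-type criterion.

    criterion = deviance + ln(n) * total_edf; ties broken by smallest total
    edf, then by grid order.  Deterministic given the cohort.
    """
    if not candidate_grid:
        raise ValueError("candidate grid is empty")
    records = list(cohort)
    best: tuple[float, float, int] | None = None
    best_config: FitConfig | None = None
    any_converged = False
    for order, cand in enumerate(candidate_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_lms(records, cand)
        if not model.fit_stats["converged"]:
            continue
        any_converged = True
        n = model.fit_stats["n"]
        crit = model.fit_stats["deviance"] + math.log(n) * cand.total_edf
        key = (crit, cand.total_edf, order)
        if best is None or key < best:
            best, best_config = key, cand
    if not any_converged:
        raise RuntimeError(
            f"no candidate in the edf grid converged ({len(candidate_grid)} candidates)"
        )
    assert best_config is not None
    return best_config
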