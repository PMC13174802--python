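"""Structural models on genetic correlation matrices (genomic SEM core).

A declarative :class:`ModelSpec` (free correlations, equality constraints,
regressions with correlated predictors, single common factors with
factor-to-target paths, residual covariances) is fitted to a genetic
correlation matrix ``R`` and the sampling covariance ``V_R`` of its
half-vectorization by diagonally weighted least squares:

    F(theta) = (s - sigma(theta))' D^-1 (s - sigma(theta)),

with ``s`` the off-diagonal elements of ``R`` (the unit diagonal is fixed
and not modeled), ``D = diag(V_R)`` restricted to those elements, and
``sigma(theta)`` the model-implied correlations.  Parameter uncertainty
uses the sandwich covariance

    (D' W D)^-1 D' W V_R W D (D' W D)^-1,  W = D^-1,

which is robust to the diagonal weighting.  Model fit is judged by the
residual-based chi-square ``T = e' Gamma^+ e`` where ``Gamma`` projects
``V_R`` onto the residual space; for single equality constraints the
asymptotically equivalent Wald contrast is co-implemented as a
cross-check.

The implied-covariance machinery follows the reticular action model:
variables are observed traits plus latent factors, with path matrix A and
exogenous covariance S0; residual variances of endogenous observed
variables are set deterministically so every implied variance equals 1,
keeping the model on the correlation metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm

from ._linalg import offdiag_positions, vech_pairs, vech_position
from .exceptions import (
    CollinearityError,
    ConvergenceError,
    DegenerateContrastError,
    InvalidArgumentError,
)

__all__ = [
    "Factor",
    "Regression",
    "ModelSpec",
    "FitResult",
    "StructuralModel",
    "fit_dwls",
    "residual_chisq",
    "wald_equality_test",
    "genetic_multiple_regression",
    "factor_residual_model",
    "MultipleRegressionResult",
    "equality_constrained_spec",
]

GRADIENT_TOL = 1e-8
HEYWOOD_TOL = 0.01


@dataclass(frozen=True)
class Factor:
    name: str
    indicators: tuple

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))


@dataclass(frozen=True)
class Regression:
    outcome: str
    predictors: tuple

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))


def _pair(p):
    return tuple(p)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structural model over the traits of a correlation matrix.

    Parameter labels are predictable and may be referenced in
    ``equality_sets``:

    * correlation between a and b:            ``r(a,b)``
    * loading of indicator i on factor f:     ``l(f,i)``
    * regression of outcome y on predictor x: ``b(y~x)``
    * path from factor f to target t:         ``b(t~f)``
    * residual covariance between a and b:    ``rc(a,b)``
    """

    variables: tuple
    correlations: tuple = ()
    equality_sets: tuple = ()
    regressions: tuple = ()
    factors: tuple = ()
    factor_regressions: tuple = ()
    residual_covariances: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "correlations",
                           tuple(_pair(p) for p in self.correlations))
        object.__setattr__(self, "equality_sets",
                           tuple(tuple(s) for s in self.equality_sets))
        object.__setattr__(self, "regressions", tuple(self.regressions))
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "factor_regressions",
                           tuple(_pair(p) for p in self.factor_regressions))
        object.__setattr__(self, "residual_covariances",
                           tuple(_pair(p) for p in self.residual_covariances))
        self._validate()

    def _validate(self):
        known = set(self.variables)
        factor_names = {f.name for f in self.factors}
        if factor_names & known:
            raise InvalidArgumentError("factor names must not clash with variables")
        for a, b in self.correlations:
            if a not in known or b not in known:
                raise InvalidArgumentError(f"correlation references unknown variable ({a}, {b})")
        for f in self.factors:
            for ind in f.indicators:
                if ind not in known:
                    raise InvalidArgumentError(f"indicator {ind!r} unknown")
        for reg in self.regressions:
            if reg.outcome not in known or any(p not in known for p in reg.predictors):
                raise InvalidArgumentError("regression references unknown variable")
        for fac, tgt in self.factor_regressions:
            if fac not in factor_names or tgt not in known:
                raise InvalidArgumentError(f"factor regression ({fac}, {tgt}) unknown")
        for a, b in self.residual_covariances:
            if a not in known or b not in known:
                raise InvalidArgumentError("residual covariance references unknown variable")
        labels = set(self.param_labels())
        seen = set()
        for eqset in self.equality_sets:
            for lab in eqset:
                if lab not in labels:
                    raise InvalidArgumentError(f"equality set references unknown parameter {lab!r}")
                if lab in seen:
                    raise InvalidArgumentError(
                        f"parameter {lab!r} appears in more than one equality set")
                seen.add(lab)

    # -- parameter bookkeeping ---------------------------------------------

    def param_labels(self) -> list:
        labels = []
        for a, b in self.correlations:
            labels.append(f"r({a},{b})")
        for reg in self.regressions:
            for p in reg.predictors:
                labels.append(f"b({reg.outcome}~{p})")
        # predictors of one regression are correlated; auto-add their
        # correlation parameters unless already declared
        declared = {frozenset(p) for p in self.correlations}
        for reg in self.regressions:
            preds = reg.predictors
            for i in range(len(preds)):
                for j in range(i + 1, len(preds)):
                    if frozenset((preds[i], preds[j])) not in declared:
                        labels.append(f"r({preds[i]},{preds[j]})")
                        declared.add(frozenset((preds[i], preds[j])))
        for f in self.factors:
            for ind in f.indicators:
                labels.append(f"l({f.name},{ind})")
        for fac, tgt in self.factor_regressions:
            labels.append(f"b({tgt}~{fac})")
        for a, b in self.residual_covariances:
            labels.append(f"rc({a},{b})")
        return labels

    def free_param_count(self) -> int:
        labels = self.param_labels()
        shared = sum(len(s) - 1 for s in self.equality_sets)
        return len(labels) - shared


@dataclass
class FitResult:
    """DWLS fit of a :class:`ModelSpec`.

    ``theta``/``se`` are in the order of ``param_names`` (unique free
    parameters; members of an equality set collapse to one entry named
    after the set's first label).  ``residuals`` are ``s - sigma(theta)``
    in vech (off-diagonal) order.  ``chisq`` is the residual-based model
    chi-square; ``p`` its upper-tail probability on ``df`` degrees of
    freedom.  ``flags`` may contain ``"heywood"`` (a loading exceeds 1)
    or ``"inadmissible"`` (a negative residual variance).
    """

    param_names: list
    theta: np.ndarray
    se: np.ndarray
    fitval: float
    residuals: np.ndarray
    df: int
    chisq: float
    p: float
    cov_params: np.ndarray
    flags: list = field(default_factory=list)
    n_starts_used: int = 3
    # internals needed to recompute the residual chi-square
    _delta: np.ndarray | None = None
    _weights: np.ndarray | None = None
    _positions: list | None = None

    def __getitem__(self, label):
        return float(self.theta[self.param_names.index(label)])

    def se_of(self, label):
        return float(self.se[self.param_names.index(label)])

    @property
    def converged(self) -> bool:
        return True

    def summary(self) -> str:
        lines = [f"DWLS fit: F = {self.fitval:.6g}, chi2({self.df}) = "
                 f"{self.chisq:.4f}, p = {self.p:.4g}"]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        lines.append(f"{'parameter':<24}{'estimate':>12}{'SE':>12}")
        for name, est, se in zip(self.param_names, self.theta, self.se):
            lines.append(f"{name:<24}{est:>12.4f}{se:>12.4f}")
        return "\n".join(lines)


class StructuralModel:
    """Structural model bound to data (R, V_R), statsmodels-style.

    ``R`` rows/columns must follow ``spec.variables`` order.  ``V_R`` is
    the sampling covariance of vech(R) (full p* x p*, unit-diagonal rows
    zero) as produced by :func:`stratsem.ldsc.standardize`.
    """

    def __init__(self, spec: ModelSpec, R: np.ndarray, V_R: np.ndarray):
        self.spec = spec
        self.R = np.asarray(R, dtype=float)
        self.V_R = np.asarray(V_R, dtype=float)
        k = len(spec.variables)
        if self.R.shape != (k, k):
            raise InvalidArgumentError("R dimension does not match spec variables")
        p_star = k * (k + 1) // 2
        if self.V_R.shape != (p_star, p_star):
            raise InvalidArgumentError("V_R must cover the full vech of R")
        self.k = k
        self.positions = offdiag_positions(k)
        self.pairs = [vech_pairs(k)[pos] for pos in self.positions]
        self.s = np.array([self.R[i, j] for i, j in self.pairs])
        self.D = np.array([self.V_R[pos, pos] for pos in self.positions])
        if np.any(self.D <= 0):
            bad = self.pairs[int(np.argmin(self.D))]
            raise InvalidArgumentError(
                f"non-positive sampling variance for element {bad}; cannot weight")
        self._build_structure()
        q = len(self._free_names)
        if q > len(self.positions):
            raise InvalidArgumentError(
                f"{q} free parameters exceed the {len(self.positions)} modeled elements")

    # -- structure ---------------------------------------------------------

    def _build_structure(self):
        spec = self.spec
        self.obs = list(spec.variables)
        self.latents = [f.name for f in spec.factors]
        self.all_vars = self.obs + self.latents
        self.n_all = len(self.all_vars)
        self._vi = {v: i for i, v in enumerate(self.all_vars)}

        labels = spec.param_labels()
        label_to_free = {}
        self._free_names = []
        eq_map = {}
        for eqset in spec.equality_sets:
            for lab in eqset:
                eq_map[lab] = eqset[0]
        for lab in labels:
            rep = eq_map.get(lab, lab)
            if rep not in label_to_free:
                label_to_free[rep] = len(self._free_names)
                self._free_names.append(rep)
            label_to_free[lab] = label_to_free[rep]
        self._label_to_free = label_to_free
        self._labels = labels

        # edges: (kind, target_idx, source_idx, label)
        self._a_edges = []
        self._s_edges = []
        for a, b in spec.correlations:
            self._s_edges.append((self._vi[a], self._vi[b], f"r({a},{b})"))
        declared = {frozenset(p) for p in spec.correlations}
        for reg in spec.regressions:
            for p in reg.predictors:
                self._a_edges.append((self._vi[reg.outcome], self._vi[p],
                                      f"b({reg.outcome}~{p})"))
            preds = reg.predictors
            for i in range(len(preds)):
                for j in range(i + 1, len(preds)):
                    key = frozenset((preds[i], preds[j]))
                    if key not in declared:
                        self._s_edges.append((self._vi[preds[i]], self._vi[preds[j]],
                                              f"r({preds[i]},{preds[j]})"))
                        declared.add(key)
        for f in spec.factors:
            for ind in f.indicators:
                self._a_edges.append((self._vi[ind], self._vi[f.name],
                                      f"l({f.name},{ind})"))
        for fac, tgt in spec.factor_regressions:
            self._a_edges.append((self._vi[tgt], self._vi[fac], f"b({tgt}~{fac})"))
        for a, b in spec.residual_covariances:
            self._s_edges.append((self._vi[a], self._vi[b], f"rc({a},{b})"))

        endo = {t for t, _, _ in self._a_edges}
        for t, s_, _ in self._a_edges:
            if s_ in endo and s_ < len(self.obs):
                raise InvalidArgumentError(
                    "endogenous observed variables may not have outgoing paths")
        for i, j, lab in self._s_edges:
            if lab.startswith("r(") and (i in endo or j in endo):
                raise InvalidArgumentError(
                    "free correlations must connect exogenous variables; "
                    "use residual covariances for endogenous pairs")
        self._endo = sorted(endo)

    @property
    def param_names(self):
        return list(self._free_names)

    def n_free(self):
        return len(self._free_names)

    @property
    def df(self) -> int:
        return len(self.positions) - self.n_free()

    # -- implied correlations ---------------------------------------------

    def implied(self, theta: np.ndarray):
        """Model-implied correlation matrix and residual variances."""
        n = self.n_all
        A = np.zeros((n, n))
        S0 = np.zeros((n, n))
        for t, s_, lab in self._a_edges:
            A[t, s_] = theta[self._label_to_free[lab]]
        for i, j, lab in self._s_edges:
            S0[i, j] = S0[j, i] = theta[self._label_to_free[lab]]
        for v in range(n):
            if v not in self._endo:
                S0[v, v] = 1.0
        T = np.linalg.inv(np.eye(n) - A)
        sigma0 = T @ S0 @ T.T
        psi = np.zeros(n)
        for v in self._endo:
            psi[v] = 1.0 - sigma0[v, v]
        sigma = sigma0 + np.diag(psi)
        ko = len(self.obs)
        return sigma[:ko, :ko], psi[:ko]

    def sigma_vec(self, theta: np.ndarray) -> np.ndarray:
        sig, _ = self.implied(theta)
        return np.array([sig[i, j] for i, j in self.pairs])

    def _jacobian(self, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
        q = len(theta)
        jac = np.empty((len(self.positions), q))
        for a in range(q):
            tp = theta.copy()
            tm = theta.copy()
            tp[a] += h
            tm[a] -= h
            jac[:, a] = (self.sigma_vec(tp) - self.sigma_vec(tm)) / (2 * h)
        return jac

    # -- starting values ---------------------------------------------------

    def _start(self) -> np.ndarray:
        theta = np.zeros(self.n_free())
        filled = np.zeros(self.n_free(), dtype=bool)
        ko = len(self.obs)
        for i, j, lab in self._s_edges:
            idx = self._label_to_free[lab]
            if lab.startswith("r(") and i < ko and j < ko and not filled[idx]:
                theta[idx] = self.R[i, j]
                filled[idx] = True
        for t, s_, lab in self._a_edges:
            idx = self._label_to_free[lab]
            if filled[idx]:
                continue
            if lab.startswith("l("):
                theta[idx] = 0.5
                filled[idx] = True
            elif s_ >= ko:  # factor -> target path
                theta[idx] = 0.2
                filled[idx] = True
        # shared (equality) correlations average the observed entries
        for eqset in self.spec.equality_sets:
            rep = eqset[0]
            idx = self._label_to_free[rep]
            vals = []
            for lab in eqset:
                if lab.startswith("r("):
                    inner = lab[2:-1].split(",")
                    a, b = inner[0], inner[1]
                    if a in self._vi and b in self._vi:
                        ia, ib = self._vi[a], self._vi[b]
                        if ia < ko and ib < ko:
                            vals.append(self.R[ia, ib])
            if vals:
                theta[idx] = float(np.mean(vals))
        return theta

    # -- fitting -----------------------------------------------------------

    def _bounds(self):
        """Parameter bounds on the correlation metric.

        Correlations live in [-1, 1]; loadings, factor paths and residual
        covariances in [-1.5, 1.5] (room to detect Heywood cases while
        blocking the unidentified ridge a fixed unit diagonal leaves
        open); observed-variable regression weights in [-5, 5] to allow
        suppression.
        """
        latents = set(self.latents)
        lower = np.empty(self.n_free())
        upper = np.empty(self.n_free())
        seen = set()
        for lab in self._labels:
            idx = self._label_to_free[lab]
            if idx in seen:
                continue
            seen.add(idx)
            if lab.startswith("r("):
                lo, hi = -1.0, 1.0
            elif lab.startswith("b("):
                source = lab[2:-1].split("~")[1]
                lo, hi = (-1.5, 1.5) if source in latents else (-5.0, 5.0)
            else:  # loadings, residual covariances
                lo, hi = -1.5, 1.5
            lower[idx], upper[idx] = lo, hi
        return lower, upper

    def fit(self, seed: int = 0, n_starts: int = 3) -> FitResult:
        """Minimize the DWLS discrepancy from ``n_starts`` jittered starts."""
        sqrt_w = 1.0 / np.sqrt(self.D)
        s = self.s

        def resid(theta):
            return (s - self.sigma_vec(theta)) * sqrt_w

        rng = np.random.default_rng(seed)
        lower, upper = self._bounds()
        base = np.clip(self._start(), lower + 1e-9, upper - 1e-9)
        best = None
        for trial in range(max(1, n_starts)):
            start = base if trial == 0 else np.clip(
                base + rng.uniform(-0.1, 0.1, base.shape),
                lower + 1e-9, upper - 1e-9)
            sol = optimize.least_squares(resid, start, method="trf",
                                         bounds=(lower, upper),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                         max_nfev=5000)
            if best is None or sol.cost < best.cost:
                best = sol
        theta = best.x
        if self.spec.factors:
            theta = self._fix_factor_signs(theta)
        r = s - self.sigma_vec(theta)
        fitval = float(np.sum(r**2 / self.D))
        delta = self._jacobian(theta)

        grad = -2.0 * delta.T @ (r / self.D) if delta.size else np.zeros(0)
        # projected gradient: directions blocked by an active bound are free
        pg = grad.copy()
        at_lower = theta <= lower + 1e-8
        at_upper = theta >= upper - 1e-8
        pg[at_lower & (pg > 0)] = 0.0
        pg[at_upper & (pg < 0)] = 0.0
        gscale = 1.0 + float(np.max(np.abs(2.0 * delta.T @ (np.abs(s) / self.D)))) \
            if delta.size else 1.0
        partial = FitResult(param_names=self.param_names, theta=theta,
                            se=np.full_like(theta, np.nan), fitval=fitval,
                            residuals=r, df=self.df, chisq=np.nan, p=np.nan,
                            cov_params=np.full((len(theta), len(theta)), np.nan))
        if pg.size and np.max(np.abs(pg)) > GRADIENT_TOL * gscale:
            raise ConvergenceError(
                f"gradient norm {np.max(np.abs(pg)):.3g} above tolerance "
                "after multi-start", best=partial)

        V_off = self.V_R[np.ix_(self.positions, self.positions)]
        if delta.size:
            bread = np.linalg.pinv(delta.T @ (delta / self.D[:, None]))
            mid = delta.T @ (V_off / self.D[:, None] / self.D[None, :]) @ delta
            cov = bread @ mid @ bread
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        else:
            cov = np.zeros((0, 0))
            se = np.zeros(0)

        chisq, dfree, p = _residual_chisq_core(r, delta, self.D, V_off, self.df)

        flags = []
        loadings = [theta[self._label_to_free[lab]]
                    for _, _, lab in self._a_edges if lab.startswith("l(")]
        if any(abs(l) > 1.0 + HEYWOOD_TOL for l in loadings):
            flags.append("heywood")
        _, psi = self.implied(theta)
        if np.any(psi < -HEYWOOD_TOL):
            flags.append("inadmissible")

        return FitResult(param_names=self.param_names, theta=theta, se=se,
                         fitval=fitval, residuals=r, df=dfree, chisq=chisq,
                         p=p, cov_params=cov, flags=flags,
                         n_starts_used=max(1, n_starts),
                         _delta=delta, _weights=self.D,
                         _positions=list(self.positions))

    def _fix_factor_signs(self, theta: np.ndarray) -> np.ndarray:
        """Sign convention: first loading of each factor is positive."""
        theta = theta.copy()
        for f in self.spec.factors:
            first = f"l({f.name},{f.indicators[0]})"
            if theta[self._label_to_free[first]] < 0:
                for _, s_, lab in self._a_edges:
                    if self.all_vars[s_] == f.name:
                        idx = self._label_to_free[lab]
                        theta[idx] = -theta[idx]
        return theta


def fit_dwls(spec: ModelSpec, R: np.ndarray, V_R: np.ndarray,
             seed: int = 0, n_starts: int = 3) -> FitResult:
    """Fit ``spec`` to (R, V_R) by DWLS; see :class:`StructuralModel`."""
    return StructuralModel(spec, R, V_R).fit(seed=seed, n_starts=n_starts)


# ---------------------------------------------------------------------------
# model chi-square


def _residual_chisq_core(resid, delta, D, V_off, df):
    if df <= 0:
        return 0.0, 0, 1.0
    p = len(resid)
    if delta.size:
        bread = np.linalg.pinv(delta.T @ (delta / D[:, None]))
        U = np.eye(p) - delta @ bread @ (delta.T / D[None, :])
    else:
        U = np.eye(p)
    gamma = U @ V_off @ U.T
    gamma = (gamma + gamma.T) / 2.0
    w, u = np.linalg.eigh(gamma)
    order = np.argsort(w)[::-1]
    w, u = w[order], u[:, order]
    floor = 1e-12 * max(w[0], 1.0)
    rank = min(df, int(np.sum(w > floor)))
    if rank == 0:
        return 0.0, df, 1.0
    proj = u[:, :rank].T @ resid
    t = float(np.sum(proj**2 / w[:rank]))
    return t, df, float(chi2.sf(t, df))


def residual_chisq(fit: FitResult, V_R: np.ndarray):
    """Residual-based model chi-square ``e' Gamma^+ e`` for a fitted model.

    Returns ``(chisq, df, p)``; a saturated model returns ``(0, 0, 1)``.
    """
    if fit.df == 0 or fit._delta is None:
        if fit.df == 0:
            return 0.0, 0, 1.0
        raise InvalidArgumentError("fit lacks the internals for the chi-square")
    V_off = np.asarray(V_R, dtype=float)[np.ix_(fit._positions, fit._positions)]
    return _residual_chisq_core(fit.residuals, fit._delta, fit._weights,
                                V_off, fit.df)


def wald_equality_test(R: np.ndarray, V_R: np.ndarray, pair1, pair2,
                       names=None):
    """1-df Wald test that two correlations are equal.

    ``pair1``/``pair2`` are index pairs into ``R`` (or label pairs when
    ``names`` is given).  Returns ``(chisq, df=1, p)`` using
    ``chi2 = (r1 - r2)^2 / (var1 + var2 - 2 cov12)`` with the variances
    and covariance read from ``V_R``.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if names is not None:
        lookup = {n: i for i, n in enumerate(names)}
        pair1 = (lookup[pair1[0]], lookup[pair1[1]])
        pair2 = (lookup[pair2[0]], lookup[pair2[1]])
    p1 = vech_position(pair1[0], pair1[1], k)
    p2 = vech_position(pair2[0], pair2[1], k)
    r1, r2 = R[pair1[0], pair1[1]], R[pair2[0], pair2[1]]
    var1, var2 = V_R[p1, p1], V_R[p2, p2]
    cov12 = V_R[p1, p2]
    denom = var1 + var2 - 2.0 * cov12
    if denom <= 0:
        raise DegenerateContrastError(
            f"non-positive contrast variance {denom:.3g}")
    stat = (r1 - r2) ** 2 / denom
    return float(stat), 1, float(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# genetic multiple regression (closed form + delta method)


@dataclass
class MultipleRegressionResult:
    outcome: str
    predictors: tuple
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    predictor_correlation: float

    def summary(self) -> str:
        lines = [f"genetic multiple regression of {self.outcome!r} "
                 f"(predictor r = {self.predictor_correlation:.3f})",
                 f"{'predictor':<20}{'beta':>10}{'SE':>10}{'p':>12}"]
        for name, b, s, p in zip(self.predictors, self.betas, self.ses, self.pvalues):
            lines.append(f"{name:<20}{b:>10.4f}{s:>10.4f}{p:>12.3g}")
        return "\n".join(lines)


COLLINEARITY_LIMIT = 0.95


def genetic_multiple_regression(R: np.ndarray, V_R: np.ndarray, outcome: str,
                                predictors, names) -> MultipleRegressionResult:
    """Standardized partial effects of two correlated genetic predictors.

    ``beta = Rxx^-1 rxy`` with delta-method standard errors propagating
    ``V_R`` through the closed form.  Refuses to fit when the predictor
    correlation magnitude reaches 0.95 (the collinearity guard that
    excludes near-duplicate strata from interpretation).
    """
    if len(predictors) != 2:
        raise InvalidArgumentError("exactly two predictors are supported")
    lookup = {n: i for i, n in enumerate(names)}
    y = lookup[outcome]
    x1, x2 = (lookup[p] for p in predictors)
    k = R.shape[0]
    r12 = float(R[x1, x2])
    if abs(r12) >= COLLINEARITY_LIMIT:
        raise CollinearityError(
            f"predictors {predictors[0]!r} and {predictors[1]!r} are collinear "
            f"(r = {r12:.2f}); partial effects are uninterpretable",
            pair=tuple(predictors))
    r1y = float(R[x1, y])
    r2y = float(R[x2, y])
    det = 1.0 - r12**2
    beta = np.array([(r1y - r12 * r2y) / det, (r2y - r12 * r1y) / det])

    # delta method over u = (r12, r1y, r2y)
    jac = np.array([
        [(-r2y * det + 2 * r12 * (r1y - r12 * r2y)) / det**2, 1.0 / det, -r12 / det],
        [(-r1y * det + 2 * r12 * (r2y - r12 * r1y)) / det**2, -r12 / det, 1.0 / det],
    ])
    idx = [vech_position(x1, x2, k), vech_position(x1, y, k), vech_position(x2, y, k)]
    cov_u = np.asarray(V_R, dtype=float)[np.ix_(idx, idx)]
    cov_b = jac @ cov_u @ jac.T
    ses = np.sqrt(np.clip(np.diag(cov_b), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, beta / ses, np.inf)
    pvals = 2.0 * norm.sf(np.abs(z))
    return MultipleRegressionResult(outcome=outcome, predictors=tuple(predictors),
                                    betas=beta, ses=ses, pvalues=pvals,
                                    predictor_correlation=r12)


# ---------------------------------------------------------------------------
# common-factor residualization


def equality_constrained_spec(stratum_a: str, stratum_b: str, external: str,
                              variables) -> ModelSpec:
    """3-variable model with r(a, ext) = r(b, ext) constrained equal."""
    return ModelSpec(
        variables=tuple(variables),
        correlations=((stratum_a, stratum_b), (stratum_a, external),
                      (stratum_b, external)),
        equality_sets=((f"r({stratum_a},{external})",
                        f"r({stratum_b},{external})"),),
    )


@dataclass
class FactorResidualResult:
    """Common-factor residualization fit.

    ``adjusted`` maps each target pair to its standardized residual
    association (the correlation left after removing the factor);
    ``adjusted_cov`` is the sampling covariance of those values in
    ``pair_order``.  ``paths`` maps each target to its factor path.
    """

    fit: FitResult
    factor: str
    indicators: tuple
    targets: tuple
    paths: dict
    path_ses: dict
    adjusted: dict
    adjusted_cov: np.ndarray
    pair_order: list

    def adjusted_se(self, pair) -> float:
        i = self.pair_order.index(tuple(pair))
        return float(np.sqrt(max(self.adjusted_cov[i, i], 0.0)))

    def adjusted_value(self, pair) -> float:
        return self.adjusted[tuple(pair)]


def factor_residual_model(R: np.ndarray, V_R: np.ndarray, indicators,
                          targets, names, seed: int = 0) -> FactorResidualResult:
    """Fit a common factor over ``indicators`` predicting each target.

    The factor has unit variance and free loadings; each target receives
    a factor path; targets keep free residual covariances among
    themselves.  Those residual covariances, standardized by the residual
    standard deviations ``sqrt(1 - b^2)``, are the factor-adjusted
    associations.
    """
    indicators = tuple(indicators)
    targets = tuple(targets)
    if len(indicators) < 3:
        raise InvalidArgumentError("need at least 3 indicators to identify the factor")
    if set(indicators) & set(targets):
        raise InvalidArgumentError("targets must be disjoint from indicators")
    order = [n for n in names if n in set(indicators) | set(targets)]
    lookup = {n: i for i, n in enumerate(names)}
    if len(order) < len(indicators) + len(targets):
        raise InvalidArgumentError("indicators/targets missing from names")

    # restrict R, V_R to the modeled variables, preserving dependencies
    idx = [lookup[n] for n in order]
    k_old = R.shape[0]
    k = len(idx)
    keep = [vech_position(idx[i], idx[j], k_old)
            for j in range(k) for i in range(j, k)]
    R_sub = np.asarray(R, dtype=float)[np.ix_(idx, idx)]
    V_sub = np.asarray(V_R, dtype=float)[np.ix_(keep, keep)]

    pair_list = [(targets[i], targets[j])
                 for i in range(len(targets)) for j in range(i + 1, len(targets))]
    spec = ModelSpec(
        variables=tuple(order),
        factors=(Factor("F", indicators),),
        factor_regressions=tuple(("F", t) for t in targets),
        residual_covariances=tuple(pair_list),
    )
    model = StructuralModel(spec, R_sub, V_sub)
    fit = model.fit(seed=seed)

    path_idx = {t: fit.param_names.index(f"b({t}~F)") for t in targets}
    rc_idx = {pr: fit.param_names.index(f"rc({pr[0]},{pr[1]})") for pr in pair_list}
    theta = fit.theta

    def adjusted_vector(th):
        out = np.empty(len(pair_list))
        for m, (a, b) in enumerate(pair_list):
            ba, bb = th[path_idx[a]], th[path_idx[b]]
            da = max(1.0 - ba**2, 1e-8)
            db = max(1.0 - bb**2, 1e-8)
            out[m] = th[rc_idx[(a, b)]] / np.sqrt(da * db)
        return out

    vals = adjusted_vector(theta)
    h = 1e-6
    jac = np.empty((len(pair_list), len(theta)))
    for a in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[a] += h
        tm[a] -= h
        jac[:, a] = (adjusted_vector(tp) - adjusted_vector(tm)) / (2 * h)
    adj_cov = jac @ fit.cov_params @ jac.T

    return FactorResidualResult(
        fit=fit, factor="F", indicators=indicators, targets=targets,
        paths={t: float(theta[path_idx[t]]) for t in targets},
        path_ses={t: float(fit.se[path_idx[t]]) for t in targets},
        adjusted={pr: float(v) for pr, v in zip(pair_list, vals)},
        adjusted_cov=adj_cov, pair_order=[tuple(p) for p in pair_list])
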