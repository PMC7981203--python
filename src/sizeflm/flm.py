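"""Penalized functional linear models (scalar-on-function regression).

The model for a vital rate :math:`Y` observed on colony :math:`c` is

.. math::

    g(E[Y]) = \\beta_{0,c} + \\sum_x \\beta(s_x)\\, W_{x} \\;(+\\, \\log d)

where :math:`W_x` is the number of workers in size bin :math:`x` (the worker
size composition), :math:`\\beta(s)` is a smooth size-specific per-capita
slope, :math:`\\beta_{0,c}` are fixed colony intercepts and :math:`d` an
exposure offset in days.  :math:`\\beta(s)` is represented in a natural cubic
regression-spline basis with at most five knots and shrunk by an integrated
squared second-derivative penalty; the penalty null space contains exactly
the linear functions, so heavy smoothing drives the slope function to a
line and, combined with the centering implied by the data, toward zero
effect.

Fitting is by penalized iteratively reweighted least squares for the
Gaussian (identity link), binomial (logit, day trials) and negative-binomial
(log link, NB2 overdispersion profiled by maximum likelihood) families.
The smoothing parameter is selected by generalized cross-validation by
default, with an approximate REML criterion as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator

from .vital_rates import CompositionMatrix, SizeGrid, VitalRateTable

__all__ = [
    "SplineBasis",
    "SmoothFit",
    "CoefficientFunction",
    "FLMConvergenceError",
    "FunctionalLinearModel",
    "build_basis",
    "fit_flm",
    "fit_age_model",
    "coefficient_function",
    "is_unimodal",
    "classify_shape",
    "age_shape_label",
]

MAX_KNOTS = 5  # hard cap on smooth-term knots; GAMs overfit readily here


class FLMConvergenceError(RuntimeError):
    """Penalized IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# natural cubic regression spline basis (value-at-knot parameterization)


def _cr_eval(knots: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cardinal basis matrix M with f(t) = M @ f(knots) for the natural
    cubic interpolant (linear when only two knots)."""
    knots = np.asarray(knots, float)
    t = np.atleast_1d(np.asarray(t, float))
    k = len(knots)
    if k == 2:
        h = knots[1] - knots[0]
        w = (t - knots[0]) / h
        return np.column_stack([1 - w, w])
    h = np.diff(knots)
    # map knot values beta to interior second derivatives: B gamma = D beta
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    G = np.zeros((k, k))  # gamma (with natural end conditions) = G @ beta
    G[1:-1] = linalg.solve(B, D, assume_a="pos")

    j = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, k - 2)
    x0, x1 = knots[j], knots[j + 1]
    hj = x1 - x0
    a = (x1 - t) / hj
    b = (t - x0) / hj
    # f(t) = a f_j + b f_{j+1} + ((a^3-a) g_j + (b^3-b) g_{j+1}) h^2/6
    M = np.zeros((len(t), k))
    rows = np.arange(len(t))
    M[rows, j] += a
    M[rows, j + 1] += b
    ca = (a**3 - a) * hj**2 / 6.0
    cb = (b**3 - b) * hj**2 / 6.0
    M += ca[:, None] * G[j] + cb[:, None] * G[j + 1]
    return M


def _cr_penalty(knots: np.ndarray) -> np.ndarray:
    """Integrated squared second derivative, S = D' B^{-1} D (zero on lines)."""
    knots = np.asarray(knots, float)
    k = len(knots)
    if k == 2:
        return np.zeros((2, 2))
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    return D.T @ linalg.solve(B, D, assume_a="pos")


@dataclass
class SplineBasis:
    """Natural cubic spline basis over a size grid, with its wiggliness penalty."""

    grid: SizeGrid
    n_knots: int
    knots: np.ndarray
    basis_matrix: np.ndarray  # (n_bins, n_knots), evaluated at bin centers
    penalty_matrix: np.ndarray  # (n_knots, n_knots), PSD, null space = lines

    def evaluate(self, s) -> np.ndarray:
        """Basis row(s) at span value(s) ``s`` (mm); ``s`` must lie in the grid."""
        s = np.atleast_1d(np.asarray(s, float))
        lo, hi = self.grid.bin_edges[0], self.grid.bin_edges[-1]
        if np.any(s < lo - 1e-9) or np.any(s > hi + 1e-9):
            raise ValueError(f"evaluation outside grid range [{lo}, {hi}]")
        if self.n_knots == 1:
            return np.ones((len(s), 1))
        return _cr_eval(self.knots, s)


def build_basis(grid: SizeGrid, n_knots: int) -> SplineBasis:
    """Basis at the grid's bin centers with knots spread over the grid range.

    ``n_knots`` is capped at five.  A single-bin grid degenerates to a scalar
    covariate (basis ``[[1]]``, zero penalty): the classical scalar
    regression of the response on total worker count.
    """
    if grid.n_bins == 1:
        return SplineBasis(grid, 1, grid.bin_centers.copy(),
                           np.ones((1, 1)), np.zeros((1, 1)))
    if n_knots > MAX_KNOTS:
        raise ValueError(f"n_knots={n_knots} exceeds the cap of {MAX_KNOTS}")
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    if n_knots > grid.n_bins:
        raise ValueError("n_knots may not exceed the number of size bins")
    knots = np.linspace(grid.bin_edges[0], grid.bin_edges[-1], n_knots)
    M = _cr_eval(knots, grid.bin_centers)
    S = _cr_penalty(knots)
    # normalize the penalty scale so smoothing parameters are comparable
    # across grids and the penalized system stays well conditioned
    eigs = np.linalg.eigvalsh(S)
    pos = eigs[eigs > 1e-10 * max(float(eigs.max()), 1.0)]
    if len(pos):
        S = S / float(np.mean(pos))
    return SplineBasis(grid, n_knots, knots, M, S)


# ---------------------------------------------------------------------------
# exponential-family pieces

_EPS = 1e-10


def _family_init(family, y, ybar, ntrials):
    """Fixed initialization from the unpenalized null (grand-mean) model."""
    if family == "gaussian":
        return np.full(len(y), float(np.mean(y)))
    if family == "binomial":
        p0 = float(np.clip(np.sum(ybar * ntrials) / max(np.sum(ntrials), 1.0),
                           1e-3, 1 - 1e-3))
        return np.full(len(y), math.log(p0 / (1 - p0)))
    mu0 = max(float(np.mean(y)), 0.1)
    return np.full(len(y), math.log(mu0))


def _irls_weights(family, eta, y, ybar, ntrials, alpha):
    """Return (w, z) working weights and response for one IRLS step."""
    if family == "gaussian":
        return np.ones_like(eta), y
    if family == "binomial":
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        p = np.clip(p, _EPS, 1 - _EPS)
        w = ntrials * p * (1 - p)
        z = eta + (ybar - p) / (p * (1 - p))
        return w, z
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    z = eta + (y - mu) / mu
    return w, z


def _deviance(family, y, ybar, ntrials, eta, alpha):
    if family == "gaussian":
        return float(np.sum((y - eta) ** 2))
    if family == "binomial":
        p = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))), _EPS, 1 - _EPS)
        s = ybar * ntrials
        f = ntrials - s
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(s > 0, s * np.log(s / (ntrials * p)), 0.0)
            t2 = np.where(f > 0, f * np.log(f / (ntrials * (1 - p))), 0.0)
        return float(2.0 * np.sum(t1 + t2))
    mu = np.exp(np.clip(eta, -30, 30))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
    return float(2.0 * np.sum(t1 - t2))


def _loglik(family, y, ybar, ntrials, eta, alpha):
    n = len(eta)
    if family == "gaussian":
        rss = float(np.sum((y - eta) ** 2))
        sig2 = max(rss / n, _EPS)
        return -0.5 * n * (math.log(2 * math.pi * sig2) + 1.0)
    if family == "binomial":
        p = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))), _EPS, 1 - _EPS)
        s = ybar * ntrials
        f = ntrials - s
        return float(
            np.sum(
                gammaln(ntrials + 1) - gammaln(s + 1) - gammaln(f + 1)
                + s * np.log(p) + f * np.log(1 - p)
            )
        )
    mu = np.maximum(np.exp(np.clip(eta, -30, 30)), _EPS)
    inv_a = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv_a) - gammaln(inv_a) - gammaln(y + 1)
            + y * np.log(alpha * mu) - (y + inv_a) * np.log1p(alpha * mu)
        )
    )


def _profile_nb_alpha(y, mu):
    """Maximum-likelihood NB2 overdispersion for fixed means."""

    def nll(log_a):
        a = math.exp(log_a)
        inv_a = 1.0 / a
        ll = np.sum(
            gammaln(y + inv_a) - gammaln(inv_a) - gammaln(y + 1)
            + y * np.log(a * mu) - (y + inv_a) * np.log1p(a * mu)
        )
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(math.log(1e-4), math.log(20.0)),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return math.exp(res.x)


# ---------------------------------------------------------------------------
# the estimator


class FunctionalLinearModel(BaseEstimator):
    """Scikit-learn-style penalized functional linear model.

    Parameters
    ----------
    grid : SizeGrid
        Size discretization over which the coefficient function lives.
    n_knots : int, default 5
        Knots of the natural cubic spline basis (2–5).
    family : {"gaussian", "binomial", "negative_binomial"}
        Response family.  Binomial responses are passed to :meth:`fit` as an
        ``(n, 2)`` array of (successes, failures) day trials.
    lam : {"gcv", "reml"} or float, default "gcv"
        Smoothing-parameter selection criterion, or a fixed nonnegative
        value (0 gives an unpenalized fit).
    nb_alpha : float or None
        Fixed NB2 overdispersion; ``None`` profiles it by maximum
        likelihood, alternating with the IRLS updates.
    include_colony_intercepts : bool, default True
        Fixed per-colony intercepts (a shared intercept otherwise).

    Attributes (after ``fit``)
    --------------------------
    coef_ : spline coefficients of the coefficient function.
    intercepts_ : mapping colony id -> fitted intercept.
    lambda_, alpha_, dispersion_, edf_, edf_smooth_, loglik_, aic_, k_,
    smooth_pvalue_, parametric_pvalue_, cov_, n_iter_ : fit summaries.
    """

    def __init__(self, grid=None, n_knots=5, family="gaussian", lam="gcv",
                 nb_alpha=None, include_colony_intercepts=True,
                 include_smooth=True, max_iter=200, tol=1e-8, basis=None):
        self.grid = grid
        self.n_knots = n_knots
        self.family = family
        self.lam = lam
        self.nb_alpha = nb_alpha
        self.include_colony_intercepts = include_colony_intercepts
        self.include_smooth = include_smooth
        self.max_iter = max_iter
        self.tol = tol
        self.basis = basis

    # -- internals ---------------------------------------------------------

    def _prepare(self, X, y, colony_ids, offset_days):
        if self.family not in ("gaussian", "binomial", "negative_binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        X = np.asarray(X, float)
        basis = self.basis if self.basis is not None else build_basis(
            self.grid, self.n_knots)
        if X.shape[1] != basis.basis_matrix.shape[0]:
            raise ValueError("composition columns do not match the size grid")
        Z = X @ basis.basis_matrix if self.include_smooth \
            else np.zeros((len(X), 0))
        n = len(X)

        y = np.asarray(y, float)
        if self.family == "binomial":
            if y.ndim != 2 or y.shape[1] != 2:
                raise ValueError("binomial response must be (successes, failures)")
            ntrials = y.sum(axis=1)
            if np.any(ntrials < 1):
                raise ValueError("every binomial row needs at least one trial")
            ybar = y[:, 0] / ntrials
            yvec = y[:, 0]
        else:
            ntrials = np.ones(n)
            ybar = y
            yvec = y

        if colony_ids is not None and self.include_colony_intercepts:
            colonies = sorted(set(map(str, colony_ids)))
            code = {c: i for i, c in enumerate(colonies)}
            C = np.zeros((n, len(colonies)))
            for i, c in enumerate(map(str, colony_ids)):
                C[i, code[c]] = 1.0
        else:
            colonies = ["_intercept"]
            C = np.ones((n, 1))

        offset = np.zeros(n)
        if offset_days is not None:
            if self.family != "negative_binomial":
                raise ValueError("offsets apply to the count (negative-binomial) family")
            offset = np.log(np.asarray(offset_days, float))

        Xd = np.hstack([C, Z])
        m = C.shape[1]
        S = np.zeros((Xd.shape[1], Xd.shape[1]))
        if Z.shape[1]:
            S[m:, m:] = basis.penalty_matrix
        return basis, Xd, S, m, colonies, yvec, ybar, ntrials, offset

    def _pirls(self, Xd, S, lam, yvec, ybar, ntrials, offset, alpha):
        """One full penalized-IRLS fit at fixed lambda (and alpha for NB)."""
        eta = _family_init(self.family, yvec, ybar, ntrials)
        dev = _deviance(self.family, yvec, ybar, ntrials, eta, alpha)
        trace = [dev]
        theta = None
        prev_theta = None
        flat_devs = 0
        for it in range(self.max_iter):
            w, z = _irls_weights(self.family, eta, yvec, ybar, ntrials, alpha)
            WX = Xd * w[:, None]
            A = Xd.T @ WX + lam * S
            # tiny ridge keeps rank-deficient designs (e.g. unpopulated
            # age bins) numerically stable without moving identified
            # coefficients at the reported precision
            A[np.diag_indices_from(A)] += 1e-10 * (np.trace(A) / A.shape[0]
                                                   + 1.0)
            b = WX.T @ (z - offset)
            try:
                theta = linalg.solve(A, b, assume_a="sym")
            except linalg.LinAlgError:
                theta = linalg.lstsq(A, b)[0]
            eta = Xd @ theta + offset
            if self.family == "binomial" and np.max(np.abs(eta)) > 30:
                raise FLMConvergenceError(
                    "binomial fit diverged (possible complete separation)", trace)
            new_dev = _deviance(self.family, yvec, ybar, ntrials, eta, alpha)
            trace.append(new_dev)
            # converge on coefficients as well as deviance: the deviance
            # flattens quadratically near the optimum, so a deviance-only
            # rule can leave coefficients several digits short
            step = np.inf if prev_theta is None else float(
                np.max(np.abs(theta - prev_theta)) / (1.0 + np.max(np.abs(theta))))
            prev_theta = theta
            if abs(new_dev - dev) < self.tol * (abs(dev) + 0.1):
                flat_devs += 1
            else:
                flat_devs = 0
            # coefficient agreement near machine precision, or a long
            # deviance plateau (degenerate directions that never settle)
            if flat_devs >= 1 and (step < 1e-10 or flat_devs >= 12):
                dev = new_dev
                break
            dev = new_dev
        else:
            raise FLMConvergenceError(
                f"IRLS did not converge in {self.max_iter} iterations", trace)
        w, _ = _irls_weights(self.family, eta, yvec, ybar, ntrials, alpha)
        return theta, eta, w, dev, it + 1

    def _fit_at(self, Xd, S, m, lam, yvec, ybar, ntrials, offset):
        """Fit at fixed lambda, profiling NB overdispersion when needed."""
        alpha = self.nb_alpha if self.nb_alpha is not None else 0.5
        if self.family != "negative_binomial" or self.nb_alpha is not None:
            return (*self._pirls(Xd, S, lam, yvec, ybar, ntrials, offset, alpha),
                    alpha)
        for _ in range(15):
            theta, eta, w, dev, nit = self._pirls(
                Xd, S, lam, yvec, ybar, ntrials, offset, alpha)
            mu = np.exp(np.clip(eta, -30, 30))
            new_alpha = _profile_nb_alpha(yvec, mu)
            if abs(math.log(new_alpha) - math.log(alpha)) < 1e-4:
                alpha = new_alpha
                break
            alpha = new_alpha
        theta, eta, w, dev, nit = self._pirls(
            Xd, S, lam, yvec, ybar, ntrials, offset, alpha)
        return theta, eta, w, dev, nit, alpha

    def _edf(self, Xd, S, w, lam):
        WX = Xd * w[:, None]
        XtWX = Xd.T @ WX
        A = XtWX + lam * S
        A[np.diag_indices_from(A)] += 1e-10 * (np.trace(A) / A.shape[0] + 1.0)
        try:
            F = linalg.solve(A, XtWX, assume_a="sym")
        except linalg.LinAlgError:
            F = linalg.lstsq(A, XtWX)[0]
        return F, XtWX, A

    def _criterion(self, kind, Xd, S, m, lam, yvec, ybar, ntrials, offset):
        try:
            theta, eta, w, dev, _, alpha = self._fit_at(
                Xd, S, m, lam, yvec, ybar, ntrials, offset)
        except FLMConvergenceError:
            return np.inf
        F, XtWX, A = self._edf(Xd, S, w, lam)
        edf = float(np.trace(F))
        n = len(yvec)
        if kind == "gcv":
            denom = max(n - edf, 1e-3)
            return n * dev / denom**2
        # approximate Laplace REML: penalized ll minus half log-determinants
        ll = _loglik(self.family, yvec, ybar, ntrials, eta, alpha)
        phi = max(dev / max(n - edf, 1.0), _EPS) if self.family == "gaussian" else 1.0
        pen = float(theta @ (S @ theta))
        sign, logdet_A = np.linalg.slogdet(A / phi)
        eigs = np.linalg.eigvalsh(S)
        pos = eigs[eigs > 1e-10 * max(eigs.max(), 1.0)]
        logdet_S = float(np.sum(np.log(lam * pos / phi))) if lam > 0 and len(pos) else 0.0
        return -(ll - 0.5 * lam * pen / phi) + 0.5 * logdet_A - 0.5 * logdet_S

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, colony_ids=None, offset_days=None):
        basis, Xd, S, m, colonies, yvec, ybar, ntrials, offset = self._prepare(
            X, y, colony_ids, offset_days)
        n = len(yvec)

        if isinstance(self.lam, str):
            kind = self.lam
            if kind not in ("gcv", "reml"):
                raise ValueError("lam must be 'gcv', 'reml', or a number")
            if Xd.shape[1] == m or np.allclose(basis.penalty_matrix, 0):
                lam = 0.0
            else:
                grid_l = np.logspace(-6, 7, 27)
                crits = [self._criterion(kind, Xd, S, m, l, yvec, ybar,
                                         ntrials, offset) for l in grid_l]
                best = int(np.argmin(crits))
                lo = grid_l[max(best - 1, 0)]
                hi = grid_l[min(best + 1, len(grid_l) - 1)]
                if lo < hi:
                    res = optimize.minimize_scalar(
                        lambda ll: self._criterion(kind, Xd, S, m, math.exp(ll),
                                                   yvec, ybar, ntrials, offset),
                        bounds=(math.log(lo), math.log(hi)), method="bounded",
                        options={"xatol": 1e-2})
                    lam = math.exp(res.x)
                    if self._criterion(kind, Xd, S, m, grid_l[best], yvec, ybar,
                                       ntrials, offset) < res.fun:
                        lam = grid_l[best]
                else:
                    lam = grid_l[best]
        else:
            lam = float(self.lam)
            if lam < 0:
                raise ValueError("lam must be nonnegative")

        theta, eta, w, dev, nit, alpha = self._fit_at(
            Xd, S, m, lam, yvec, ybar, ntrials, offset)
        F, XtWX, A = self._edf(Xd, S, w, lam)
        edf = float(np.trace(F))
        edf_smooth = float(np.trace(F[m:, m:]))

        ll = _loglik(self.family, yvec, ybar, ntrials, eta, alpha)
        if self.family == "gaussian":
            phi = dev / max(n - edf, 1.0)
        else:
            phi = 1.0
        try:
            Vp = phi * linalg.inv(A)
        except linalg.LinAlgError:
            Vp = phi * linalg.pinvh(A)

        # scale-ish parameters count toward AIC's k
        k = edf + (1.0 if self.family in ("gaussian", "negative_binomial") else 0.0)

        self.basis_ = basis
        self.colonies_ = colonies
        self.n_parametric_ = m
        self.coef_ = theta[m:].copy()
        self.intercepts_ = {c: float(theta[i]) for i, c in enumerate(colonies)}
        self.theta_ = theta
        self.lambda_ = float(lam)
        self.alpha_ = float(alpha) if self.family == "negative_binomial" else None
        self.dispersion_ = float(phi) if self.family == "gaussian" else (
            float(alpha) if self.family == "negative_binomial" else 1.0)
        self.edf_ = edf
        self.edf_smooth_ = max(edf_smooth, 0.0)
        self.deviance_ = float(dev)
        self.loglik_ = float(ll)
        self.k_ = float(k)
        self.aic_ = -2.0 * ll + 2.0 * k
        self.cov_ = Vp
        self.n_iter_ = nit
        self.n_obs_ = n
        self._offset_used = offset_days is not None

        self.smooth_pvalue_, self.smooth_statistic_ = self._smooth_test(Vp, m, n)
        self.parametric_pvalue_ = self._parametric_test(Vp, m, n)
        return self

    def _smooth_test(self, Vp, m, n):
        """Wald-type test of the smooth term, rank ~ rounded EDF.

        These p-values are approximate (and tend to be anti-conservative),
        which is why downstream selection applies the stricter .01 cutoff.
        """
        ts = self.theta_[m:]
        if len(ts) == 0:
            return float("nan"), 0.0
        Vs = Vp[m:, m:]
        r = max(1, int(round(self.edf_smooth_)))
        r = min(r, len(ts))
        evals, evecs = linalg.eigh(Vs)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.maximum(evals, _EPS)
        proj = evecs[:, :r].T @ ts
        stat = float(np.sum(proj**2 / evals[:r]))
        if self.family == "gaussian":
            p = float(f_dist.sf(stat / r, r, max(n - self.edf_, 1.0)))
        else:
            p = float(chi2_dist.sf(stat, r))
        return p, stat

    def _parametric_test(self, Vp, m, n):
        """Wald test that all colony intercepts are equal."""
        if m < 2:
            return float("nan")
        C = np.zeros((m - 1, Vp.shape[0]))
        for i in range(m - 1):
            C[i, 0] = 1.0
            C[i, i + 1] = -1.0
        d = C @ self.theta_
        V = C @ Vp @ C.T
        try:
            stat = float(d @ linalg.solve(V, d, assume_a="sym"))
        except linalg.LinAlgError:
            stat = float(d @ linalg.pinvh(V) @ d)
        if self.family == "gaussian":
            return float(f_dist.sf(stat / (m - 1), m - 1, max(n - self.edf_, 1.0)))
        return float(chi2_dist.sf(stat, m - 1))

    def linear_predictor(self, X, colony_ids=None, offset_days=None):
        X = np.asarray(X, float)
        if self.coef_.size:
            eta = (X @ self.basis_.basis_matrix) @ self.coef_
        else:
            eta = np.zeros(len(X))
        if colony_ids is not None:
            eta = eta + np.array([self.intercepts_[str(c)] for c in colony_ids])
        else:
            eta = eta + np.mean(list(self.intercepts_.values()))
        if offset_days is not None:
            eta = eta + np.log(np.asarray(offset_days, float))
        return eta

    def predict(self, X, colony_ids=None, offset_days=None):
        """Expected response on the natural scale."""
        eta = self.linear_predictor(X, colony_ids, offset_days)
        if self.family == "gaussian":
            return eta
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return np.exp(eta)


# ---------------------------------------------------------------------------
# record types and functional wrappers


@dataclass
class SmoothFit:
    """Summary of one fitted functional linear model."""

    family: str
    colony_intercepts: dict[str, float]
    spline_coefficients: np.ndarray
    smoothing_parameter: float
    dispersion: float
    edf: float  # effective degrees of freedom of the smooth term
    k: float  # effective parameter count entering the AIC
    loglik: float
    aic: float
    smooth_pvalue: float
    parametric_pvalue: float
    n_knots: int
    n_obs: int
    basis: SplineBasis
    cov_spline: np.ndarray
    estimator: FunctionalLinearModel = field(repr=False, default=None)

    @classmethod
    def from_estimator(cls, est: FunctionalLinearModel) -> "SmoothFit":
        m = est.n_parametric_
        return cls(
            family=est.family,
            colony_intercepts=dict(est.intercepts_),
            spline_coefficients=est.coef_.copy(),
            smoothing_parameter=est.lambda_,
            dispersion=est.dispersion_,
            edf=est.edf_smooth_,
            k=est.k_,
            loglik=est.loglik_,
            aic=est.aic_,
            smooth_pvalue=est.smooth_pvalue_,
            parametric_pvalue=est.parametric_pvalue_,
            n_knots=est.basis_.n_knots,
            n_obs=est.n_obs_,
            basis=est.basis_,
            cov_spline=est.cov_[m:, m:].copy(),
            estimator=est,
        )


@dataclass
class CoefficientFunction:
    """The fitted size-specific per-capita slope function beta(s)."""

    basis: SplineBasis
    coefficients: np.ndarray
    cov: np.ndarray

    @property
    def grid_values(self) -> np.ndarray:
        if self.coefficients.size == 0:  # dropped smooth: the zero function
            return np.zeros(self.basis.grid.n_bins)
        return self.basis.basis_matrix @ self.coefficients

    @property
    def pointwise_se(self) -> np.ndarray:
        if self.coefficients.size == 0:
            return np.zeros(self.basis.grid.n_bins)
        B = self.basis.basis_matrix
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, self.cov, B), 0.0))

    def __call__(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        if self.coefficients.size == 0:
            return np.zeros(len(s))
        return self.basis.evaluate(s) @ self.coefficients

    def se(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        if self.coefficients.size == 0:
            return np.zeros(len(s))
        M = self.basis.evaluate(s)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", M, self.cov, M), 0.0))


def fit_flm(
    table: VitalRateTable,
    comp: CompositionMatrix,
    basis: SplineBasis,
    family: str | None = None,
    include_colony_intercepts: bool = True,
    lam="gcv",
    nb_alpha=None,
    include_smooth: bool = True,
) -> SmoothFit:
    """Fit the functional linear model for one vital-rate table."""
    if comp.counts.shape[0] != table.n:
        raise ValueError("composition rows do not align with the response table")
    family = family or table.family
    offset = table.df["offset_days"].to_numpy(float) \
        if "offset_days" in table.df.columns else None
    est = FunctionalLinearModel(
        grid=comp.grid, family=family, lam=lam, nb_alpha=nb_alpha,
        include_colony_intercepts=include_colony_intercepts,
        include_smooth=include_smooth, basis=basis)
    est.fit(comp.counts, table.response_matrix(),
            colony_ids=table.df["colony_id"], offset_days=offset)
    return SmoothFit.from_estimator(est)


def coefficient_function(fit: SmoothFit, basis: SplineBasis | None = None
                         ) -> CoefficientFunction:
    basis = basis or fit.basis
    return CoefficientFunction(basis, fit.spline_coefficients, fit.cov_spline)


def is_unimodal(cf: CoefficientFunction, grid: SizeGrid, n_eval: int = 101) -> bool:
    """True iff the function has at most one interior mode over the grid.

    Evaluated on ``n_eval`` equally spaced points; the sign sequence of
    first differences may change at most once, so monotone and single
    peak/valley functions pass and multimodal ones fail.
    """
    if n_eval < 50:
        raise ValueError("n_eval must be >= 50")
    s = np.linspace(grid.bin_edges[0], grid.bin_edges[-1], n_eval)
    v = cf(s)
    d = np.diff(v)
    scale = max(float(np.max(np.abs(v))), 1e-12)
    signs = [int(np.sign(x)) for x in d if abs(x) > 1e-9 * scale]
    changes = sum(1 for a, b in zip(signs[:-1], signs[1:]) if a != b)
    return changes <= 1


def classify_shape(cf: CoefficientFunction, grid: SizeGrid,
                   n_eval: int = 101) -> tuple[str, str]:
    """Label the per-capita sign and size trend of a coefficient function.

    Sign: pointwise values whose +/- 2 SE band covers zero count as no
    effect; the label is ``positive`` / ``negative`` / ``mixed`` / ``none``.
    Trend from first differences: ``increasing`` / ``decreasing`` / ``both``
    / ``none``.
    """
    s = np.linspace(grid.bin_edges[0], grid.bin_edges[-1], n_eval)
    v = cf(s)
    se = cf.se(s)
    nonzero = np.abs(v) > 2.0 * se
    has_pos = bool(np.any(nonzero & (v > 0)))
    has_neg = bool(np.any(nonzero & (v < 0)))
    if has_pos and has_neg:
        sign = "mixed"
    elif has_pos:
        sign = "positive"
    elif has_neg:
        sign = "negative"
    else:
        sign = "none"
    if sign == "none":
        return "none", "none"
    d = np.diff(v)
    scale = max(float(np.max(np.abs(v))), 1e-12)
    up = bool(np.any(d > 1e-6 * scale))
    down = bool(np.any(d < -1e-6 * scale))
    if up and down:
        trend = "both"
    elif up:
        trend = "increasing"
    elif down:
        trend = "decreasing"
    else:
        trend = "none"
    return sign, trend


def fit_age_model(
    table: VitalRateTable,
    colony_age: Sequence[float],
    family: str | None = None,
    n_knots: int = MAX_KNOTS,
    lam="gcv",
    include_colony_intercepts: bool = True,
) -> SmoothFit:
    """Fit the same machinery with a univariate smooth of colony age.

    Colony age replaces the functional composition term; the result is used
    to screen for confounding between colony age and worker numbers.
    """
    ages = np.asarray(colony_age, float)
    if np.any(ages <= 0):
        raise ValueError("colony ages must be positive")
    family = family or table.family
    lo, hi = float(ages.min()), float(ages.max())
    if not hi > lo:
        raise ValueError("degenerate age range")
    # a univariate smooth is a functional term over a 1-wide identity design:
    # bins at unique-age resolution with one "worker" in the row's own bin
    grid = SizeGrid(np.linspace(lo - 1e-9, hi + 1e-9, 65))
    X = np.zeros((len(ages), grid.n_bins))
    X[np.arange(len(ages)), grid.bin_index(ages)] = 1.0
    offset = table.df["offset_days"].to_numpy(float) \
        if "offset_days" in table.df.columns else None
    est = FunctionalLinearModel(
        grid=grid, n_knots=n_knots, family=family, lam=lam,
        include_colony_intercepts=include_colony_intercepts)
    est.fit(X, table.response_matrix(), colony_ids=table.df["colony_id"],
            offset_days=offset)
    return SmoothFit.from_estimator(est)


def age_shape_label(fit: SmoothFit, alpha_smooth: float = 0.01,
                    n_eval: int = 201) -> str:
    """Shape label for a univariate age smooth.

    One of ``Constant``, ``Increases``, ``Decreases``, ``Concave``,
    ``Convex``, ``Multimodal``: non-significant smooths are Constant;
    monotone fits Increase/Decrease; one interior maximum is Concave, one
    interior minimum Convex; more extrema are Multimodal.
    """
    if not (fit.smooth_pvalue < alpha_smooth):
        return "Constant"
    cf = coefficient_function(fit)
    grid = fit.basis.grid
    s = np.linspace(grid.bin_edges[0], grid.bin_edges[-1], n_eval)
    v = cf(s)
    d = np.diff(v)
    scale = max(float(np.max(np.abs(v))), 1e-12)
    signs = [int(np.sign(x)) for x in d if abs(x) > 1e-8 * scale]
    if not signs:
        return "Constant"
    changes = [(a, b) for a, b in zip(signs[:-1], signs[1:]) if a != b]
    if not changes:
        return "Increases" if signs[0] > 0 else "Decreases"
    if len(changes) == 1:
        return "Concave" if changes[0] == (1, -1) else "Convex"
    return "Multimodal"
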