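"""Logistic mixed-effects analysis of the stepped-wedge ALRI panel.

The analysis model for child j in village (sector) i at month t is

    logit Pr(Y_ijt = 1) = alpha0 + b_i + c_ij + s(t, v) + theta * X_it

with independent Normal random intercepts b_i ~ N(0, sigma2_village) and
c_ij ~ N(0, sigma2_child), a natural cubic spline time function s(t, v) with
v degrees of freedom absorbing secular and seasonal variation, and theta the
stove-intervention effect of primary interest.

Estimation maximizes the Laplace-approximated marginal likelihood.  The
nested (child-within-sector) structure makes the joint penalized Hessian of
the random effects arrow-shaped within each sector, so the Newton solve and
the Laplace log-determinant are linear-time in the number of children; the
two variance parameters are profiled by an outer derivative-free optimizer.
An adaptive Gauss-Hermite path is provided as an accuracy audit for
single-level models, and a cluster-aggregated sandwich estimator gives
robust standard errors for theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "natural_spline_basis",
    "SteppedWedgeLogit",
    "SteppedWedgeLogitResults",
    "robust_variance",
    "sensitivity_over_v",
    "fit_birthweight",
    "BirthweightResults",
    "anova_icc",
]


@dataclass(frozen=True)
class ModelSpec:
    """Analysis-model configuration.

    ``v`` is the spline degrees of freedom (0 disables the time function;
    1 is rejected since a natural spline needs at least the linear term plus
    one constraint); ``cluster_level`` chooses the unit for the robust
    variance ("sector", 51 analysis villages in the field design, or
    "group", the 12 randomization units).
    """

    v: int = 8
    cluster_level: Literal["sector", "group"] = "sector"
    include_child_effect: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.v == 1 or self.v < 0 or self.v > 12:
            raise ValueError("v must be 0 or between 2 and 12")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cluster_level not in ("sector", "group"):
            raise ValueError("cluster_level must be 'sector' or 'group'")


def natural_spline_basis(
    t: Sequence[float],
    v: int,
    boundary: tuple[float, float] | None = None,
    interior_knots: Sequence[float] | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Natural cubic spline basis with ``v`` degrees of freedom (no intercept).

    Uses the truncated-power natural basis: the linear term plus ``v - 1``
    cubic terms constrained to be linear beyond the boundary knots.  Interior
    knots sit at equally spaced quantiles of the observed ``t``; boundary
    knots at the min/max.  Columns are centered and scaled (span-preserving)
    for numerical conditioning.
    """
    t = np.asarray(t, dtype=float)
    if v == 0:
        return np.empty((t.size, 0))
    if v < 2:
        raise ValueError("v must be 0 or >= 2")
    uniq = np.unique(t)
    if uniq.size < 2:
        raise ValueError("t must take at least two distinct values")
    if uniq.size < v + 1:
        raise ValueError(
            f"v={v} requires at least {v + 1} distinct time points, got {uniq.size}"
        )
    lo, hi = boundary if boundary is not None else (uniq[0], uniq[-1])
    if interior_knots is None:
        probs = np.arange(1, v) / v
        interior = np.quantile(uniq, probs)
    else:
        interior = np.asarray(interior_knots, dtype=float)
        if interior.size != v - 1:
            raise ValueError("need v - 1 interior knots")
    knots = np.concatenate([[lo], interior, [hi]])  # K = v + 1 knots
    K = knots.size

    def d(k: int) -> np.ndarray:
        num = np.clip(t - knots[k], 0, None) ** 3 - np.clip(t - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [t]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    basis = np.column_stack(cols)
    if standardize:
        mean = basis.mean(axis=0)
        scale = basis.std(axis=0)
        scale[scale == 0] = 1.0
        basis = (basis - mean) / scale
    return basis


# ---------------------------------------------------------------------------
# Laplace engine for the nested random-intercept logistic model


class _NestedLaplaceEngine:
    """Laplace-approximated ML for logit(p) = X beta + b[sector] + c[child].

    ``sector_idx`` (and optionally ``child_idx``) are dense 0-based codes.
    The child level must be nested in the sector level.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        sector_idx: np.ndarray,
        child_idx: np.ndarray | None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.sector = np.asarray(sector_idx, dtype=np.intp)
        self.S = int(self.sector.max()) + 1 if len(self.sector) else 0
        self.p = self.X.shape[1]
        self.has_child = child_idx is not None
        if self.has_child:
            self.child = np.asarray(child_idx, dtype=np.intp)
            self.C = int(self.child.max()) + 1
            # nesting check: max and min sector per child must agree
            mx = np.full(self.C, -1)
            mn = np.full(self.C, np.iinfo(np.int64).max)
            np.maximum.at(mx, self.child, self.sector)
            np.minimum.at(mn, self.child, self.sector)
            if not np.array_equal(mx, mn):
                raise ValueError("child level is not nested within sectors")
            self.child_sector = mx
        else:
            self.child = None
            self.C = 0
            self.child_sector = None
        self.beta = np.zeros(self.p)
        self.b = np.zeros(self.S)
        self.c = np.zeros(self.C)

    # -- penalized objective pieces -----------------------------------------

    def _eta(self, beta, b, c):
        eta = self.X @ beta + b[self.sector]
        if self.has_child:
            eta = eta + c[self.child]
        return eta

    @staticmethod
    def _nll(y, eta):
        # -log-likelihood, numerically stable via logaddexp
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    def _f(self, beta, b, c, s2v, s2c):
        val = self._nll(self.y, self._eta(beta, b, c)) + 0.5 * b @ b / s2v
        if self.has_child:
            val += 0.5 * c @ c / s2c
        return val

    def _arrow_solve(self, Dbb, Dcc, a, rb, rc):
        """Solve the arrow system [[diag(Dbb), coupling], [coupling', diag(Dcc)]]."""
        if not self.has_child:
            return rb / Dbb, None
        q = a / Dcc
        denom = Dbb - np.bincount(self.child_sector, a * q, minlength=self.S)
        zb = (rb - np.bincount(self.child_sector, q * rc, minlength=self.S)) / denom
        zc = (rc - a * zb[self.child_sector]) / Dcc
        return zb, zc

    def _pirls(self, s2v, s2c, tol=1e-9, maxiter=100):
        """Joint Newton over (beta, b, c) of the penalized deviance."""
        beta, b, c = self.beta.copy(), self.b.copy(), self.c.copy()
        f = self._f(beta, b, c, s2v, s2c)
        converged = False
        for _ in range(maxiter):
            eta = self._eta(beta, b, c)
            mu = expit(eta)
            r = self.y - mu
            w = np.clip(mu * (1.0 - mu), 1e-12, None)

            gb = self.X.T @ r
            gvb = np.bincount(self.sector, r, minlength=self.S) - b / s2v
            gvc = (
                np.bincount(self.child, r, minlength=self.C) - c / s2c
                if self.has_child
                else None
            )

            A = (self.X * w[:, None]).T @ self.X
            Bb = np.stack(
                [np.bincount(self.sector, w * self.X[:, k], minlength=self.S) for k in range(self.p)]
            )  # p x S
            Dbb = np.bincount(self.sector, w, minlength=self.S) + 1.0 / s2v
            if self.has_child:
                a = np.bincount(self.child, w, minlength=self.C)
                Dcc = a + 1.0 / s2c
                Bc = np.stack(
                    [np.bincount(self.child, w * self.X[:, k], minlength=self.C) for k in range(self.p)]
                )  # p x C
            else:
                a = Dcc = Bc = None

            # D^{-1} applied to B' (p right-hand sides) and to the u-gradient
            DiBb = np.empty((self.p, self.S))
            DiBc = np.empty((self.p, self.C)) if self.has_child else None
            for k in range(self.p):
                zb, zc = self._arrow_solve(
                    Dbb, Dcc, a, Bb[k], Bc[k] if self.has_child else None
                )
                DiBb[k] = zb
                if self.has_child:
                    DiBc[k] = zc
            zgb, zgc = self._arrow_solve(Dbb, Dcc, a, gvb, gvc)

            M = A - DiBb @ Bb.T
            rhs = gb - Bb @ zgb
            if self.has_child:
                M = M - DiBc @ Bc.T
                rhs = rhs - Bc @ zgc
            try:
                d_beta = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                d_beta = np.linalg.lstsq(M, rhs, rcond=None)[0]
            resb = gvb - Bb.T @ d_beta
            resc = gvc - Bc.T @ d_beta if self.has_child else None
            d_b, d_c = self._arrow_solve(Dbb, Dcc, a, resb, resc)

            step = 1.0
            for _ in range(30):
                nb = beta + step * d_beta
                bb = b + step * d_b
                cc = c + step * d_c if self.has_child else c
                fn = self._f(nb, bb, cc, s2v, s2c)
                if fn <= f + 1e-12:
                    break
                step *= 0.5
            else:
                converged = True  # no descent possible: at a (numerical) optimum
                break
            improvement = f - fn
            beta, b, c, f = nb, bb, cc, fn
            if improvement < tol * (abs(f) + 1.0):
                converged = True
                break
        self.beta, self.b, self.c = beta, b, c
        self._last = dict(M=M, Dbb=Dbb, Dcc=Dcc, a=a, f=f, w=w)
        return beta, b, c, f, converged

    def deviance(self, s2v, s2c):
        """-2 x Laplace log-likelihood at the penalized mode (beta profiled)."""
        beta, b, c, f, conv = self._pirls(s2v, s2c)
        eta = self._eta(beta, b, c)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        Dbb = np.bincount(self.sector, w, minlength=self.S) + 1.0 / s2v
        if self.has_child:
            a = np.bincount(self.child, w, minlength=self.C)
            Dcc = a + 1.0 / s2c
            q = a / Dcc
            denom = Dbb - np.bincount(self.child_sector, a * q, minlength=self.S)
            logdet = float(np.sum(np.log(s2c * Dcc))) + float(
                np.sum(np.log(s2v * denom))
            )
        else:
            logdet = float(np.sum(np.log(s2v * Dbb)))
        return 2.0 * f + logdet, conv

    def fit(self, start_logvar=None, outer_tol=1e-6, maxiter=200):
        if start_logvar is None:
            start_logvar = (
                [np.log(0.05), np.log(0.1)] if self.has_child else [np.log(0.05)]
            )
        self._inner_converged = True

        def objective(logvar):
            s2v = float(np.exp(np.clip(logvar[0], -16.0, 6.0)))
            s2c = (
                float(np.exp(np.clip(logvar[1], -16.0, 6.0)))
                if self.has_child
                else 1.0
            )
            dev, conv = self.deviance(s2v, s2c)
            if not conv:
                self._inner_converged = False
            return dev

        res = optimize.minimize(
            objective,
            np.asarray(start_logvar, dtype=float),
            method="Nelder-Mead",
            options=dict(
                xatol=1e-3, fatol=outer_tol * 10, maxiter=maxiter, maxfev=maxiter * 2
            ),
        )
        logvar = np.clip(res.x, -16.0, 6.0)
        s2v = float(np.exp(logvar[0]))
        s2c = float(np.exp(logvar[1])) if self.has_child else 0.0
        self._inner_converged = True
        dev, inner_conv = self.deviance(s2v, s2c if self.has_child else 1.0)
        cov_beta = np.linalg.inv(self._last["M"])
        separation = bool(np.max(np.abs(self._eta(self.beta, self.b, self.c))) > 30)
        return dict(
            beta=self.beta.copy(),
            b=self.b.copy(),
            c=self.c.copy() if self.has_child else None,
            s2v=s2v,
            s2c=s2c,
            deviance=dev,
            loglik=-0.5 * dev,
            cov_beta=cov_beta,
            converged=bool(res.success or res.status == 1) and inner_conv,
            separation=separation,
            n_outer=int(res.nfev),
        )

    def cluster_scores(self, cluster_idx: np.ndarray) -> np.ndarray:
        """Per-cluster score contributions d loglik / d beta (envelope form)."""
        eta = self._eta(self.beta, self.b, self.c)
        r = self.y - expit(eta)
        n_cl = int(cluster_idx.max()) + 1
        scores = np.zeros((n_cl, self.p))
        for k in range(self.p):
            scores[:, k] = np.bincount(cluster_idx, r * self.X[:, k], minlength=n_cl)
        return scores


def _agq_loglik(
    y: np.ndarray,
    X: np.ndarray,
    sector_idx: np.ndarray,
    beta: np.ndarray,
    s2v: float,
    n_nodes: int = 15,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood for the single-level model.

    Accuracy-audit path: centers the quadrature at each sector's posterior
    mode with curvature-based scaling.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    sigma = np.sqrt(s2v)
    xb = X @ beta
    S = int(sector_idx.max()) + 1
    total = 0.0
    for i in range(S):
        m = sector_idx == i
        yi, xbi = y[m], xb[m]

        def neg(u):
            eta = xbi + u
            return np.sum(np.logaddexp(0, eta) - yi * eta) + 0.5 * u * u / s2v

        res = optimize.minimize_scalar(neg, bounds=(-10, 10), method="bounded")
        mode = res.x
        mu = expit(xbi + mode)
        curv = np.sum(mu * (1 - mu)) + 1.0 / s2v
        scale = 1.0 / np.sqrt(curv)
        u_k = mode + np.sqrt(2.0) * scale * nodes
        ll_k = np.array(
            [-np.sum(np.logaddexp(0, xbi + u) - yi * (xbi + u)) for u in u_k]
        )
        log_phi = -0.5 * u_k**2 / s2v - 0.5 * np.log(2 * np.pi * s2v)
        log_terms = np.log(weights) + nodes**2 + ll_k + log_phi
        m_max = log_terms.max()
        total += (
            np.log(np.sum(np.exp(log_terms - m_max)))
            + m_max
            + np.log(np.sqrt(2.0) * scale)
        )
    return float(total)


def fit_agq_single_level(
    panel: pd.DataFrame, v: int = 0, n_nodes: int = 15
) -> dict:
    """Fit the sector-only model by adaptive quadrature (audit path).

    Intended for small panels; optimizes (beta, log sigma2_village) by
    Nelder-Mead over the AGQ log-likelihood.
    """
    y, X, sector_idx, _, names = _build_design(panel, v, include_child=False)
    engine = _NestedLaplaceEngine(y, X, sector_idx, None)
    lap = engine.fit()
    x0 = np.concatenate([lap["beta"], [np.log(max(lap["s2v"], 1e-4))]])

    def neg(parvec):
        return -_agq_loglik(
            y, X, sector_idx, parvec[:-1], float(np.exp(parvec[-1])), n_nodes
        )

    res = optimize.minimize(
        neg, x0, method="Nelder-Mead", options=dict(xatol=1e-5, fatol=1e-7, maxiter=4000, maxfev=8000)
    )
    beta = res.x[:-1]
    return dict(
        params=pd.Series(beta, index=names),
        theta_hat=float(beta[names.index("x")]),
        s2v=float(np.exp(res.x[-1])),
        loglik=-float(res.fun),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# statsmodels-style model / results objects


def _build_design(panel: pd.DataFrame, v: int, include_child: bool):
    required = {"child_id", "sector_id", "group_id", "period", "x", "y"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    if len(panel) == 0:
        raise ValueError("empty panel")
    y = panel["y"].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary")
    t = panel["period"].to_numpy(dtype=float)
    basis = natural_spline_basis(t, v) if v else np.empty((len(panel), 0))
    X = np.column_stack(
        [np.ones(len(panel)), panel["x"].to_numpy(dtype=float), basis]
    )
    names = ["const", "x"] + [f"s{k}" for k in range(1, basis.shape[1] + 1)]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            "reduce v or check the panel"
        )
    sector_codes, _ = pd.factorize(panel["sector_id"], sort=True)
    child_codes, _ = pd.factorize(panel["child_id"], sort=True)
    return y, X, sector_codes, (child_codes if include_child else None), names


class SteppedWedgeLogit:
    """Logistic random-intercept model for the stepped-wedge ALRI panel.

    Parameters
    ----------
    panel
        Child-period table with columns ``child_id``, ``sector_id``,
        ``group_id``, ``period``, ``x`` (exposure indicator), ``y`` (binary
        ALRI outcome).
    spec
        A :class:`ModelSpec`, or pass its fields as keyword arguments.

    Examples
    --------
    >>> model = SteppedWedgeLogit.from_dataframe(panel, v=8)
    >>> result = model.fit()
    >>> print(result.summary())        # doctest: +SKIP
    """

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec | None = None, **kwargs):
        self.spec = spec if spec is not None else ModelSpec(**kwargs)
        self.panel = panel.reset_index(drop=True)
        required = {"child_id", "sector_id", "group_id", "period", "x", "y"}
        missing = required - set(self.panel.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.panel["x"].nunique() < 2:
            raise ValueError(
                "exposure indicator x is constant; theta is not identified"
            )
        (
            self._y,
            self._X,
            self._sector,
            self._child,
            self.exog_names,
        ) = _build_design(self.panel, self.spec.v, self.spec.include_child_effect)

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, **kwargs) -> "SteppedWedgeLogit":
        return cls(panel, **kwargs)

    def fit(
        self, start_logvar=None, outer_tol: float = 1e-6, maxiter: int = 200
    ) -> "SteppedWedgeLogitResults":
        engine = _NestedLaplaceEngine(self._y, self._X, self._sector, self._child)
        raw = engine.fit(start_logvar=start_logvar, outer_tol=outer_tol, maxiter=maxiter)
        if not raw["converged"]:
            warnings.warn("Laplace fit did not converge; estimates are flagged")
        if raw["separation"]:
            warnings.warn("possible separation: extreme fitted log-odds")
        res = SteppedWedgeLogitResults(self, engine, raw)
        return res


@dataclass
class SteppedWedgeLogitResults:
    """Fitted stepped-wedge logistic mixed model.

    Carries the fixed-effect estimates, the variance components, model-based
    and cluster-robust standard errors for the intervention effect theta, and
    the Wald test against theta = 0.
    """

    model: SteppedWedgeLogit
    _engine: _NestedLaplaceEngine
    _raw: dict

    def __post_init__(self):
        names = self.model.exog_names
        self.params = pd.Series(self._raw["beta"], index=names)
        self.cov_params = pd.DataFrame(
            self._raw["cov_beta"], index=names, columns=names
        )
        self.bse = pd.Series(np.sqrt(np.diag(self._raw["cov_beta"])), index=names)
        self.alpha0_hat = float(self.params["const"])
        self.theta_hat = float(self.params["x"])
        self.se_model = float(self.bse["x"])
        self.var_village_hat = float(self._raw["s2v"])
        self.var_child_hat = float(self._raw["s2c"])
        self.loglik = float(self._raw["loglik"])
        self.converged = bool(self._raw["converged"])
        self.n_obs = int(len(self.model.panel))
        self.spline_coefs = self.params.drop(["const", "x"])
        self.se_robust: float | None = None
        self.robust_ratio: float | None = None
        self.use_robust: bool | None = None
        try:
            robust_variance(self)
        except ValueError:
            pass  # e.g. single cluster; explicit robust_variance() still raises

    # -- inference -----------------------------------------------------------

    @property
    def wald_z(self) -> float:
        return self.theta_hat / self.se_model

    @property
    def p_value(self) -> float:
        return float(2 * stats.norm.sf(abs(self.wald_z)))

    def conf_int(self, robust: bool = False) -> tuple[float, float]:
        se = self.se_robust if robust else self.se_model
        zc = stats.norm.ppf(1 - self.model.spec.alpha / 2)
        return self.theta_hat - zc * se, self.theta_hat + zc * se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Stepped-wedge logistic mixed model (Laplace ML)",
            "=" * 56,
            f"Observations: {self.n_obs}   Converged: {self.converged}",
            f"Spline df (v): {self.model.spec.v}   "
            f"Cluster level: {self.model.spec.cluster_level}",
            f"log-likelihood: {self.loglik:.2f}",
            "-" * 56,
            f"theta (stove effect): {self.theta_hat:+.4f}",
            f"  SE (model-based):   {self.se_model:.4f}",
            (
                f"  SE (robust):        {self.se_robust:.4f}"
                f"   ratio {self.robust_ratio:.2f}"
                f"   -> use {'robust' if self.use_robust else 'model-based'}"
                if self.se_robust is not None
                else "  SE (robust):        unavailable"
            ),
            f"  Wald z: {self.wald_z:+.2f}   p = {self.p_value:.4g}",
            f"  {100 * (1 - self.model.spec.alpha):.0f}% CI: ({lo:+.4f}, {hi:+.4f})",
            f"  odds ratio: {np.exp(self.theta_hat):.3f}",
            "-" * 56,
            f"alpha0 (baseline log-odds): {self.alpha0_hat:+.4f}",
            f"sigma2 village: {self.var_village_hat:.4f}   "
            f"sigma2 child: {self.var_child_hat:.4f}",
        ]
        return "\n".join(lines)

    def plot_time_trend(self, ax=None):
        """Plot the fitted spline time function s(t, v) on the log-odds scale."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.unique(self.model.panel["period"])
        if self.model.spec.v:
            basis = natural_spline_basis(
                self.model.panel["period"].to_numpy(dtype=float), self.model.spec.v
            )
            fitted = basis @ self.spline_coefs.to_numpy()
            order = np.argsort(self.model.panel["period"].to_numpy())
            tt = self.model.panel["period"].to_numpy()[order]
            _, first = np.unique(tt, return_index=True)
            ax.plot(tt[first], fitted[order][first], marker="o")
        else:
            ax.axhline(0.0)
        ax.set_xlabel("period (month)")
        ax.set_ylabel("s(t, v) [log-odds]")
        ax.set_title(f"Fitted time trend, v={self.model.spec.v}")
        return ax


def robust_variance(
    results: SteppedWedgeLogitResults,
    cluster_level: Literal["sector", "group"] | None = None,
    ratio_threshold: float = 1.2,
) -> SteppedWedgeLogitResults:
    """Cluster-aggregated sandwich SE for theta; updates the results in place.

    Scores are aggregated at ``cluster_level`` (defaults to the model spec's
    level) and combined with the model-based bread with a G/(G-1)
    small-sample factor.  The recorded decision rule: robust SEs are used
    for inference whenever they exceed the model-based SE by more than
    ``ratio_threshold``-fold.
    """
    level = cluster_level or results.model.spec.cluster_level
    col = "sector_id" if level == "sector" else "group_id"
    codes, uniques = pd.factorize(results.model.panel[col], sort=True)
    G = len(uniques)
    if G < 2:
        raise ValueError("sandwich variance undefined with a single cluster")
    if G < 10:
        warnings.warn(f"only {G} clusters at level '{level}'; robust SEs unstable")
    scores = results._engine.cluster_scores(codes)
    bread = results.cov_params.to_numpy()
    meat = scores.T @ scores
    V = bread @ meat @ bread * (G / (G - 1))
    idx = results.model.exog_names.index("x")
    results.se_robust = float(np.sqrt(V[idx, idx]))
    results.robust_ratio = results.se_robust / results.se_model
    results.use_robust = bool(results.robust_ratio > ratio_threshold)
    return results


def sensitivity_over_v(
    panel: pd.DataFrame, v_list: Sequence[int] = tuple(range(4, 13)), **model_kwargs
) -> pd.DataFrame:
    """Refit the model over a range of spline df and tabulate theta.

    One row per requested ``v`` with the estimate, both SEs, and the CI;
    values of ``v`` whose basis would be rank-deficient on this panel are
    reported with NaNs and a warning.
    """
    rows = []
    for v in v_list:
        row = {"v": v}
        try:
            fit = SteppedWedgeLogit(panel, v=v, **model_kwargs).fit()
            lo, hi = fit.conf_int()
            row.update(
                theta_hat=fit.theta_hat,
                se_model=fit.se_model,
                se_robust=fit.se_robust,
                ci_low=lo,
                ci_high=hi,
                converged=fit.converged,
            )
        except ValueError as exc:
            warnings.warn(f"v={v} skipped: {exc}")
            row.update(
                theta_hat=np.nan,
                se_model=np.nan,
                se_robust=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                converged=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Birthweight models


@dataclass
class BirthweightResults:
    """Treatment effect on birthweight (continuous g, or low-birthweight odds)."""

    outcome: str
    effect: float
    se_model: float
    se_robust: float
    var_cluster: float
    icc: float | None
    n_obs: int
    n_clusters: int

    def summary(self) -> str:
        unit = "g" if self.outcome == "continuous" else "log-odds(LBW)"
        return (
            f"Birthweight ({self.outcome}): effect {self.effect:+.2f} {unit}, "
            f"SE model {self.se_model:.2f} / robust {self.se_robust:.2f}, "
            f"ICC {self.icc if self.icc is None else round(self.icc, 5)}, "
            f"n={self.n_obs} in {self.n_clusters} clusters"
        )


def fit_birthweight(
    data: pd.DataFrame, outcome: Literal["continuous", "lbw"] = "continuous"
) -> BirthweightResults:
    """Cluster-adjusted treatment effect on birthweight.

    ``data`` needs columns ``cluster_id``, ``arm`` ("control"/"intervention"),
    ``weight_g``.  Continuous: linear mixed model (ML) with cluster random
    intercepts; robust SE from an exchangeable GEE.  LBW: logistic random-
    intercept model on the strict <2500 g indicator via the package's
    Laplace engine, with the cluster sandwich SE.
    """
    required = {"cluster_id", "arm", "weight_g"}
    if not required <= set(data.columns):
        raise ValueError(f"data missing columns: {sorted(required - set(data.columns))}")
    arm = (data["arm"] == "intervention").astype(float).to_numpy()
    per_arm = data.groupby("arm")["cluster_id"].nunique()
    if len(per_arm) < 2 or (per_arm < 2).any():
        raise ValueError("need at least 2 clusters per arm")
    clusters = data["cluster_id"].to_numpy()
    n_clusters = data["cluster_id"].nunique()
    exog = sm.add_constant(pd.DataFrame({"arm": arm}))
    if outcome == "continuous":
        w = data["weight_g"].astype(float)
        mixed = sm.MixedLM(w, exog, groups=clusters).fit(reml=False)
        gee = sm.GEE(
            w,
            exog,
            groups=clusters,
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        var_cluster = float(mixed.cov_re.iloc[0, 0])
        resid_var = float(mixed.scale)
        icc = var_cluster / (var_cluster + resid_var)
        return BirthweightResults(
            outcome="continuous",
            effect=float(mixed.params["arm"]),
            se_model=float(mixed.bse["arm"]),
            se_robust=float(gee.bse["arm"]),
            var_cluster=var_cluster,
            icc=icc,
            n_obs=len(data),
            n_clusters=n_clusters,
        )
    if outcome != "lbw":
        raise ValueError("outcome must be 'continuous' or 'lbw'")
    lbw = (data["weight_g"] < 2500.0).astype(float).to_numpy()  # strict cut
    X = np.column_stack([np.ones(len(data)), arm])
    codes, _ = pd.factorize(data["cluster_id"], sort=True)
    engine = _NestedLaplaceEngine(lbw, X, codes, None)
    raw = engine.fit()
    se_model = float(np.sqrt(raw["cov_beta"][1, 1]))
    scores = engine.cluster_scores(codes)
    G = int(codes.max()) + 1
    V = raw["cov_beta"] @ (scores.T @ scores) @ raw["cov_beta"] * (G / (G - 1))
    s2 = raw["s2v"]
    return BirthweightResults(
        outcome="lbw",
        effect=float(raw["beta"][1]),
        se_model=se_model,
        se_robust=float(np.sqrt(V[1, 1])),
        var_cluster=s2,
        icc=s2 / (s2 + np.pi**2 / 3),  # latent-scale ICC
        n_obs=len(data),
        n_clusters=n_clusters,
    )


def anova_icc(values: Sequence[float], clusters: Sequence) -> float:
    """One-way ANOVA method-of-moments intra-cluster correlation estimate."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(clusters)})
    groups = df.groupby("g")["y"]
    k = groups.ngroups
    n_i = groups.size().to_numpy(dtype=float)
    n = n_i.sum()
    grand = df["y"].mean()
    ssb = float((n_i * (groups.mean().to_numpy() - grand) ** 2).sum())
    ssw = float(((df["y"] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - (n_i**2).sum() / n) / (k - 1)
    return float((msb - msw) / (msb + (n0 - 1) * msw))
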