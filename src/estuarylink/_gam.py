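"""Penalized additive model engine shared by the load and estuary models.

Fitting is delegated to :class:`statsmodels.gam.generalized_additive_model.GLMGam`
(penalized IRLS).  This module supplies the pieces the pipeline needs on top
of it:

* low-rank penalized B-spline smoothers with a selectable derivative-penalty
  order (first-order penalties shrink flow smooths toward a flat function,
  constraining extrapolation at high flows), plus cyclic cubic smoothers for
  day-of-year terms;
* automatic smoothness selection by minimizing a GCV score or a
  Laplace-approximate REML score over the per-term penalty weights;
* the Bayesian coefficient covariance ``Vb = phi * (X'WX + S)^-1`` used for
  posterior simulation of derived quantities.

Smooth terms are centered (sum-to-zero over the training data), so the model
intercept carries the overall level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from statsmodels.gam.api import GLMGam
from statsmodels.gam.smooth_basis import (
    GenericSmoothers,
    UnivariateBSplines,
    UnivariateCubicCyclicSplines,
    _eval_bspline_basis,
)

from .errors import FitError, ValidationError

__all__ = ["SmoothTerm", "ModelSpec", "FittedAdditiveModel", "fit_gam"]


class _PSpline(UnivariateBSplines):
    """B-spline smoother with a derivative penalty of order 1 or 2."""

    def __init__(self, x, df, degree=3, penalty_order=2, **kwargs):
        self.penalty_order = penalty_order
        super().__init__(x, df=df, degree=degree, **kwargs)

    def _smooth_basis_for_single_variable(self):
        basis, der_basis, der2_basis = _eval_bspline_basis(
            self.x, self.knots, self.degree, include_intercept=self.include_intercept
        )
        db = der_basis if self.penalty_order == 1 else der2_basis
        cov = db.T @ db / len(self.x)
        return basis, der_basis, der2_basis, cov


@dataclass
class SmoothTerm:
    """One smooth term of an additive model.

    ``basis`` is ``"thin_plate"`` for an ordinary one-dimensional penalized
    regression spline or ``"cyclic_cubic"`` for a periodic (day-of-year)
    spline whose ends match.  ``penalty_order`` 1 penalizes departures from a
    flat function, 2 penalizes curvature.
    """

    name: str
    basis: str = "thin_plate"
    basis_dim: int = 10
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.basis not in ("thin_plate", "cyclic_cubic"):
            raise ValidationError(f"unknown basis {self.basis!r}")
        if self.basis_dim < 4:
            raise ValidationError("basis_dim must be >= 4")
        if self.penalty_order not in (1, 2):
            raise ValidationError("penalty_order must be 1 or 2")


_FAMILIES = {
    "gaussian_log_link": lambda: sm.families.Gaussian(sm.families.links.Log()),
    "gamma_log_link": lambda: sm.families.Gamma(sm.families.links.Log()),
    "gaussian_identity": lambda: sm.families.Gaussian(),
}


@dataclass
class ModelSpec:
    """Family, smooth terms and smoothness-selection method of a model."""

    response_family: str = "gaussian_log_link"
    terms: list = field(default_factory=list)
    smoothness_selection: str = "REML"
    fixed_alpha: list | None = None

    def __post_init__(self) -> None:
        if self.response_family not in _FAMILIES:
            raise ValidationError(f"unknown response family {self.response_family!r}")
        if self.smoothness_selection not in ("REML", "GCV"):
            raise ValidationError("smoothness_selection must be 'REML' or 'GCV'")
        self.terms = [t if isinstance(t, SmoothTerm) else SmoothTerm(**t) for t in self.terms]


@dataclass
class FittedAdditiveModel:
    """A fitted penalized additive model with everything needed downstream.

    ``coefficients`` includes the intercept (first entry);
    ``coefficient_covariance`` is the Bayesian posterior covariance
    ``phi * (X'WX + S)^-1`` evaluated at convergence, the input to posterior
    simulation of derived quantities.
    """

    basis_spec: ModelSpec
    coefficients: np.ndarray
    coefficient_covariance: np.ndarray
    smoothing_parameters: np.ndarray
    scale: float
    n_obs: int
    effective_dof: float
    edof_per_term: dict
    loglik: float
    _smoother: GenericSmoothers
    _term_slices: dict
    _domain: dict

    @property
    def term_names(self) -> list:
        return [t.name for t in self.basis_spec.terms]

    def _clip_columns(self, table: pd.DataFrame) -> list:
        cols = []
        for term in self.basis_spec.terms:
            if term.name not in table.columns:
                raise ValidationError(f"covariate {term.name!r} missing from prediction table")
            x = table[term.name].to_numpy(dtype=float)
            if term.basis != "cyclic_cubic":
                lo, hi = self._domain[term.name]
                x = np.clip(x, lo, hi)
            cols.append(x)
        return cols

    def design_matrix(self, table: pd.DataFrame) -> np.ndarray:
        """Full design matrix [1 | basis columns] for new covariate rows.

        Non-cyclic covariates are clipped to the training domain, i.e.
        predictions are held flat beyond the range the spline basis covers.
        """
        cols = self._clip_columns(table)
        blocks = [np.ones((len(table), 1))]
        for x, s in zip(cols, self._smoother.smoothers):
            blocks.append(np.asarray(s.transform(x)))
        return np.hstack(blocks)

    def predict_linear(self, table: pd.DataFrame) -> np.ndarray:
        return self.design_matrix(table) @ self.coefficients

    def predict_response(self, table: pd.DataFrame) -> np.ndarray:
        eta = self.predict_linear(table)
        if self.basis_spec.response_family == "gaussian_identity":
            return eta
        return np.exp(eta)

    def partial_linear(self, table: pd.DataFrame, names) -> np.ndarray:
        """Sum of the named smooth contributions to the linear predictor."""
        cols = dict(zip(self.term_names, self._clip_columns(table)))
        out = np.zeros(len(table))
        for name in names:
            s = self._smoother.smoothers[self.term_names.index(name)]
            out += np.asarray(s.transform(cols[name])) @ self.coefficients[self._term_slices[name]]
        return out

    def partial_effect(self, name: str, values: np.ndarray) -> np.ndarray:
        """Centered smooth contribution of one term on a grid of values."""
        frame = pd.DataFrame({name: np.asarray(values, dtype=float)})
        for t in self.basis_spec.terms:
            if t.name != name:
                frame[t.name] = self._domain[t.name][0]
        return self.partial_linear(frame, [name])

    def posterior_coefficient_draws(
        self, n_draws: int, seed: int | None = None, allow_repair: bool = False
    ) -> np.ndarray:
        """Draws from the MVN coefficient posterior, shape (n_draws, p)."""
        cov = np.asarray(self.coefficient_covariance, dtype=float)
        cov = 0.5 * (cov + cov.T)
        w, v = np.linalg.eigh(cov)
        tol = 1e-10 * max(w.max(), 1e-300)
        if w.min() < -tol:
            if not allow_repair:
                raise ValidationError(
                    "coefficient covariance is not positive semidefinite; "
                    "pass allow_repair=True to clip negative eigenvalues"
                )
            w = np.clip(w, 0.0, None)
        w = np.clip(w, 0.0, None)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_draws, len(w)))
        return self.coefficients + z @ (v * np.sqrt(w)).T


def _working_weights(mu: np.ndarray, family: str) -> np.ndarray:
    if family == "gaussian_log_link":
        return mu**2  # (dmu/deta)^2 / V(mu) with V = 1
    if family == "gamma_log_link":
        return np.ones_like(mu)  # mu^2 / mu^2
    return np.ones_like(mu)  # identity Gaussian


def _penalty_blockdiag(pen_mats, alphas, p_total, offset=1):
    S = np.zeros((p_total, p_total))
    off = offset
    for a, P in zip(alphas, pen_mats):
        k = P.shape[0]
        S[off : off + k, off : off + k] = a * P
        off += k
    return S


def fit_gam(
    y: np.ndarray,
    table: pd.DataFrame,
    spec: ModelSpec,
    domain: dict | None = None,
    optimizer_maxfev: int | None = None,
) -> FittedAdditiveModel:
    """Fit a penalized additive model with automatic smoothness selection.

    Parameters
    ----------
    y : array
        Response observations.
    table : DataFrame
        One row per observation; must contain a column for each smooth term.
    spec : ModelSpec
        Family, terms, and selection method.
    domain : dict, optional
        ``name -> (lower, upper)`` bounds for the spline knots of non-cyclic
        terms.  By default each term's knots span the training values and
        predictions are clipped to that range (held flat beyond it): with
        sparse ambient sampling the data carry no information about the
        response shape at unsampled covariate extremes, and an unconstrained
        spline tail would dominate both point predictions and posterior
        draws once exponentiated.
    optimizer_maxfev : int, optional
        Cap on criterion evaluations during smoothness selection.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(table) != n:
        raise ValidationError("response and covariate table lengths differ")
    if spec.response_family == "gamma_log_link" and np.any(y <= 0):
        bad = np.nonzero(y <= 0)[0][:10].tolist()
        raise ValidationError(f"Gamma response requires positive values; offending rows {bad}")

    domain = dict(domain or {})
    smoothers = []
    xcols = []
    for term in spec.terms:
        if term.name not in table.columns:
            raise ValidationError(f"covariate {term.name!r} missing from design table")
        x = table[term.name].to_numpy(dtype=float)
        if np.ptp(x) <= 0:
            raise ValidationError(f"covariate {term.name!r} is constant; drop the term")
        xcols.append(x)
        if term.basis == "cyclic_cubic":
            smoothers.append(
                UnivariateCubicCyclicSplines(
                    x, df=term.basis_dim, constraints="center", variable_name=term.name
                )
            )
            domain[term.name] = (float(x.min()), float(x.max()))
        else:
            lo, hi = domain.get(term.name, (float(x.min()), float(x.max())))
            lo = min(lo, float(x.min()))
            hi = max(hi, float(x.max()))
            pad = 1e-9 * max(hi - lo, 1.0)
            domain[term.name] = (lo, hi)
            smoothers.append(
                _PSpline(
                    x,
                    df=term.basis_dim,
                    degree=3,
                    penalty_order=term.penalty_order,
                    constraints="center",
                    variable_name=term.name,
                    lower_bound=lo - pad,
                    upper_bound=hi + pad,
                )
            )

    # normalize each penalty so one smoothing parameter scale fits all terms
    pen_consts = []
    for s in smoothers:
        nrm = np.linalg.norm(s.cov_der2)
        if nrm <= 0:
            raise FitError(f"degenerate penalty for term {s.variable_name!r}")
        s.cov_der2 = s.cov_der2 / nrm
        eig = np.linalg.eigvalsh(s.cov_der2)
        pos = eig[eig > 1e-10 * eig.max()]
        pen_consts.append((len(pos), float(np.sum(np.log(pos)))))

    smoother = GenericSmoothers(np.column_stack(xcols), smoothers)
    p_total = smoother.dim_basis + 1
    if n <= p_total:
        raise FitError(
            f"{n} observations cannot support a basis of total dimension {p_total}; "
            "lower basis_dim on one or more terms"
        )

    family = _FAMILIES[spec.response_family]()
    exog = np.ones((n, 1))
    k_terms = len(spec.terms)

    def _fit(alphas):
        gam = GLMGam(y, exog, smoother=smoother, alpha=list(alphas), family=family)
        return gam.fit(maxiter=100)

    X_full = np.column_stack([exog, smoother.basis])

    def _quantities(res, alphas):
        mu = np.asarray(res.fittedvalues)
        w = _working_weights(mu, spec.response_family)
        XtWX = X_full.T @ (X_full * w[:, None])
        S = _penalty_blockdiag(smoother.penalty_matrices, alphas, p_total)
        F = np.linalg.solve(XtWX + S, XtWX)
        return mu, XtWX, S, F

    rank_S = sum(r for r, _ in pen_consts)
    m_p = p_total - rank_S  # dimension of the unpenalized null space

    def _criterion(res, alphas):
        mu, XtWX, S, F = _quantities(res, alphas)
        dev = float(res.deviance)
        if spec.smoothness_selection == "GCV":
            edof = float(np.trace(F))
            denom = max(n - edof, 1e-8)
            return n * max(dev, 1e-300) / denom**2
        # Laplace-approximate REML with the scale profiled out:
        # (n - Mp) log(Dp) + log|X'WX + S| - log|S|_+  (constants dropped)
        beta = np.asarray(res.params)
        d_p = dev + float(beta @ S @ beta)
        sign, logdet = np.linalg.slogdet(XtWX + S)
        if sign <= 0:
            return np.inf
        logdet_S = sum(
            r * np.log(a) + c for a, (r, c) in zip(alphas, pen_consts)
        )
        return (n - m_p) * np.log(max(d_p, 1e-300)) + logdet - logdet_S

    if spec.fixed_alpha is not None:
        alphas = np.asarray(spec.fixed_alpha, dtype=float)
        if len(alphas) != k_terms:
            raise ValidationError("fixed_alpha length must match number of terms")
    else:
        def objective(rho):
            a = np.exp(np.clip(rho, -14.0, 22.0))
            try:
                return _criterion(_fit(a), a)
            except (np.linalg.LinAlgError, ValueError):
                return np.inf

        grid = np.arange(-4.0, 13.0, 2.0)
        scores = [objective(np.full(k_terms, g)) for g in grid]
        start = np.full(k_terms, grid[int(np.nanargmin(scores))])
        maxfev = optimizer_maxfev or 40 * k_terms
        opt = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 0.2, "fatol": 1e-9},
        )
        alphas = np.exp(np.clip(opt.x, -14.0, 22.0))

    try:
        res = _fit(alphas)
    except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
        raise FitError(f"penalized IRLS failed at selected penalties: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("fit did not converge to finite coefficients")

    mu, XtWX, S, F = _quantities(res, alphas)
    edof_diag = np.diag(F)
    scale = float(res.scale)
    Vb = scale * np.linalg.inv(XtWX + S)

    term_slices = {}
    edof_per_term = {}
    off = 1
    for term, s in zip(spec.terms, smoother.smoothers):
        sl = slice(off, off + s.dim_basis)
        term_slices[term.name] = sl
        edof_per_term[term.name] = float(edof_diag[sl].sum())
        off += s.dim_basis

    return FittedAdditiveModel(
        basis_spec=spec,
        coefficients=np.asarray(res.params),
        coefficient_covariance=Vb,
        smoothing_parameters=np.asarray(alphas),
        scale=scale,
        n_obs=n,
        effective_dof=float(edof_diag.sum()),
        edof_per_term=edof_per_term,
        loglik=float(res.llf),
        _smoother=smoother,
        _term_slices=term_slices,
        _domain=domain,
    )
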