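"""Closed-form genomic BLUP (GBLUP) and ridge-regression marker BLUP.

The statistical model is the standard whole-genome regression

    y = X beta + e,      beta ~ N(0, sigma2_beta * I),
                         e    ~ N(0, sigma2_e * D),

with ``X`` the (column-centered) n x p marker matrix and ``D`` a diagonal
matrix of reciprocal weights (all ones for single records per
individual).  With lam = sigma2_e / sigma2_beta the BLUP of the genomic
signal g = X beta has the equivalent dual (kernel) form

    ghat = G alpha,      (G + lam * D) alpha = y,     G = X X',

so only an n x n system needs solving even when p >> n.  The primal
(marker-effect) solution is beta_hat = (X'X + lam I)^(-1) X'y, obtainable
from the dual coefficients as beta_hat = X' alpha.

Two model classes expose this, statsmodels-style:

``GBLUP``
    dual form, built from a genomic relationship matrix (GRM);
``MarkerRidge``
    primal form, built from the marker matrix itself, with marker-level
    prediction-error covariance and reliabilities.

Both have a ``fit()`` returning a results object with estimates,
reliabilities, hat-matrix diagnostics and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .exceptions import AlignmentError, EstimabilityError, ParameterError, SolverError
from .markers import MarkerMatrix, as_marker_matrix

__all__ = [
    "VarianceComponents", "build_grm", "GBLUP", "GBLUPResults",
    "MarkerRidge", "MarkerRidgeResults", "ReliabilityReport",
    "fit_gblup", "predict_gblup", "ridge_marker_blup", "ols_effects",
    "prediction_error_covariance", "hat_matrix",
    "predictive_correlation_bound",
]


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------
@dataclass
class VarianceComponents:
    """Residual and marker-effect variances, their ratio, and weights.

    ``lam`` is the ridge/regularization parameter sigma2_e/sigma2_beta.
    Any one of (sigma2_e & sigma2_beta) or lam may be supplied; the
    ratio is resolved on construction.  ``weights`` is the diagonal of D
    (reciprocal weights), defaulting to ones.
    """

    sigma2_e: float | None = None
    sigma2_beta: float | None = None
    lam: float | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma2_e is not None and self.sigma2_e <= 0:
            raise ParameterError("sigma2_e must be positive")
        if self.sigma2_beta is not None and self.sigma2_beta <= 0:
            raise ParameterError("sigma2_beta must be positive")
        if self.sigma2_e is not None and self.sigma2_beta is not None:
            ratio = self.sigma2_e / self.sigma2_beta
            if self.lam is None:
                self.lam = ratio
            elif not np.isclose(self.lam, ratio):
                raise ParameterError(
                    f"lam={self.lam} inconsistent with sigma2_e/sigma2_beta={ratio}")
        if self.lam is None:
            raise ParameterError(
                "supply lam or both sigma2_e and sigma2_beta")
        if self.lam < 0:
            raise ParameterError("lam must be nonnegative")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ParameterError("weights must be strictly positive")

    def weight_vector(self, n: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(n)
        if self.weights.shape != (n,):
            raise AlignmentError(
                f"weights have length {self.weights.size}, expected {n}")
        return self.weights


def _as_vc(vc) -> VarianceComponents:
    if isinstance(vc, VarianceComponents):
        return vc
    return VarianceComponents(lam=float(vc))


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------
def build_grm(X, scheme: str = "cross_product") -> np.ndarray:
    """Genomic relationship matrix from marker genotypes.

    ``cross_product`` gives G = Xc Xc' with Xc column-centered, left
    unscaled so that lam = sigma2_e/sigma2_beta is exactly the ridge
    parameter of the equivalent marker regression.  ``correlation``
    rescales the cross-product to unit diagonal ("genomic correlation
    matrix"), used only for similarity diagnostics between QTL-based and
    marker-based relationships.
    """
    Xc = as_marker_matrix(X).center()
    G = Xc.values @ Xc.values.T
    if scheme == "cross_product":
        return G
    if scheme == "correlation":
        d = np.sqrt(np.diag(G))
        if np.any(d <= 0):
            bad = [Xc.ids[i] for i in np.flatnonzero(d <= 0)]
            raise ParameterError(
                f"zero-norm individuals, correlation undefined: {bad[:5]}")
        return G / np.outer(d, d)
    raise ParameterError(f"unknown GRM scheme {scheme!r}")


def _solve_system(G: np.ndarray, lam: float, w: np.ndarray, rhs: np.ndarray):
    """Solve (G + lam*diag(w)) x = rhs via Cholesky, with a clear error."""
    A = G + lam * np.diag(w)
    try:
        c, low = sla.cho_factor(A, lower=True, check_finite=False)
    except sla.LinAlgError:
        emin = float(sla.eigvalsh(A, subset_by_index=[0, 0])[0])
        raise SolverError(
            f"(G + lam*D) is not positive definite at lam={lam} "
            f"(minimum eigenvalue {emin:.3e}); increase lam") from None
    return sla.cho_solve((c, low), rhs, check_finite=False)


# ---------------------------------------------------------------------------
# GBLUP (dual / kernel form)
# ---------------------------------------------------------------------------
class GBLUP:
    """Genomic BLUP in its dual form, built from a relationship matrix.

    Parameters
    ----------
    endog : array_like, shape (n,)
        Phenotypes (mean-centered internally; the mean is recorded and
        restored on prediction).
    grm : array_like, shape (n, n)
        Genomic relationship matrix among training individuals.
    vc : VarianceComponents or float
        Variance components, or just the ratio lam.
    ids : sequence of str, optional
        Training individual labels.
    """

    def __init__(self, endog, grm, vc, ids=None):
        self.y = np.asarray(endog, dtype=float).ravel()
        self.G = np.asarray(grm, dtype=float)
        n = self.y.size
        if self.G.shape != (n, n):
            raise AlignmentError(
                f"GRM is {self.G.shape}, phenotypes have length {n}")
        self.vc = _as_vc(vc)
        self.ids = list(ids) if ids is not None else [
            f"id_{i + 1:04d}" for i in range(n)]
        self.nobs = n

    @classmethod
    def from_markers(cls, endog, X, vc, scheme: str = "cross_product"):
        """Build the model from a marker matrix (GRM = Xc Xc')."""
        Xm = as_marker_matrix(X)
        return cls(endog, build_grm(Xm, scheme), vc, ids=Xm.ids)

    def fit(self) -> "GBLUPResults":
        w = self.vc.weight_vector(self.nobs)
        y_mean = float(self.y.mean())
        yc = self.y - y_mean
        alpha = _solve_system(self.G, self.vc.lam, w, yc)
        ghat = self.G @ alpha
        return GBLUPResults(model=self, alpha=alpha, ghat=ghat,
                            y_mean=y_mean, weights=w)


@dataclass
class GBLUPResults:
    """Fitted GBLUP: dual coefficients, fitted signal and diagnostics."""

    model: GBLUP
    alpha: np.ndarray
    ghat: np.ndarray
    y_mean: float
    weights: np.ndarray
    _hat: np.ndarray | None = field(default=None, repr=False)

    @property
    def lam(self) -> float:
        return self.model.vc.lam

    @property
    def training_ids(self):
        return self.model.ids

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fitted phenotypes on the original scale (ghat + mean)."""
        return self.ghat + self.y_mean

    def predict(self, grm_cross) -> np.ndarray:
        """Predict genomic values for new individuals.

        ``grm_cross`` is the n_new x n_train matrix of relationships
        between candidates and the training set; predictions are
        grm_cross @ alpha plus the recorded training phenotype mean.
        """
        K = np.asarray(grm_cross, dtype=float)
        if K.ndim == 1:
            K = K[None, :]
        if K.shape[1] != self.model.nobs:
            raise AlignmentError(
                f"cross-relationship matrix has {K.shape[1]} columns, "
                f"training set has {self.model.nobs} individuals")
        return K @ self.alpha + self.y_mean

    def hat_matrix(self) -> np.ndarray:
        """H = G (G + lam D)^(-1); maps centered y to ghat."""
        if self._hat is None:
            G, w = self.model.G, self.weights
            self._hat = _solve_system(G, self.lam, w, G).T
        return self._hat

    @property
    def edf(self) -> float:
        """Effective number of parameters, trace of the hat matrix."""
        return float(np.trace(self.hat_matrix()))

    @property
    def reliabilities(self) -> np.ndarray:
        """Model-derived per-individual reliabilities, diag of H.

        These use marker information and variance components only — no
        phenotypic outcomes — so they measure information content of the
        training design, not realized predictive performance.
        """
        return np.diag(self.hat_matrix()).copy()

    def summary(self) -> str:
        r = np.corrcoef(self.fittedvalues, self.model.y)[0, 1]
        lines = [
            "GBLUP results",
            "=" * 46,
            f"n obs                 {self.model.nobs:>12d}",
            f"lambda (sig2e/sig2b)  {self.lam:>12.4g}",
            f"phenotype mean        {self.y_mean:>12.4g}",
            f"trace(H) (eff. par.)  {self.edf:>12.4g}",
            f"training correlation  {r:>12.4f}",
            f"mean reliability      {self.reliabilities.mean():>12.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# marker-level ridge (primal form)
# ---------------------------------------------------------------------------
class MarkerRidge:
    """Ridge-regression BLUP of marker effects (primal form).

    Solves beta_hat = (X'X + lam I)^(-1) X'y, switching to the dual
    identity beta_hat = X'(XX' + lam D)^(-1) y when p > n.  X is
    column-centered and y mean-centered internally; the training means
    are reused at prediction time.
    """

    def __init__(self, endog, X, vc):
        self.X = as_marker_matrix(X)
        self.y = np.asarray(endog, dtype=float).ravel()
        if self.y.size != self.X.n:
            raise AlignmentError(
                f"{self.y.size} phenotypes for {self.X.n} individuals")
        self.vc = _as_vc(vc)
        if self.vc.lam <= 0:
            raise ParameterError(
                "ridge requires lam > 0; use ols_effects for least squares")
        self.nobs = self.X.n

    def fit(self) -> "MarkerRidgeResults":
        Xc = self.X.center()
        w = self.vc.weight_vector(self.nobs)
        y_mean = float(self.y.mean())
        yc = self.y - y_mean
        n, p = Xc.shape
        V = Xc.values
        if p > n:
            alpha = _solve_system(V @ V.T, self.vc.lam, w, yc)
            beta = V.T @ alpha
        else:
            A = V.T @ (V / w[:, None]) + self.vc.lam * np.eye(p)
            try:
                c, low = sla.cho_factor(A, lower=True, check_finite=False)
            except sla.LinAlgError:  # pragma: no cover - lam>0 keeps A pd
                raise SolverError(f"ridge system singular at lam={self.vc.lam}")
            beta = sla.cho_solve((c, low), V.T @ (yc / w), check_finite=False)
        return MarkerRidgeResults(model=self, params=beta, y_mean=y_mean,
                                  Xc=Xc, weights=w)


@dataclass
class MarkerRidgeResults:
    """Fitted marker ridge: effect estimates and marker reliabilities."""

    model: MarkerRidge
    params: np.ndarray
    y_mean: float
    Xc: MarkerMatrix
    weights: np.ndarray

    @property
    def lam(self) -> float:
        return self.model.vc.lam

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.Xc.values @ self.params + self.y_mean

    def predict(self, X_new) -> np.ndarray:
        """Predict phenotypes for new individuals' genotypes."""
        Xn = as_marker_matrix(X_new).center_like(self.Xc)
        return Xn.values @ self.params + self.y_mean

    def reliability_report(self) -> "ReliabilityReport":
        return prediction_error_covariance(self.model.X, self.model.vc,
                                           level="marker")

    def summary(self) -> str:
        rep_mean = float(np.mean(self.reliability_report().reliabilities)) \
            if self.model.vc.sigma2_beta is not None else float("nan")
        r = np.corrcoef(self.fittedvalues, self.model.y)[0, 1]
        lines = [
            "Marker ridge (BLUP of marker effects)",
            "=" * 46,
            f"n obs / p markers     {self.model.nobs:>6d} /{self.Xc.p:>5d}",
            f"lambda                {self.lam:>12.4g}",
            f"training correlation  {r:>12.4f}",
            f"mean |beta_hat|       {np.abs(self.params).mean():>12.4g}",
            f"mean marker reliab.   {rep_mean:>12.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------
def fit_gblup(G, y, vc) -> GBLUPResults:
    """Solve (G + lam D) alpha = y_centered; return the fitted GBLUP."""
    return GBLUP(y, G, vc).fit()


def predict_gblup(fit: GBLUPResults, grm_cross) -> np.ndarray:
    return fit.predict(grm_cross)


def ridge_marker_blup(X, y, vc) -> np.ndarray:
    """Ridge-regression BLUP of the p marker effects."""
    return MarkerRidge(y, X, vc).fit().params


def ols_effects(X, y) -> np.ndarray:
    """Ordinary least-squares marker effects (X'X)^(-1) X'y.

    Requires n > p and a full-rank design; otherwise the effects are
    not estimable and an :class:`EstimabilityError` is raised.
    """
    Xc = as_marker_matrix(X).center()
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xc.shape
    if n <= p:
        raise EstimabilityError(
            f"OLS not estimable: n={n} <= p={p} (rank deficiency); "
            "use ridge_marker_blup")
    yc = y - y.mean()
    beta, _, rank, _ = sla.lstsq(Xc.values, yc)
    if rank < p:
        raise EstimabilityError(
            f"OLS not estimable: design rank {rank} < p={p}")
    return beta


@dataclass
class ReliabilityReport:
    """Prediction-error covariance and reliabilities, marker or signal level."""

    pev: np.ndarray
    reliabilities: np.ndarray
    scheme: str


def prediction_error_covariance(X, vc, level: str = "marker") -> ReliabilityReport:
    """Model-derived prediction-error covariance and reliabilities.

    marker level
        C = sigma2_beta * (I - X'(XX' + lam D)^(-1) X), the PEV matrix of
        the ridge BLUP of marker effects; reliability of effect j is
        r_j = 1 - C_jj / sigma2_beta.
    signal level
        PEV of g = X beta, sigma2_beta * (G - G (G + lam D)^(-1) G); the
        reported reliabilities are diag(G (G + lam D)^(-1)), the
        "heritability matrix" diagonal — a phenotype-free measure of
        training-set information.
    """
    vc = _as_vc(vc)
    Xc = as_marker_matrix(X).center()
    n, p = Xc.shape
    w = vc.weight_vector(n)
    s2b = vc.sigma2_beta if vc.sigma2_beta is not None else 1.0
    V = Xc.values
    G = V @ V.T
    if level == "marker":
        # X'(XX'+lam D)^{-1} X via one SPD solve
        M = V.T @ _solve_system(G, vc.lam, w, V)
        C = s2b * (np.eye(p) - M)
        rel = 1.0 - np.diag(C) / s2b
        return ReliabilityReport(pev=C, reliabilities=rel, scheme="marker")
    if level == "signal":
        H = _solve_system(G, vc.lam, w, G).T
        pev = s2b * (G - H @ G)
        return ReliabilityReport(pev=pev, reliabilities=np.diag(H).copy(),
                                 scheme="signal")
    raise ParameterError(f"unknown level {level!r}")


def hat_matrix(G, vc) -> np.ndarray:
    """H = G (G + lam D)^(-1): the influence of phenotypes on fitted values."""
    vc = _as_vc(vc)
    G = np.asarray(G, dtype=float)
    w = vc.weight_vector(G.shape[0])
    return _solve_system(G, vc.lam, w, G).T


def predictive_correlation_bound(h2: float, n_bar: int = 1) -> float:
    """Upper bound sqrt(h2) on the predictive correlation (markers = QTL).

    For predicting a mean of ``n_bar`` records the bound rises to
    sqrt(n_bar*h2 / (1 + (n_bar - 1)*h2)) — the square root of the
    "heritability of a mean" — approaching 1 as n_bar grows but never
    reaching it.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ParameterError(f"h2 must lie in [0, 1], got {h2}")
    if n_bar < 1:
        raise ParameterError("n_bar must be >= 1")
    return float(np.sqrt(n_bar * h2 / (1.0 + (n_bar - 1.0) * h2)))
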