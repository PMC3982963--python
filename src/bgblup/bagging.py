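"""Bootstrap-aggregated (bagged) GBLUP and bagged marker effects.

Bagging emulates variation over training sets of a fixed size: take B
bootstrap copies of the training records (sampling individuals with
replacement, so a record may be absent or repeated), refit GBLUP on each
copy with the variance ratio fixed from the full data, and average the
B per-candidate predictions.  The average has the same bias as a single
GBLUP fit but — when the copies are not too correlated — a smaller
variance, which is where any predictive gain comes from.

Resampling is of individuals; a duplicated individual enters the
bootstrap relationship matrix as a duplicated row *and* column.  With
lam > 0 the bootstrap systems stay positive definite despite the
duplicates.  Each copy centers phenotypes on its own resampled mean.

The marker-effect (primal) path averages per-copy ridge BLUPs of the p
effects instead; the "indirect" bagged GBLUP maps those averaged effects
back to genomic values and is algebraically identical to the dual-form
bagged prediction when built from the same plan, lam and kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, ParameterError, SolverError
from .markers import MarkerMatrix, as_marker_matrix
from .model import VarianceComponents, _as_vc, _solve_system

__all__ = [
    "BootstrapPlan", "make_bootstrap_plan", "BaggedGBLUP",
    "BaggedEnsemble", "bag_gblup", "bag_marker_effects",
    "indirect_bagged_gblup",
]


@dataclass(frozen=True)
class BootstrapPlan:
    """B with-replacement resamples of the training index set."""

    B: int
    n_train: int
    indices: np.ndarray  # (B, n_train) integer positions
    seed: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.indices)
        if idx.shape != (self.B, self.n_train):
            raise ParameterError(
                f"indices have shape {idx.shape}, expected "
                f"({self.B}, {self.n_train})")


def make_bootstrap_plan(n_train: int, B: int, seed=0) -> BootstrapPlan:
    """Draw B independent bootstrap index lists of size n_train."""
    if B < 1:
        raise ParameterError(f"B must be >= 1, got {B}")
    if n_train < 2:
        raise ParameterError(
            f"n_train must be >= 2 for resampling, got {n_train}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.integers(0, n_train, size=(B, n_train))
    return BootstrapPlan(B=B, n_train=n_train, indices=idx,
                         seed=None if isinstance(seed, np.random.Generator)
                         else int(seed))


@dataclass
class BaggedEnsemble:
    """Per-bootstrap predictions/effects and their bagged means."""

    plan: BootstrapPlan
    pred_matrix: np.ndarray | None = None      # (B, n_target)
    bagged_mean: np.ndarray | None = None      # (n_target,)
    effect_matrix: np.ndarray | None = None    # (B, p)
    bagged_effects: np.ndarray | None = None   # (p,)
    intercepts: np.ndarray | None = None       # per-copy phenotype means
    lam: float | None = None
    target_ids: list | None = None
    alphas: np.ndarray | None = field(default=None, repr=False)  # (B, n_train)

    @property
    def B(self) -> int:
        return self.plan.B

    @property
    def intercept(self) -> float:
        """Average per-copy training phenotype mean."""
        return float(np.mean(self.intercepts))


class BaggedGBLUP:
    """Bagged GBLUP model: dual-form GBLUP averaged over bootstrap copies.

    Parameters
    ----------
    endog : array_like, shape (n,)
        Training phenotypes.
    grm : array_like, shape (n, n)
        Relationship matrix among training individuals.
    vc : VarianceComponents or float
        Variance components (ratio fixed once, from the full data).
    plan : BootstrapPlan, optional
        Explicit resampling plan; otherwise drawn from ``B`` and ``seed``.
    """

    def __init__(self, endog, grm, vc, plan: BootstrapPlan | None = None,
                 B: int = 25, seed=0, ids=None):
        self.y = np.asarray(endog, dtype=float).ravel()
        self.G = np.asarray(grm, dtype=float)
        n = self.y.size
        if self.G.shape != (n, n):
            raise AlignmentError(
                f"GRM is {self.G.shape}, phenotypes have length {n}")
        if plan is None:
            plan = make_bootstrap_plan(n, B, seed)
        if plan.n_train != n:
            raise AlignmentError(
                f"plan resamples {plan.n_train} records, data has {n}")
        self.plan = plan
        self.vc = _as_vc(vc)
        self.ids = list(ids) if ids is not None else [
            f"id_{i + 1:04d}" for i in range(n)]
        self.nobs = n

    def fit(self, grm_target=None, target_ids=None) -> BaggedEnsemble:
        """Fit GBLUP on every bootstrap copy and average the predictions.

        ``grm_target`` is an n_target x n matrix of relationships between
        prediction candidates and the full training set (defaults to the
        training GRM itself, i.e. in-sample targets).
        """
        G, y, vc, plan = self.G, self.y, self.vc, self.plan
        K = G if grm_target is None else np.asarray(grm_target, dtype=float)
        if K.ndim == 1:
            K = K[None, :]
        if K.shape[1] != self.nobs:
            raise AlignmentError(
                f"target relationships have {K.shape[1]} columns, "
                f"training set has {self.nobs}")
        w = vc.weight_vector(self.nobs)
        preds = np.empty((plan.B, K.shape[0]))
        mus = np.empty(plan.B)
        alphas = np.empty((plan.B, self.nobs))
        for b, idx in enumerate(plan.indices):
            Gbb = G[np.ix_(idx, idx)]
            yb = y[idx]
            mus[b] = yb.mean()
            try:
                alpha = _solve_system(Gbb, vc.lam, w[idx], yb - mus[b])
            except SolverError as err:
                raise SolverError(
                    f"bootstrap copy {b}: {err}; duplicated records make "
                    "G_bb singular when lam = 0 — use lam > 0") from None
            # scatter-add maps the copy's dual coefficients back to the
            # full index set, so K_new @ alphas[b] == K_new[:, idx] @ alpha
            alphas[b, :] = 0.0
            np.add.at(alphas[b], idx, alpha)
            preds[b] = K[:, idx] @ alpha + mus[b]
        return BaggedEnsemble(
            plan=plan, pred_matrix=preds, bagged_mean=preds.mean(axis=0),
            intercepts=mus, lam=vc.lam, alphas=alphas,
            target_ids=list(target_ids) if target_ids is not None else None)


def bag_gblup(G_full, y, vc, plan: BootstrapPlan, grm_target=None,
              target_ids=None) -> BaggedEnsemble:
    """Functional form of :class:`BaggedGBLUP` (dual-form bagging)."""
    model = BaggedGBLUP(y, G_full, vc, plan=plan)
    return model.fit(grm_target=grm_target, target_ids=target_ids)


def bag_marker_effects(X, y, vc, plan: BootstrapPlan) -> BaggedEnsemble:
    """Bagged ridge-regression BLUP of marker effects.

    Marker genotypes are centered once on the full-sample column means;
    each bootstrap copy then resamples rows of the centered matrix and
    its phenotypes, centers the phenotypes on the resampled mean, and
    computes the ridge BLUP through the dual identity.  The bagged
    estimator is the average of the B per-copy effect vectors.
    """
    vc = _as_vc(vc)
    if vc.lam <= 0:
        raise ParameterError("bagged ridge requires lam > 0")
    Xc = as_marker_matrix(X).center()
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xc.shape
    if y.size != n:
        raise AlignmentError(f"{y.size} phenotypes for {n} individuals")
    if plan.n_train != n:
        raise AlignmentError(
            f"plan resamples {plan.n_train} records, data has {n}")
    V = Xc.values
    w = vc.weight_vector(n)
    effects = np.empty((plan.B, p))
    mus = np.empty(plan.B)
    for b, idx in enumerate(plan.indices):
        Vb = V[idx]
        yb = y[idx]
        mus[b] = yb.mean()
        alpha = _solve_system(Vb @ Vb.T, vc.lam, w[idx], yb - mus[b])
        effects[b] = Vb.T @ alpha
    return BaggedEnsemble(plan=plan, effect_matrix=effects,
                          bagged_effects=effects.mean(axis=0),
                          intercepts=mus, lam=vc.lam)


def indirect_bagged_gblup(X, bagged_effects, intercept: float = 0.0,
                          center_like: MarkerMatrix | None = None) -> np.ndarray:
    """Map bagged marker effects back to genomic-value predictions.

    ghat_bag = Xc @ bagged_effects + intercept.  When ``X`` is the
    training matrix, the same plan and lam are used, and ``intercept``
    is the ensemble's average per-copy phenotype mean, this reproduces
    the dual-form bagged prediction exactly.
    """
    bagged_effects = np.asarray(bagged_effects, dtype=float).ravel()
    Xm = as_marker_matrix(X)
    Xc = Xm.center() if center_like is None else Xm.center_like(center_like)
    if Xc.p != bagged_effects.size:
        raise AlignmentError(
            f"{bagged_effects.size} effects for {Xc.p} loci")
    return Xc.values @ bagged_effects + intercept
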