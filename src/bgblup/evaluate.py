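"""Cross-validation machinery and end-to-end case-study runners.

Repeated random disjoint training/testing partitions, regularization
grids, the three evaluation metrics (predictive correlation, mean
squared error, mean absolute deviation), slope diagnostics of true
values on predictions, and runners that regenerate each simulated case
study's headline statistics from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from . import simulate
from .bagging import bag_gblup, bag_marker_effects, make_bootstrap_plan
from .exceptions import EstimabilityError, ParameterError
from .markers import as_marker_matrix
from .model import GBLUP, build_grm, ols_effects, ridge_marker_blup
from .reliability import (adjusted_reliability, empirical_pmse,
                          empirical_reliability, reliability_disconnect)

__all__ = [
    "PartitionSet", "make_partitions", "lambda_grid", "DEFAULT_MULTIPLIERS",
    "prediction_metrics", "slope_true_on_predicted", "ols_fit",
    "CvReport", "run_cv", "run_case_study", "reliability_experiment",
    "theoretical_testing_reliability",
]

# 13 multipliers spanning heavy under- to heavy over-regularization
# around the value treated as correct (reconstruction; the original
# sequence is not printed).
DEFAULT_MULTIPLIERS = (1 / 64, 1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2,
                       1, 2, 5, 10, 20, 50, 100)


# ---------------------------------------------------------------------------
# partitions and grids
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PartitionSet:
    """Repeated random disjoint, exhaustive train/test splits."""

    n: int
    n_train: int
    train_idx: tuple
    test_idx: tuple
    seed: int | None = None

    @property
    def repeats(self) -> int:
        return len(self.train_idx)


def make_partitions(n: int, n_train: int, repeats: int,
                    seed=0) -> PartitionSet:
    """Draw ``repeats`` uniformly random disjoint train/test splits."""
    if not 0 < n_train < n:
        raise ParameterError(
            f"need 0 < n_train < n, got n_train={n_train}, n={n}")
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    train, test = [], []
    for _ in range(repeats):
        perm = rng.permutation(n)
        train.append(tuple(np.sort(perm[:n_train])))
        test.append(tuple(np.sort(perm[n_train:])))
    return PartitionSet(n=n, n_train=n_train, train_idx=tuple(train),
                        test_idx=tuple(test),
                        seed=None if isinstance(seed, np.random.Generator)
                        else int(seed))


def lambda_grid(lam_base: float, multipliers=DEFAULT_MULTIPLIERS) -> list[float]:
    """Ordered regularization grid multiplier_j * lam_base."""
    mult = [float(m) for m in multipliers]
    if lam_base <= 0 or any(m <= 0 for m in mult):
        raise ParameterError("lambda grid entries must be positive")
    if any(b <= a for a, b in zip(mult, mult[1:])):
        raise ParameterError("multipliers must be strictly ascending")
    return [m * lam_base for m in mult]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
def prediction_metrics(y_test, pred):
    """(pearson correlation, mse, mad) between realized and predicted.

    With a zero-variance input the correlation is undefined and returned
    as nan; mse and mad are always returned.
    """
    y = np.asarray(y_test, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if y.size != p.size:
        raise ParameterError(f"length mismatch {y.size} vs {p.size}")
    diff = p - y
    mse = float(np.mean(diff ** 2))
    mad = float(np.mean(np.abs(diff)))
    if np.std(y) == 0 or np.std(p) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(y, p)[0, 1])
    return corr, mse, mad


def slope_true_on_predicted(truth, predicted):
    """Least-squares slope of truth on predicted, and its R^2.

    A slope of 1 means predictions are on the right scale on average;
    shrinkage-deficient estimators (OLS with noisy designs) give slopes
    below 1, while bagged predictors — less variable than their target
    regression — give slopes above 1.
    """
    t = np.asarray(truth, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if t.size != p.size:
        raise ParameterError(f"length mismatch {t.size} vs {p.size}")
    vp = np.var(p)
    if vp == 0:
        raise ParameterError("zero-variance predictor: slope undefined")
    slope = float(np.cov(t, p, bias=True)[0, 1] / vp)
    vt = np.var(t)
    r2 = float(np.cov(t, p, bias=True)[0, 1] ** 2 / (vp * vt)) if vt > 0 else 0.0
    return slope, r2


def ols_fit(X, y):
    """OLS multiple regression of y on genotype columns: (fitted, R^2)."""
    Xc = as_marker_matrix(X).center()
    y = np.asarray(y, dtype=float).ravel()
    beta = ols_effects(Xc, y)
    fitted = Xc.values @ beta + y.mean()
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return fitted, 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# cross-validation runner
# ---------------------------------------------------------------------------
@dataclass
class CvReport:
    """Per (repeat, lambda, method) metrics plus aggregation helpers."""

    table: pd.DataFrame
    config: dict = field(default_factory=dict)
    reliability_table: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        """Median and range of each metric by method and lambda."""
        g = self.table.groupby(["method", "lam"])[
            ["train_corr", "pred_corr", "pred_mse", "pred_mad"]]
        out = g.agg(["median", "min", "max"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()

    def improvement(self, lam=None) -> dict:
        """BGBLUP-vs-GBLUP median comparison at one lambda.

        Returns the percent gain in median predictive correlation, the
        median-MSE ratio (as %), and the fraction of repeats where
        BGBLUP beats GBLUP on each metric.
        """
        t = self.table
        if lam is None:
            lam = t["lam"].iloc[0]
        sel = t[np.isclose(t["lam"], lam)]
        g = sel[sel["method"] == "gblup"].set_index("repeat")
        b = sel[sel["method"] == "bgblup"].set_index("repeat")
        if g.empty or b.empty:
            raise ParameterError("improvement() needs both methods")
        return {
            "lam": float(lam),
            "median_corr_gblup": float(g["pred_corr"].median()),
            "median_corr_bgblup": float(b["pred_corr"].median()),
            "corr_gain_pct": 100.0 * (b["pred_corr"].median()
                                      / g["pred_corr"].median() - 1.0),
            "median_mse_gblup": float(g["pred_mse"].median()),
            "median_mse_bgblup": float(b["pred_mse"].median()),
            "mse_ratio_pct": 100.0 * (b["pred_mse"].median()
                                      / g["pred_mse"].median()),
            "frac_repeats_corr_better": float(
                np.mean(b["pred_corr"].values > g["pred_corr"].values)),
            "frac_repeats_mse_better": float(
                np.mean(b["pred_mse"].values < g["pred_mse"].values)),
        }


def _eig_alpha(d, V, yc, lam):
    return V @ ((V.T @ yc) / (d + lam))


def run_cv(y, G, grid, partitions: PartitionSet, B: int = 25,
           methods: str = "both", bootstrap_seed=0,
           collect_reliability: bool = False) -> CvReport:
    """Repeated-partition cross-validation of GBLUP and bagged GBLUP.

    For every repeat and every lambda in ``grid``, the model is fitted
    on the training half (bagging refits on B bootstrap copies of it),
    the testing half is predicted through the cross-relationship rows of
    ``G``, and training correlation plus the three predictive metrics
    are recorded.  A spectral decomposition of each (bootstrap) training
    kernel is reused across the whole lambda grid, so the grid length
    adds almost nothing to the cost.

    ``collect_reliability`` additionally stores the per-candidate
    bootstrap PMSE and empirical reliabilities (training-phenotype
    variance denominator) for every repeat and lambda.
    """
    y = np.asarray(y, dtype=float).ravel()
    G = np.asarray(G, dtype=float)
    grid = [float(l) for l in grid]
    if not grid:
        raise ParameterError("empty lambda grid")
    if methods not in ("gblup", "bgblup", "both"):
        raise ParameterError(f"unknown methods {methods!r}")
    do_g = methods in ("gblup", "both")
    do_b = methods in ("bgblup", "both")
    if do_b and B < 1:
        raise ParameterError("B must be >= 1 for bagging")
    rng = bootstrap_seed if isinstance(bootstrap_seed, np.random.Generator) \
        else np.random.default_rng(bootstrap_seed)
    rows, rel_rows = [], []
    for rep in range(partitions.repeats):
        T = np.asarray(partitions.train_idx[rep])
        S = np.asarray(partitions.test_idx[rep])
        G_TT = G[np.ix_(T, T)]
        G_ST = G[np.ix_(S, T)]
        yT, yS = y[T], y[S]
        mu = yT.mean()
        yc = yT - mu
        try:
            if do_g:
                d, V = sla.eigh(G_TT, check_finite=False)
                for lam in grid:
                    alpha = _eig_alpha(d, V, yc, lam)
                    fit_tr = G_TT @ alpha + mu
                    pred = G_ST @ alpha + mu
                    c, mse, mad = prediction_metrics(yS, pred)
                    rows.append((rep, lam, "gblup",
                                 float(np.corrcoef(fit_tr, yT)[0, 1]),
                                 c, mse, mad))
            if do_b:
                plan = make_bootstrap_plan(T.size, B, rng)
                fit_acc = {lam: np.zeros(T.size) for lam in grid}
                pred_all = {lam: np.empty((B, S.size)) for lam in grid}
                for b, idx in enumerate(plan.indices):
                    Gbb = G_TT[np.ix_(idx, idx)]
                    yb = yT[idx]
                    mub = yb.mean()
                    db, Vb = sla.eigh(Gbb, check_finite=False)
                    for lam in grid:
                        ab = _eig_alpha(db, Vb, yb - mub, lam)
                        fit_acc[lam] += G_TT[:, idx] @ ab + mub
                        pred_all[lam][b] = G_ST[:, idx] @ ab + mub
                for lam in grid:
                    fit_tr = fit_acc[lam] / B
                    pred = pred_all[lam].mean(axis=0)
                    c, mse, mad = prediction_metrics(yS, pred)
                    rows.append((rep, lam, "bgblup",
                                 float(np.corrcoef(fit_tr, yT)[0, 1]),
                                 c, mse, mad))
                    if collect_reliability:
                        pmse = empirical_pmse(pred_all[lam], yS)
                        rel = empirical_reliability(pmse, np.var(yT, ddof=1))
                        for j, cand in enumerate(S):
                            rel_rows.append((rep, lam, int(cand),
                                             pmse[j], rel[j]))
        except Exception as err:
            raise type(err)(f"repeat {rep}: {err}") from err
    table = pd.DataFrame(rows, columns=[
        "repeat", "lam", "method", "train_corr",
        "pred_corr", "pred_mse", "pred_mad"])
    rel_table = (pd.DataFrame(rel_rows, columns=[
        "repeat", "lam", "candidate", "pmse", "rel"])
        if collect_reliability else None)
    cfg = {"grid": grid, "B": B, "methods": methods,
           "repeats": partitions.repeats, "n_train": partitions.n_train,
           "partition_seed": partitions.seed}
    return CvReport(table=table, config=cfg, reliability_table=rel_table)


# ---------------------------------------------------------------------------
# case-study runners
# ---------------------------------------------------------------------------
def _case12_report(case_id: int, seed, B_list, B_gblup=None) -> dict:
    ds = simulate.case_study(case_id, seed=seed)
    lam = ds.lambda_true
    Q, y = ds.Q, ds.y
    out = {"case": case_id, "h2_effective": ds.h2_effective,
           "lambda_true": lam}
    try:
        beta_ols = ols_effects(Q, y)
        s, r2 = slope_true_on_predicted(ds.beta_true, beta_ols)
        out["ols_slope"], out["ols_r2"] = s, r2
        out["ols_estimable"] = True
    except EstimabilityError as err:
        out["ols_estimable"] = False
        out["ols_error"] = str(err)
    beta_ridge = ridge_marker_blup(Q, y, lam)
    s, r2 = slope_true_on_predicted(ds.beta_true, beta_ridge)
    out["ridge_slope"], out["ridge_r2"] = s, r2

    G = build_grm(Q)
    res = GBLUP(y, G, lam).fit()
    s, r2 = slope_true_on_predicted(ds.signal, res.ghat)
    out["gblup_signal_slope"], out["gblup_signal_r2"] = s, r2

    rng = np.random.default_rng(np.random.SeedSequence(
        [int(case_id), _seed_int(seed)]))
    for B in B_list:
        plan = make_bootstrap_plan(ds.n, B, rng)
        bag = bag_marker_effects(Q, y, lam, plan)
        s, r2 = slope_true_on_predicted(ds.beta_true, bag.bagged_effects)
        out[f"bagged_ridge_slope_B{B}"] = s
        out[f"bagged_ridge_r2_B{B}"] = r2
        ens = bag_gblup(G, y, lam, plan)
        s, r2 = slope_true_on_predicted(ds.signal, ens.bagged_mean)
        out[f"bgblup_signal_slope_B{B}"] = s
        out[f"bgblup_signal_r2_B{B}"] = r2
        out[f"var_bagged_means_B{B}"] = float(np.var(ens.bagged_mean))
        out[f"mean_within_copy_var_B{B}"] = float(
            np.mean(np.var(ens.pred_matrix, axis=1)))
        sl, _ = slope_true_on_predicted(ens.bagged_mean, res.fittedvalues)
        out[f"bgblup_on_gblup_slope_B{B}"] = sl
    return out


def _case3_report(seed, B: int = 25) -> dict:
    ds = simulate.case_study(3, seed=seed)
    Q, X, y = ds.Q, ds.X, ds.y
    out = {"case": 3, "h2_effective": ds.h2_effective,
           "lambda_true": ds.lambda_true}
    qv, xv = Q.values, X.values

    def _corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    out["corr_q1_q2"] = _corr(qv[:, 0], qv[:, 1])
    out["corr_q1_q15"] = _corr(qv[:, 0], qv[:, 14])
    out["corr_m1_m2"] = _corr(xv[:, 0], xv[:, 1])
    out["corr_m1_m200"] = _corr(xv[:, 0], xv[:, 199])
    out["corr_q2_m105"] = _corr(qv[:, 1], xv[:, 104])

    # how well do the 200 markers linearly capture each QTL genotype?
    r2_block, r2_le = [], []
    for j in range(Q.p):
        _, r2 = ols_fit(X, qv[:, j])
        (r2_block if j < 10 else r2_le).append(r2)
    out["qtl_on_markers_r2_block_mean"] = float(np.mean(r2_block))
    out["qtl_on_markers_r2_le_mean"] = float(np.mean(r2_le))

    fitted_q, r2_q = ols_fit(Q, y)
    fitted_x, r2_x = ols_fit(X, y)
    out["fit_r2_qtl"] = r2_q
    out["fit_r2_markers"] = r2_x
    out["signal_r2_qtl"] = _corr(fitted_q, ds.signal) ** 2
    out["signal_r2_markers"] = _corr(fitted_x, ds.signal) ** 2

    # genomic correlation matrices: marker-based off-diagonals shrink
    Cq = build_grm(Q, "correlation")
    Cx = build_grm(X, "correlation")
    iu = np.triu_indices(ds.n, k=1)
    out["mean_abs_offdiag_qtl_corr"] = float(np.mean(np.abs(Cq[iu])))
    out["mean_abs_offdiag_marker_corr"] = float(np.mean(np.abs(Cx[iu])))

    # GBLUP / BGBLUP on markers at three regularization levels
    G = build_grm(X)
    rng = np.random.default_rng(np.random.SeedSequence([3, _seed_int(seed)]))
    for k, mult in enumerate((1.0, 5.0, 10.0), start=1):
        lam = mult * ds.lambda_true
        res = GBLUP(y, G, lam).fit()
        s, _ = slope_true_on_predicted(ds.signal, res.ghat)
        out[f"gblup_signal_slope_lam{k}"] = s
        plan = make_bootstrap_plan(ds.n, B, rng)
        ens = bag_gblup(G, y, lam, plan)
        s, _ = slope_true_on_predicted(ds.signal, ens.bagged_mean)
        out[f"bgblup_signal_slope_lam{k}"] = s
    return out


def _case4_report(seed, B: int = 25, repeats: int = 100,
                  grid=None, n: int | None = None,
                  bootstrap_seed=None) -> dict:
    ds = simulate.case_study(4, seed=seed, n=n)
    lam_true = ds.lambda_true_marker
    grid = [lam_true] if grid is None else list(grid)
    G = build_grm(ds.X)
    parts = make_partitions(ds.n, ds.n // 2, repeats,
                            seed=np.random.default_rng(
                                np.random.SeedSequence([4, _seed_int(seed)])))
    report = run_cv(ds.y, G, grid, parts, B=B,
                    bootstrap_seed=np.random.default_rng(
                        np.random.SeedSequence(
                            [44, _seed_int(bootstrap_seed if bootstrap_seed
                                           is not None else seed)])))
    out = {"case": 4, "h2_effective": ds.h2_effective,
           "lambda_true_marker": lam_true,
           "summary": report.summary()}
    # improvement at the grid value closest to the "true" lambda
    lam_ref = min(grid, key=lambda l: abs(np.log(l / lam_true)))
    out.update({f"imp_{k}": v
                for k, v in report.improvement(lam=lam_ref).items()})
    out["report"] = report
    return out


def _seed_int(seed) -> int:
    try:
        return abs(int(seed)) % (2 ** 31)
    except (TypeError, ValueError):
        return 0


def run_case_study(case_id: int, seed=0, **kw) -> dict:
    """Regenerate one case study's headline statistics from scratch.

    Keyword arguments are forwarded to the case-specific runner
    (``B_list`` for cases 1-2, ``B`` for case 3, ``B``/``repeats``/
    ``grid``/``n`` for case 4).
    """
    if case_id == 1:
        return _case12_report(1, seed, kw.get("B_list", (200, 500)))
    if case_id == 2:
        return _case12_report(2, seed, kw.get("B_list", (10, 25, 50)))
    if case_id == 3:
        return _case3_report(seed, B=kw.get("B", 25))
    if case_id == 4:
        return _case4_report(seed, B=kw.get("B", 25),
                             repeats=kw.get("repeats", 100),
                             grid=kw.get("grid"), n=kw.get("n"),
                             bootstrap_seed=kw.get("bootstrap_seed"))
    raise ParameterError(f"unknown case_id {case_id!r}; expected 1-4")


# ---------------------------------------------------------------------------
# reliability experiment (case-4 structure, variance ratio 20)
# ---------------------------------------------------------------------------
def theoretical_testing_reliability(G, train_idx, test_idx,
                                    lam: float) -> np.ndarray:
    """Model-derived reliability of predicted genomic values, per candidate.

    The proportion of a testing candidate's genetic variance that the
    training relationships recover:
    diag(G_ST (G_TT + lam I)^(-1) G_TS) / diag(G_SS).  Uses genotypes and
    variance components only — no phenotypes (reconstruction of the
    phenotype-free "expected" reliability).
    """
    G = np.asarray(G, dtype=float)
    T = np.asarray(train_idx)
    S = np.asarray(test_idx)
    G_TT = G[np.ix_(T, T)]
    G_TS = G[np.ix_(T, S)]
    A = G_TT + lam * np.eye(T.size)
    M = sla.solve(A, G_TS, assume_a="pos")
    num = np.einsum("ij,ij->j", G_TS, M)
    den = np.diag(G)[S]
    return num / den


def reliability_experiment(seed=0, lam_train: float = 100.0, B: int = 25,
                           sigma2_e: float = 20.0, n: int = 500) -> dict:
    """Candidate-specific reliabilities under the case-4 design.

    Regenerates the case-4 genotype/LD structure but with the residual
    variance set to give a true QTL-level variance ratio
    sigma2_e/sigma2_beta = 20, splits once into equal training and
    testing halves, bags GBLUP on the training half, and computes the
    per-candidate bootstrap PMSE, the raw empirical reliabilities
    (training-phenotype-variance denominator), the diagonal-adjusted
    reliabilities, and their (dis)association with the model-derived
    testing-set reliabilities.
    """
    cfg = simulate.case_config(4)
    cfg["sigma2_e"] = float(sigma2_e)
    cfg["lambda_true_qtl"] = float(sigma2_e)
    cfg["lambda_true_marker"] = sigma2_e * cfg["p"] / cfg["q"]
    cfg["n"] = int(n)
    rng = np.random.default_rng(np.random.SeedSequence([10, _seed_int(seed)]))
    ld = cfg["ld"]
    spec = simulate.LdBlockSpec(
        n_qtl_total=cfg["q"], n_markers_total=cfg["p"],
        qtl_ld_block=tuple(ld["qtl_block"]),
        marker_ld_block=tuple(ld["marker_block"]),
        beta_a=ld["beta_a"], beta_b=ld["beta_b"])
    Q, X = simulate.sample_ld_genotypes(cfg["n"], spec, seed=rng)
    ds = simulate.make_phenotypes(Q, effect_sd=cfg["effect_sd"],
                                  sigma2_e=cfg["sigma2_e"], seed=rng,
                                  X=X, config=cfg)
    G = build_grm(ds.X)
    parts = make_partitions(ds.n, ds.n // 2, 1, seed=rng)
    T = np.asarray(parts.train_idx[0])
    S = np.asarray(parts.test_idx[0])
    plan = make_bootstrap_plan(T.size, B, rng)
    ens = bag_gblup(G[np.ix_(T, T)], ds.y[T], lam_train, plan,
                    grm_target=G[np.ix_(S, T)])
    pmse = empirical_pmse(ens.pred_matrix, ds.y[S])
    denom = float(np.var(ds.y[T], ddof=1))
    rel = empirical_reliability(pmse, denom)
    # per-candidate phenotypic variance: sigma2_beta * G_ii + sigma2_e
    rel_adj = adjusted_reliability(pmse, np.diag(G)[S], 1.0, sigma2_e)
    theo = theoretical_testing_reliability(G, T, S, lam_train)
    disc = reliability_disconnect(theo, rel)
    return {
        "lam_train": lam_train, "B": B, "sigma2_e": sigma2_e,
        "h2_effective": ds.h2_effective, "denom": denom,
        "pmse": pmse, "rel": rel, "rel_adjusted": rel_adj,
        "theoretical": theo,
        "median_rel": float(np.median(rel)),
        "n_negative_rel": int(np.sum(rel < 0)),
        "median_rel_adjusted": float(np.median(rel_adj)),
        "frac_adj_in_band": float(np.mean((rel_adj > 0.40)
                                          & (rel_adj < 1.0))),
        "disconnect_spearman": disc["spearman"],
        "disconnect_pearson": disc["pearson"],
        "test_idx": S, "train_idx": T,
    }
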