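"""Candidate-specific empirical cross-validation reliabilities.

Bagging yields, for each candidate i in a testing set with fixed
realized outcome y_i, a set of B bootstrap predictions ghat_i^(b).  The
bootstrap average squared prediction error

    pmse_i = (1/B) * sum_b (y_i - ghat_i^(b))^2

reflects both squared bias and predictor variance (exactly:
pmse_i = (mean_b ghat_i^(b) - y_i)^2 + var_b(ghat_i^(b))).  An empirical
reliability is then

    rel_i = 1 - pmse_i / denom,

with the phenotypic variance of the training set as the default
denominator; rel_i <= 1 always, and negative values are reported
unclipped (a clipped companion column is provided).  Because the
unscaled cross-product kernel gives every candidate its own genetic
variance sigma2_beta * G_ii, an adjusted variant divides by the
candidate-specific phenotypic variance instead:

    rel*_i = 1 - pmse_i / (g_ii * sigma2_g + sigma2_e).

These are phenotype-prediction metrics; they gauge closeness of
prediction to realized outcome, not the model-internal precision that
theoretical (PEV-based) reliabilities measure — and empirically the two
are unrelated, which ``reliability_disconnect`` quantifies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ParameterError

__all__ = [
    "empirical_pmse", "empirical_reliability", "adjusted_reliability",
    "reliability_disconnect", "candidate_reliability_table",
]


def empirical_pmse(pred_matrix, y_test) -> np.ndarray:
    """Per-candidate bootstrap average squared prediction error."""
    P = np.asarray(pred_matrix, dtype=float)
    y = np.asarray(y_test, dtype=float).ravel()
    if P.ndim != 2:
        raise ParameterError("pred_matrix must be B x n_test")
    if P.shape[0] < 1:
        raise ParameterError("need at least one bootstrap copy")
    if P.shape[1] != y.size:
        raise AlignmentError(
            f"pred_matrix has {P.shape[1]} candidates, y_test {y.size}")
    return np.mean((P - y[None, :]) ** 2, axis=0)


def empirical_reliability(pmse, denom) -> np.ndarray:
    """rel_i = 1 - pmse_i / denom_i; unclipped, may be negative."""
    pmse = np.asarray(pmse, dtype=float).ravel()
    denom = np.asarray(denom, dtype=float)
    if denom.ndim == 0:
        denom = np.full_like(pmse, float(denom))
    if denom.size != pmse.size:
        raise AlignmentError(
            f"{denom.size} denominators for {pmse.size} candidates")
    if np.any(denom <= 0):
        raise ParameterError("reliability denominator must be positive")
    return 1.0 - pmse / denom


def adjusted_reliability(pmse, g_diag, sigma2_g: float, sigma2_e: float,
                         training_constant: bool = False) -> np.ndarray:
    """Diagonal-adjusted reliability 1 - pmse_i/(g_ii*sigma2_g + sigma2_e).

    ``g_diag`` are the candidates' diagonal elements of the testing-set
    relationship structure.  With ``training_constant=True`` the
    candidate-specific g_ii is replaced by its mean, i.e. a constant
    denominator over the set (the variant used alongside the
    candidate-specific one).
    """
    pmse = np.asarray(pmse, dtype=float).ravel()
    g_diag = np.asarray(g_diag, dtype=float).ravel()
    if g_diag.size != pmse.size:
        raise AlignmentError(
            f"{g_diag.size} diagonal elements for {pmse.size} candidates")
    if sigma2_g < 0 or sigma2_e <= 0:
        raise ParameterError("variance components must be positive")
    if training_constant:
        g_diag = np.full_like(g_diag, g_diag.mean())
    denom = g_diag * sigma2_g + sigma2_e
    if np.any(denom <= 0):
        raise ParameterError("adjusted denominator must be positive")
    return 1.0 - pmse / denom


def reliability_disconnect(theoretical, empirical, bins: int = 10) -> dict:
    """Quantify (lack of) association between the two reliability notions.

    Returns rank (Spearman) and product-moment (Pearson) correlations
    plus a binned summary table of empirical reliability by decile of
    theoretical reliability, suitable for plotting.  No thresholding.
    """
    t = np.asarray(theoretical, dtype=float).ravel()
    e = np.asarray(empirical, dtype=float).ravel()
    if t.size != e.size:
        raise AlignmentError(f"{t.size} theoretical vs {e.size} empirical")
    rho, rho_p = stats.spearmanr(t, e)
    r, r_p = stats.pearsonr(t, e)
    edges = np.quantile(t, np.linspace(0, 1, bins + 1))
    which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, bins - 1)
    table = pd.DataFrame({
        "bin": range(bins),
        "theoretical_mid": [t[which == b].mean() if np.any(which == b)
                            else np.nan for b in range(bins)],
        "empirical_mean": [e[which == b].mean() if np.any(which == b)
                           else np.nan for b in range(bins)],
        "n": [int(np.sum(which == b)) for b in range(bins)],
    })
    return {"spearman": float(rho), "spearman_p": float(rho_p),
            "pearson": float(r), "pearson_p": float(r_p), "table": table}


def candidate_reliability_table(pred_matrix, y_test, denom=None,
                                g_diag=None, sigma2_g=None, sigma2_e=None,
                                ids=None) -> pd.DataFrame:
    """Assemble the per-candidate TSV-ready table (id, pmse, rel, ...)."""
    pmse = empirical_pmse(pred_matrix, y_test)
    n = pmse.size
    out = pd.DataFrame({
        "id": list(ids) if ids is not None
        else [f"id_{i + 1:04d}" for i in range(n)],
        "pmse": pmse,
    })
    if denom is not None:
        rel = empirical_reliability(pmse, denom)
        out["rel"] = rel
        out["rel_clipped"] = np.clip(rel, 0.0, None)
    if g_diag is not None:
        if sigma2_g is None or sigma2_e is None:
            raise ParameterError(
                "adjusted reliability needs sigma2_g and sigma2_e")
        out["rel_adjusted"] = adjusted_reliability(
            pmse, g_diag, sigma2_g, sigma2_e)
    return out
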