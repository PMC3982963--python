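"""Synthetic genotype/phenotype generators for the four case studies.

The generating model throughout is the finite-locus additive model of
quantitative genetics for inbred lines: binary genotype codes (0/1) at
``q`` QTL, allelic substitution effects drawn iid N(0, effect_sd^2),
signal g = Q beta, phenotype y = g + e with e iid N(0, sigma2_e).

Linkage disequilibrium (LD) is statistical, not positional: for each
individual a latent allele probability p_i ~ Beta(a, b) is drawn once
and shared by every locus inside a designated block, so genotypes inside
the block are beta-binomial with expected pairwise column correlation
1/(a + b + 1) (the beta-binomial intraclass correlation).  Loci outside
the block are independent Bernoulli(0.5).  With a = b = 0.5 the expected
within-block correlation is 0.5.  There is no genetic map and no
recombination; a single latent p_i drives both the QTL and the marker
block, which is what creates QTL-marker LD.

Effect and residual variances are calibrated, not copied: effect_sd = 1
everywhere and sigma2_e is solved per case so that the *expected*
heritability q*freq*(1-freq) / (q*freq*(1-freq) + sigma2_e) matches the
case's target; the realized ("effective") heritability — variance of the
simulated signal over total variance — is then recorded from the drawn
vectors, never forced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParameterError
from .markers import MarkerMatrix

__all__ = [
    "LdBlockSpec", "SimDataset", "sample_binary_genotypes",
    "sample_ld_genotypes", "make_phenotypes", "case_study",
    "case_config", "write_dataset", "CASE_CONFIGS",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LdBlockSpec:
    """Layout of one shared beta-binomial LD block over QTL and markers.

    ``qtl_ld_block`` and ``marker_ld_block`` are half-open index ranges
    (start, stop) of the columns sharing the per-individual latent
    Beta(beta_a, beta_b) success probability.  Expected pairwise
    correlation of any two block columns is 1/(beta_a + beta_b + 1).
    """

    n_qtl_total: int
    n_markers_total: int
    qtl_ld_block: tuple[int, int]
    marker_ld_block: tuple[int, int]
    beta_a: float = 0.5
    beta_b: float = 0.5

    def __post_init__(self):
        if self.n_qtl_total < 1 or self.n_markers_total < 0:
            raise ParameterError("totals must be positive")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ParameterError("beta parameters must be positive")
        for (lo, hi), total, name in (
                (self.qtl_ld_block, self.n_qtl_total, "qtl"),
                (self.marker_ld_block, self.n_markers_total, "marker")):
            if not (0 <= lo <= hi <= total):
                raise ParameterError(
                    f"{name} block {lo}:{hi} outside 0:{total}")

    @property
    def expected_block_correlation(self) -> float:
        """Beta-binomial intraclass correlation 1/(a + b + 1)."""
        return 1.0 / (self.beta_a + self.beta_b + 1.0)


@dataclass
class SimDataset:
    """A simulated sample: genotypes, true effects, signal and phenotypes."""

    Q: MarkerMatrix
    beta_true: np.ndarray
    signal: np.ndarray
    y: np.ndarray
    sigma2_e: float
    h2_effective: float
    X: MarkerMatrix | None = None
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.Q.n

    @property
    def lambda_true(self) -> float | None:
        """True variance ratio sigma2_e/effect variance at the QTL level."""
        return self.config.get("lambda_true_qtl")

    @property
    def lambda_true_marker(self) -> float | None:
        """Variance ratio appropriate when training on markers."""
        return self.config.get("lambda_true_marker")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------
def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_binary_genotypes(n: int, p: int, freq: float = 0.5,
                            seed=0, prefix: str = "m") -> MarkerMatrix:
    """n x p independent 0/1 genotypes with allele frequency ``freq``."""
    if not 0.0 < freq < 1.0:
        raise ParameterError(f"freq must be in (0, 1), got {freq}")
    if n < 1 or p < 1:
        raise ParameterError("n and p must be >= 1")
    rng = _rng(seed)
    vals = (rng.random((n, p)) < freq).astype(float)
    return MarkerMatrix(vals, locus_ids=[f"{prefix}{j + 1:04d}"
                                         for j in range(p)])


def sample_ld_genotypes(n: int, spec: LdBlockSpec, seed=0):
    """QTL and marker genotypes with one shared beta-binomial LD block.

    Returns ``(Q, X)``; every column inside the joint block is an
    independent Bernoulli(p_i) draw given the individual's latent
    p_i ~ Beta(a, b); all remaining columns are Bernoulli(0.5).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = _rng(seed)
    latent = rng.beta(spec.beta_a, spec.beta_b, size=n)

    def _block(total, block, prefix):
        vals = (rng.random((n, total)) < 0.5).astype(float)
        lo, hi = block
        if hi > lo:
            vals[:, lo:hi] = (rng.random((n, hi - lo))
                              < latent[:, None]).astype(float)
        return MarkerMatrix(vals, locus_ids=[f"{prefix}{j + 1:04d}"
                                             for j in range(total)])

    Q = _block(spec.n_qtl_total, spec.qtl_ld_block, "q")
    X = (_block(spec.n_markers_total, spec.marker_ld_block, "m")
         if spec.n_markers_total else None)
    return Q, X


def make_phenotypes(Q: MarkerMatrix, effect_sd: float = 1.0,
                    sigma2_e: float = 1.0, seed=0,
                    X: MarkerMatrix | None = None,
                    config: dict | None = None) -> SimDataset:
    """Draw effects and residuals; record the realized heritability."""
    if effect_sd < 0:
        raise ParameterError("effect_sd must be nonnegative")
    if sigma2_e <= 0:
        raise ParameterError("sigma2_e must be positive")
    rng = _rng(seed)
    beta = rng.normal(0.0, effect_sd, size=Q.p)
    signal = Q.values @ beta
    y = signal + rng.normal(0.0, np.sqrt(sigma2_e), size=Q.n)
    vy = float(np.var(y))
    h2 = float(np.var(signal) / vy) if vy > 0 else 0.0
    return SimDataset(Q=Q, X=X, beta_true=beta, signal=signal, y=y,
                      sigma2_e=sigma2_e, h2_effective=h2,
                      config=dict(config or {}))


# ---------------------------------------------------------------------------
# case-study presets
# ---------------------------------------------------------------------------
def _resid_var(q: int, freq: float, effect_sd: float, h2: float) -> float:
    vg = q * freq * (1.0 - freq) * effect_sd ** 2
    return vg * (1.0 - h2) / h2

# Preset configurations.  Cases 1-2: markers are the (known) QTL, no LD
# beyond finite-sample noise.  Cases 3-4: unknown QTL flagged by markers,
# with the first half of the QTL and of the markers in one shared LD
# block of expected correlation 0.5.  The marker-level "true" lambda
# follows the p/q rule of thumb: when p markers proxy q QTL, the correct
# variance ratio is p/q times the QTL-level one.
CASE_CONFIGS: dict[int, dict] = {}
for _cid, _q, _p, _h2, _blk in (
        (1, 200, 0, 0.34, None),
        (2, 1000, 0, 0.68, None),
        (3, 20, 200, 0.19, ((0, 10), (0, 100))),
        (4, 100, 500, 0.74, ((0, 50), (0, 250)))):
    _s2e = _resid_var(_q, 0.5, 1.0, _h2)
    _cfg = {
        "case": _cid, "n": 500, "q": _q, "p": _p, "freq": 0.5,
        "effect_sd": 1.0, "target_h2": _h2,
        "sigma2_e": _s2e, "lambda_true_qtl": _s2e,
    }
    if _blk is not None:
        _cfg["ld"] = {"qtl_block": _blk[0], "marker_block": _blk[1],
                      "beta_a": 0.5, "beta_b": 0.5}
        _cfg["lambda_true_marker"] = _s2e * _p / _q
    CASE_CONFIGS[_cid] = _cfg


def case_config(case_id: int) -> dict:
    """A copy of the preset configuration for one case study."""
    if case_id not in CASE_CONFIGS:
        raise ParameterError(f"unknown case_id {case_id!r}; expected 1-4")
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in CASE_CONFIGS[case_id].items()}
    return cfg


def case_study(case_id: int, seed=0, n: int | None = None) -> SimDataset:
    """Generate one realization of a preset case study.

    case 1: n=500, 200 known QTL, target realized h2 ~ 0.34
    case 2: n=500, 1000 known QTL (q > n, OLS inestimable), h2 ~ 0.68
    case 3: n=500, 20 unknown QTL + 200 markers, shared LD block over
            QTL 1-10 and markers 1-100, h2 ~ 0.19
    case 4: n=500, 100 unknown QTL + 500 markers, LD block over QTL 1-50
            and markers 1-250, h2 ~ 0.74
    """
    cfg = case_config(case_id)
    if n is not None:
        cfg["n"] = int(n)
    rng = _rng(seed)
    if "ld" in cfg:
        ld = cfg["ld"]
        spec = LdBlockSpec(n_qtl_total=cfg["q"], n_markers_total=cfg["p"],
                           qtl_ld_block=tuple(ld["qtl_block"]),
                           marker_ld_block=tuple(ld["marker_block"]),
                           beta_a=ld["beta_a"], beta_b=ld["beta_b"])
        Q, X = sample_ld_genotypes(cfg["n"], spec, seed=rng)
    else:
        Q = sample_binary_genotypes(cfg["n"], cfg["q"], cfg["freq"],
                                    seed=rng, prefix="q")
        X = None
    return make_phenotypes(Q, effect_sd=cfg["effect_sd"],
                           sigma2_e=cfg["sigma2_e"], seed=rng, X=X,
                           config=cfg)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------
def write_dataset(ds: SimDataset, outdir) -> None:
    """Write genotype/phenotype/effect TSVs plus a JSON config sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def _write_matrix(M: MarkerMatrix, path: Path):
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(M.locus_ids) + "\n")
            for i, row in enumerate(M.values):
                fh.write(M.ids[i] + "\t"
                         + "\t".join(f"{v:g}" for v in row) + "\n")

    _write_matrix(ds.Q, out / "qtl_genotypes.tsv")
    if ds.X is not None:
        _write_matrix(ds.X, out / "marker_genotypes.tsv")
    with open(out / "phenotypes.tsv", "w") as fh:
        fh.write("id\ty\tsignal\n")
        for i in range(ds.n):
            fh.write(f"{ds.Q.ids[i]}\t{ds.y[i]:.10g}\t{ds.signal[i]:.10g}\n")
    with open(out / "effects.tsv", "w") as fh:
        fh.write("locus\tbeta_true\n")
        for lid, b in zip(ds.Q.locus_ids, ds.beta_true):
            fh.write(f"{lid}\t{b:.10g}\n")
    sidecar = dict(ds.config)
    sidecar["h2_effective"] = ds.h2_effective
    sidecar["sigma2_e"] = ds.sigma2_e
    with open(out / "config.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
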