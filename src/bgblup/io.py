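"""Reading and writing the package's plain-text tabular formats.

Genotypes and phenotypes travel as TSV/CSV with a header row of locus
IDs and a leading individual-ID column; an optional ``plink_raw``
dialect strips the standard six leading metadata columns of a PLINK
``.raw`` export.  Missing genotypes are not supported: the data this
package targets are small dense matrices of inbred-line 0/1 codes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError
from .markers import MarkerMatrix

__all__ = ["read_genotypes", "write_genotypes", "read_phenotypes",
           "write_report"]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sep(path, dialect):
    if dialect == "csv" or (dialect == "auto"
                            and str(path).endswith(".csv")):
        return ","
    return "\t"


def read_genotypes(path, dialect: str = "auto") -> MarkerMatrix:
    """Parse a genotype table into a :class:`MarkerMatrix`.

    dialect: ``tsv`` | ``csv`` | ``plink_raw`` | ``auto`` (by extension).
    """
    if dialect not in ("tsv", "csv", "plink_raw", "auto"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "plink_raw" else _sep(path, dialect)
    if dialect == "plink_raw":
        sep = r"\s+"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as err:
        raise FormatError(f"{path}: cannot parse table: {err}") from err
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected an ID column plus loci")
    if dialect == "plink_raw":
        missing = [c for c in _PLINK_META if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: not a PLINK .raw file, missing {missing}")
        ids = df["IID"].tolist()
        df = df.drop(columns=_PLINK_META)
    else:
        ids = df.iloc[:, 0].tolist()
        df = df.iloc[:, 1:]
    dup = df.index[pd.Index(ids).duplicated()].tolist()
    if dup:
        names = sorted({ids[i] for i in dup})
        raise FormatError(f"{path}: duplicate individual IDs {names[:5]}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            # +2: header line plus 1-based counting
            raise FormatError(
                f"{path}: non-numeric genotype in column {col!r}, "
                f"line {int(bad[0]) + 2}") from None
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing genotypes are not supported")
    return MarkerMatrix(values, ids=ids, locus_ids=list(df.columns))


def write_genotypes(M: MarkerMatrix, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path, "w") as fh:
        fh.write("id" + sep + sep.join(M.locus_ids) + "\n")
        for i, row in enumerate(M.values):
            fh.write(M.ids[i] + sep
                     + sep.join(f"{v:g}" for v in row) + "\n")


def read_phenotypes(path, column: str = "y") -> tuple[list, np.ndarray]:
    """Read an (id, y, ...) table; returns (ids, values)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected id and value columns")
    col = column if column in df.columns else df.columns[1]
    ids = df.iloc[:, 0].astype(str).tolist()
    if pd.Index(ids).duplicated().any():
        raise FormatError(f"{path}: duplicate individual IDs")
    try:
        vals = pd.to_numeric(df[col], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as err:
        raise FormatError(f"{path}: non-numeric phenotype: {err}") from None
    return ids, vals


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report, outdir) -> dict:
    """Write a CvReport as TSV tables + JSON summary + log.

    Outputs ``metrics.tsv`` (per repeat x lambda x method),
    ``summary.json`` (medians/ranges, config echo, seeds, config hash),
    optionally ``reliability.tsv``, and a plain-text ``run.log``.
    Returns the summary dict.
    """
    if report.table.empty:
        raise ParameterError("refusing to write an empty report")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(out / "metrics.tsv", sep="\t", index=False,
                        float_format="%.10g")
    if report.reliability_table is not None:
        report.reliability_table.to_csv(out / "reliability.tsv", sep="\t",
                                        index=False, float_format="%.10g")
    summary_df = report.summary()
    summary = {
        "config": report.config,
        "config_hash": _config_hash(report.config),
        "summary": summary_df.to_dict(orient="records"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write(f"config_hash {summary['config_hash']}\n")
        for _, row in report.table.iterrows():
            fh.write("repeat={repeat} lam={lam:g} method={method} "
                     "pred_corr={pred_corr:.6g} pred_mse={pred_mse:.6g} "
                     "pred_mad={pred_mad:.6g}\n".format(**row))
    return summary
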