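"""Genotype matrix container with explicit centering metadata.

Genotypes are held as an ``n x p`` numeric array (individuals by loci).
For inbred lines the codes are binary (0/1, presence/absence of an
allele); the container is agnostic about the coding.  Column centering
— subtracting each locus mean — is the only transformation applied
anywhere in the package, and it is recorded on the object so that it is
(a) idempotent and (b) reproducible on new individuals at prediction
time.
"""

from __future__ import annotations

import numpy as np

from .exceptions import AlignmentError, ParameterError


class MarkerMatrix:
    """Individuals-by-loci genotype codes plus labels and centering state.

    Parameters
    ----------
    values : array_like, shape (n, p)
        Numeric genotype codes.
    ids : sequence of str, optional
        Individual labels; defaults to ``"id_0001" ...``.
    locus_ids : sequence of str, optional
        Locus labels; defaults to ``"m0001" ...``.
    centered : bool
        Whether ``values`` are already column-centered.
    column_means : array_like, shape (p,), optional
        The means subtracted when centering (required if ``centered``).
    """

    def __init__(self, values, ids=None, locus_ids=None, centered=False,
                 column_means=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ParameterError("genotype values must be a 2-d array")
        n, p = values.shape
        if n < 1 or p < 1:
            raise ParameterError("genotype matrix must be non-empty")
        if ids is None:
            ids = [f"id_{i + 1:04d}" for i in range(n)]
        if locus_ids is None:
            locus_ids = [f"m{j + 1:04d}" for j in range(p)]
        ids = list(map(str, ids))
        locus_ids = list(map(str, locus_ids))
        if len(ids) != n:
            raise AlignmentError(f"{len(ids)} ids for {n} rows")
        if len(locus_ids) != p:
            raise AlignmentError(f"{len(locus_ids)} locus ids for {p} columns")
        if len(set(ids)) != n:
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate individual ids: {dup[:5]}")
        if centered and column_means is None:
            raise ParameterError("centered matrix requires column_means")
        self.values = values
        self.ids = ids
        self.locus_ids = locus_ids
        self.centered = bool(centered)
        self.column_means = (None if column_means is None
                             else np.asarray(column_means, dtype=float))

    # -- basic shape ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self):
        return self.values.shape

    def __repr__(self):  # pragma: no cover - cosmetic
        state = "centered" if self.centered else "raw"
        return f"MarkerMatrix({self.n} x {self.p}, {state})"

    # -- centering ------------------------------------------------------
    def center(self) -> "MarkerMatrix":
        """Return a column-centered copy; centering twice is a no-op."""
        if self.centered:
            return self
        mu = self.values.mean(axis=0)
        return MarkerMatrix(self.values - mu, ids=self.ids,
                            locus_ids=self.locus_ids, centered=True,
                            column_means=mu)

    def center_like(self, other: "MarkerMatrix") -> "MarkerMatrix":
        """Center using the column means recorded on ``other``.

        Used at prediction time so that new individuals are deviated from
        the *training* locus means, not their own.
        """
        ref = other.center() if not other.centered else other
        if ref.p != self.p:
            raise AlignmentError(
                f"cannot center {self.p} loci with means for {ref.p}")
        if self.centered:
            return self
        return MarkerMatrix(self.values - ref.column_means, ids=self.ids,
                            locus_ids=self.locus_ids, centered=True,
                            column_means=ref.column_means)


def as_marker_matrix(X) -> MarkerMatrix:
    """Coerce an array or MarkerMatrix to a MarkerMatrix."""
    if isinstance(X, MarkerMatrix):
        return X
    return MarkerMatrix(np.asarray(X, dtype=float))
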