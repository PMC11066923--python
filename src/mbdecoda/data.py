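"""In-memory containers for count tables and model covariates.

The observed data are an ``n x K`` matrix of sequencing counts (samples by
taxa) together with per-sample covariates: the variable of interest ``X``,
a design ``U`` for the zero-inflation (logistic) part and a design ``V``
for the abundance (negative binomial) part.  Both designs carry a leading
intercept column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataValidationError(ValueError):
    """Raised when an input table or design violates its contract."""


@dataclass
class AbundanceTable:
    """An ``n x K`` matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        Array of shape ``(n, K)``: rows are samples, columns are taxa.
    sample_ids, taxon_ids
        Unique string labels for the two axes.
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    taxon_ids: list[str] = field(default_factory=list)
    #: single-taxon or heavily subset tables may legitimately contain samples
    #: with zero totals; full observed tables must not
    allow_empty_samples: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataValidationError("counts must be a 2-D samples x taxa array")
        n, K = self.counts.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if not self.taxon_ids:
            self.taxon_ids = [f"T{k + 1}" for k in range(K)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != n or len(self.taxon_ids) != K:
            raise DataValidationError("axis labels do not match counts shape")
        if len(set(self.sample_ids)) != n:
            raise DataValidationError("sample_ids are not unique")
        if len(set(self.taxon_ids)) != K:
            raise DataValidationError("taxon_ids are not unique")
        if not np.all(np.isfinite(self.counts)):
            raise DataValidationError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            i, k = np.argwhere(self.counts < 0)[0]
            raise DataValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[k]!r}"
            )
        if np.any(self.counts != np.floor(self.counts)):
            i, k = np.argwhere(self.counts != np.floor(self.counts))[0]
            raise DataValidationError(
                f"non-integer count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[k]!r} (use allow_real to round)"
            )
        self.counts = self.counts.astype(np.int64)
        if not self.allow_empty_samples and np.any(self.counts.sum(axis=1) <= 0):
            i = int(np.argmin(self.counts.sum(axis=1)))
            raise DataValidationError(
                f"sample {self.sample_ids[i]!r} has zero total count"
            )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def select_taxa(self, keep: np.ndarray) -> "AbundanceTable":
        """Return a new table restricted to the taxa selected by ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return AbundanceTable(
            counts=self.counts[:, keep],
            sample_ids=list(self.sample_ids),
            taxon_ids=[self.taxon_ids[k] for k in keep],
            allow_empty_samples=True,
        )

    def select_samples(self, keep: np.ndarray) -> "AbundanceTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return AbundanceTable(
            counts=self.counts[keep, :],
            sample_ids=[self.sample_ids[i] for i in keep],
            taxon_ids=list(self.taxon_ids),
            allow_empty_samples=self.allow_empty_samples,
        )


@dataclass
class CovariateSet:
    """Per-sample covariates: variable of interest and the two model designs.

    ``U`` (zero model) and ``V`` (abundance model) each include a leading
    all-ones intercept column.  ``X`` is binary 0/1 or continuous and must
    not be constant.
    """

    X: np.ndarray
    U: np.ndarray | None = None
    V: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).ravel()
        n = self.X.shape[0]
        if self.U is None:
            self.U = np.ones((n, 1))
        if self.V is None:
            self.V = np.ones((n, 1))
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        if self.U.shape[0] != n or self.V.shape[0] != n:
            raise DataValidationError("X, U and V must have the same number of rows")
        for name, M in (("U", self.U), ("V", self.V)):
            if not np.allclose(M[:, 0], 1.0):
                raise DataValidationError(f"{name} must have a leading intercept column")
        if np.ptp(self.X) == 0:
            raise DataValidationError("variable of interest X is constant")
        for j in range(1, self.V.shape[1]):
            if np.ptp(self.V[:, j]) == 0:
                raise DataValidationError(f"column {j} of V is constant")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def select_samples(self, keep: np.ndarray) -> "CovariateSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CovariateSet(X=self.X[keep], U=self.U[keep], V=self.V[keep])
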