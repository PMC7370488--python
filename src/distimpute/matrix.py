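"""Masked distance-matrix data model and its plain-text I/O.

A :class:`MaskedDistanceMatrix` is the central container of the package: a
square symmetric matrix of pairwise evolutionary distances (substitutions per
site, or arbitrary units for synthetic additive matrices) together with a
symmetric boolean mask marking pairs whose distance is unknown.  Every other
module either produces or consumes this type.

On disk the matrix is stored in a relaxed square PHYLIP-like dialect::

    4
    taxonA 0 0.1 NA 0.3
    taxonB 0.1 0 0.2 0.4
    taxonC NA 0.2 0 0.5
    taxonD 0.3 0.4 0.5 0

First line is the number of taxa N; each following line is a whitespace-free
label and N whitespace-separated values.  A configurable marker token
(default ``"NA"``) denotes a missing entry.  Values round-trip at full
precision.  Lower-triangular input is not accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = ["MaskedDistanceMatrix", "read_matrix", "write_matrix"]

#: default token marking a missing entry in matrix files
MISSING_MARKER = "NA"

_SYM_TOL = 1e-9


class MatrixFormatError(ValueError):
    """Raised for files or arrays that violate the matrix contract."""


@dataclass(frozen=True)
class MaskedDistanceMatrix:
    """Symmetric pairwise distance matrix with a missing-entry mask.

    Parameters
    ----------
    labels
        Ordered, unique, whitespace-free taxon names.
    values
        N x N float array.  Observed off-diagonal entries must be finite and
        non-negative; entries under the mask may hold hidden ground-truth
        values (used when scoring imputations) but are never written out.
    mask
        N x N boolean array, ``True`` = missing.  Must be symmetric with an
        all-``False`` diagonal: a taxon's self-distance is never missing.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise MatrixFormatError(
                f"values shape {values.shape} does not match {n} labels"
            )
        mask = self.mask
        if mask is None:
            mask = np.zeros((n, n), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n, n):
            raise MatrixFormatError("mask shape does not match values")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        self._validate()

    def _validate(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixFormatError("duplicate taxon labels")
        for lab in self.labels:
            if not lab or any(c.isspace() for c in lab):
                raise MatrixFormatError(f"label {lab!r} is empty or has whitespace")
        if self.mask.diagonal().any():
            raise MatrixFormatError("diagonal entries cannot be missing")
        if not np.array_equal(self.mask, self.mask.T):
            raise MatrixFormatError("mask is not symmetric")
        diag = self.values.diagonal()
        if not np.allclose(diag, 0.0, atol=_SYM_TOL):
            raise MatrixFormatError("diagonal of values must be zero")
        obs = ~self.mask
        vals = self.values[obs]
        if not np.all(np.isfinite(vals)):
            raise MatrixFormatError("observed entries must be finite")
        if np.any(vals < 0):
            raise MatrixFormatError("observed distances must be non-negative")
        asym = np.abs(self.values - self.values.T)
        if np.any(asym[obs & obs.T] > _SYM_TOL):
            raise MatrixFormatError("observed values are not symmetric")

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def missing_count(self) -> int:
        """Number of distinct missing unordered pairs m, 0 <= m <= N(N-1)/2."""
        c = int(self.mask.sum())
        assert c % 2 == 0
        return c // 2

    @property
    def observed_count(self) -> int:
        """Number of observed unordered off-diagonal pairs."""
        n = self.n_taxa
        return n * (n - 1) // 2 - self.missing_count

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    def observed_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield observed lower-triangular index pairs (i, j), i > j, row-major."""
        for i in range(1, self.n_taxa):
            for j in range(i):
                if not self.mask[i, j]:
                    yield i, j

    def missing_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield missing lower-triangular index pairs (i, j), i > j, row-major."""
        for i in range(1, self.n_taxa):
            for j in range(i):
                if self.mask[i, j]:
                    yield i, j

    def copy(self) -> "MaskedDistanceMatrix":
        return MaskedDistanceMatrix(self.labels, self.values.copy(), self.mask.copy())

    def with_mask(self, mask: np.ndarray) -> "MaskedDistanceMatrix":
        return MaskedDistanceMatrix(self.labels, self.values.copy(), mask)


# ----------------------------------------------------------------------
# I/O


def read_matrix(
    path: str | Path,
    missing_marker: str = MISSING_MARKER,
    symmetrize: bool = False,
) -> MaskedDistanceMatrix:
    """Read a square PHYLIP-like distance matrix with a missing-value marker.

    Parameters
    ----------
    path
        File whose first line is N followed by N rows ``label v1 ... vN``.
    missing_marker
        Token denoting a missing entry (compared case-sensitively).
    symmetrize
        If ``True``, repair asymmetric input: half-missing pairs become
        missing, numerically asymmetric observed pairs are averaged.  If
        ``False`` (default) such input is rejected.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty matrix file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: first line must be the taxon count") from exc
    if len(lines) - 1 != n:
        raise MatrixFormatError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    labels: list[str] = []
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != n + 1:
            raise MatrixFormatError(
                f"{path}: row {i + 1} has {len(parts) - 1} values, expected {n}"
            )
        labels.append(parts[0])
        for j, tok in enumerate(parts[1:]):
            if tok == missing_marker:
                if i == j:
                    raise MatrixFormatError(
                        f"{path}: missing marker on diagonal (row {i + 1})"
                    )
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError as exc:
                    raise MatrixFormatError(
                        f"{path}: unparseable value {tok!r} at row {i + 1}"
                    ) from exc
    if len(set(labels)) != n:
        raise MatrixFormatError(f"{path}: duplicate taxon labels")

    half_missing = mask != mask.T
    obs_both = ~mask & ~mask.T
    asym = np.abs(values - values.T) > _SYM_TOL
    if (half_missing.any() or (asym & obs_both).any()) and not symmetrize:
        raise MatrixFormatError(
            f"{path}: asymmetric matrix (pass symmetrize=True / --symmetrize to repair)"
        )
    if symmetrize:
        mask |= mask.T
        values = np.where(~mask, (values + values.T) / 2.0, values)
        np.fill_diagonal(values, 0.0)
    values[mask] = 0.0
    return MaskedDistanceMatrix(tuple(labels), values, mask)


def write_matrix(
    m: MaskedDistanceMatrix,
    path: str | Path,
    missing_marker: str = MISSING_MARKER,
) -> None:
    """Write a matrix in the square dialect read by :func:`read_matrix`.

    Observed values are emitted with ``repr`` precision (17 significant
    digits) so that a read/write round trip is exact; masked cells are
    emitted as the marker token, never their internal values.
    """
    lines = [str(m.n_taxa)]
    for i, lab in enumerate(m.labels):
        row = [
            missing_marker if m.mask[i, j] else format(m.values[i, j], ".17g")
            for j in range(m.n_taxa)
        ]
        lines.append(lab + " " + " ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
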