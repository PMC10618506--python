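"""Distance matrices: construction, normalization, and matrix-level comparison.

The pipeline compares methods at the matrix level: each encoding produces a
pairwise Euclidean distance matrix over sequence descriptors, each alignment
reference produces a Jukes-Cantor distance matrix, every matrix is min-max
normalized to [0, 1] over its off-diagonal entries, and matrices are then
compared to one another by the Euclidean norm of their (upper-triangle)
difference — the smaller the norm, the more similar the two methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .seqio import SeqIOError, SequenceSet

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-9


class MatrixError(ValueError):
    """Invalid distance matrix or incompatible matrix pair."""


@dataclass
class DistanceMatrix:
    """Labeled, symmetric, zero-diagonal matrix of pairwise dissimilarities."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __init__(self, labels, values):
        labels = tuple(labels)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise MatrixError(f"matrix must be square, got shape {values.shape}")
        if len(labels) != values.shape[0]:
            raise MatrixError(
                f"{len(labels)} labels for a {values.shape[0]}x{values.shape[1]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise MatrixError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(values)):
            raise MatrixError("non-finite entries in distance matrix")
        if np.any(values < -_SYM_TOL):
            raise MatrixError("negative entries in distance matrix")
        if np.max(np.abs(values - values.T), initial=0.0) > _SYM_TOL:
            raise MatrixError("matrix is not symmetric (tolerance 1e-9)")
        if np.max(np.abs(np.diag(values)), initial=0.0) > _SYM_TOL:
            raise MatrixError("matrix diagonal is not zero")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        np.clip(values, 0.0, None, out=values)
        self.labels = labels
        self.values = values

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels) -> "DistanceMatrix":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        labels = tuple(labels)
        if set(labels) != set(self.labels) or len(labels) != len(self.labels):
            raise MatrixError("reorder labels are not a permutation of matrix labels")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def offdiag(self) -> np.ndarray:
        """Strict-upper-triangle entries as a flat vector (each pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DistanceMatrix)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


def pairwise_euclidean(descriptors, labels) -> DistanceMatrix:
    """Euclidean distance between every pair of fixed-length descriptors.

    ``descriptors`` may be Descriptor objects (anything with ``.values``) or
    plain vectors; all must share one length.
    """
    vecs = [np.asarray(getattr(d, "values", d), dtype=float) for d in descriptors]
    labels = tuple(labels)
    if len(vecs) != len(labels):
        raise MatrixError(f"{len(vecs)} descriptors but {len(labels)} labels")
    lengths = {v.shape for v in vecs}
    if len(lengths) > 1:
        raise MatrixError(f"mixed descriptor lengths: {sorted(lengths)}")
    mat = squareform(pdist(np.vstack(vecs), metric="euclidean"))
    return DistanceMatrix(labels, mat)


def normalize_minmax(m: DistanceMatrix) -> DistanceMatrix:
    """Affine rescale of off-diagonal entries onto [0, 1].

    The minimum and maximum are taken over off-diagonal entries only, so a
    matrix whose smallest true distance exceeds zero is not distorted by its
    zero diagonal. The diagonal stays zero.
    """
    if m.n < 2:
        raise MatrixError("cannot normalize a matrix with fewer than 2 labels")
    off = m.offdiag()
    lo, hi = float(off.min()), float(off.max())
    if hi - lo <= 0:
        raise MatrixError(
            "degenerate matrix: all off-diagonal entries equal "
            f"({lo!r}); min-max normalization undefined"
        )
    out = (m.values - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(m.labels, out)


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) of a mismatch fraction."""
    if p < 0:
        raise MatrixError(f"mismatch fraction must be non-negative, got {p}")
    if p >= 0.75:
        raise MatrixError(f"JC saturation: mismatch fraction {p} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jukes_cantor_matrix(aln: SequenceSet) -> DistanceMatrix:
    """Jukes-Cantor distance matrix from a multiple sequence alignment.

    Sites where either sequence carries a gap or N are excluded pair by pair
    (pairwise deletion); the JC69 correction is applied to each pairwise
    mismatch fraction.
    """
    if not aln.aligned:
        raise SeqIOError("jukes_cantor_matrix requires an aligned SequenceSet")
    if len(aln) < 2:
        raise MatrixError("need at least 2 sequences for a distance matrix")
    codes = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
    arr = np.array(
        [[codes[c] for c in rec.seq] for rec in aln], dtype=np.int8
    )
    valid = arr < 4
    n = len(aln)
    out = np.zeros((n, n))
    ids = aln.ids
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise MatrixError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = float(np.count_nonzero(arr[i][both] != arr[j][both])) / m
            try:
                d = jc_distance(p)
            except MatrixError as exc:
                raise MatrixError(f"pair ({ids[i]!r}, {ids[j]!r}): {exc}") from exc
            out[i, j] = out[j, i] = d
    return DistanceMatrix(tuple(ids), out)


def matrix_euclidean(a: DistanceMatrix, b: DistanceMatrix, *, full: bool = False) -> float:
    """Euclidean norm of the entrywise difference of two distance matrices.

    ``b`` is reordered to ``a``'s label order first. By default each
    unordered pair is counted once (strict upper triangle); ``full=True``
    counts the whole matrix (both triangles and the zero diagonal).
    """
    if set(a.labels) != set(b.labels):
        missing_in_b = sorted(set(a.labels) - set(b.labels))
        missing_in_a = sorted(set(b.labels) - set(a.labels))
        raise MatrixError(
            f"label sets differ: only in first={missing_in_b}, only in second={missing_in_a}"
        )
    b = b.reorder(a.labels)
    if full:
        return float(np.linalg.norm(a.values - b.values))
    return float(np.linalg.norm(a.offdiag() - b.offdiag()))


# ---------------------------------------------------------------------------
# Matrix file I/O
# ---------------------------------------------------------------------------

def write_matrix_csv(m: DistanceMatrix, path: str | Path) -> None:
    """Write a labeled CSV (header row + first column carry the labels)."""
    m.to_dataframe().to_csv(path, float_format="%.17g")


def read_matrix_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise MatrixError(f"{path}: row and column labels disagree")
    try:
        return DistanceMatrix(tuple(labels), df.to_numpy(dtype=float))
    except MatrixError as exc:
        raise MatrixError(f"{path}: {exc}") from exc


def write_matrix_phylip(m: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix export."""
    with open(path, "w") as fh:
        fh.write(f"{m.n}\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "  " + "  ".join(f"{v:.10f}" for v in row) + "\n")
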