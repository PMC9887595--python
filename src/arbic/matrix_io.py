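"""Labeled expression matrices and bicluster result files.

Input follows the QUBIC/RecBic convention: a tab-delimited text file whose
first row holds condition names and whose subsequent rows hold a gene name
followed by numeric expression values.  Output is a plain-text "blocks" file
(one record per bicluster, genes and conditions listed by name) with an
optional machine-readable JSON twin.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "Bicluster",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "write_biclusters",
    "read_biclusters",
    "write_biclusters_json",
]


class MatrixFormatError(ValueError):
    """Raised when an expression-matrix file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """An m×n numeric matrix with unique gene and condition labels."""

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"matrix must be at least 2x2, got {m}x{n}")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match row count")
        if len(self.condition_ids) != n:
            raise ValueError("condition_ids length does not match column count")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids are not unique")
        if len(set(self.condition_ids)) != n:
            raise ValueError("condition_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Bicluster:
    """A bicluster: row/column index sets plus significance score.

    ``signs`` records, per row, whether the row follows the consensus trend
    order-preserved (+1) or order-reversed (−1).  ``consensus`` optionally
    keeps the ordered clique groups of column indices that define the
    consensus trend (used by the noise-tolerant extension).
    """

    rows: np.ndarray
    cols: np.ndarray
    score: float | None = None
    signs: np.ndarray | None = None
    consensus: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        if self.rows.size < 2 or self.cols.size < 2:
            raise ValueError("a bicluster needs at least 2 rows and 2 columns")
        if self.signs is None:
            self.signs = np.ones(self.rows.size, dtype=np.int64)
        else:
            self.signs = np.asarray(self.signs, dtype=np.int64)
            if self.signs.size != self.rows.size:
                raise ValueError("signs must align with rows")

    @property
    def n_rows(self) -> int:
        return int(self.rows.size)

    @property
    def n_cols(self) -> int:
        return int(self.cols.size)


def read_matrix(path, impute_median: bool = False) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix.

    The first row is a header of condition names; every following row starts
    with a gene name and continues with exactly n numeric fields.  Malformed
    files raise :class:`MatrixFormatError` naming the offending line.

    Missing cells (blank or "NA") are rejected by default because silently
    imputed values change within-row ranks, which drive everything
    downstream; with ``impute_median=True`` they are replaced by the row
    median instead.
    """
    genes: list[str] = []
    rows: list[np.ndarray] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixFormatError(f"{path}: empty file") from None
        conditions = [c.strip() for c in header[1:]]
        n = len(conditions)
        if n < 2:
            raise MatrixFormatError(
                f"{path}: line 1: header must name at least 2 conditions"
            )
        if len(set(conditions)) != n:
            raise MatrixFormatError(f"{path}: line 1: duplicate condition names")
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue  # skip blank lines
            if len(rec) != n + 1:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: expected {n + 1} fields, got {len(rec)}"
                )
            try:
                body = np.array(
                    [
                        float("nan")
                        if x.strip() in ("", "NA", "na", "NaN", "nan")
                        else float(x)
                        for x in rec[1:]
                    ]
                )
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: non-numeric expression value"
                ) from None
            bad = ~np.isfinite(body)
            if bad.any():
                if not impute_median or bad.all():
                    raise MatrixFormatError(
                        f"{path}: line {lineno}: missing/non-finite expression value"
                    )
                body[bad] = np.median(body[~bad])
            genes.append(rec[0].strip())
            rows.append(body)
    if len(rows) < 2:
        raise MatrixFormatError(f"{path}: fewer than 2 data rows")
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})[0]
        raise MatrixFormatError(f"{path}: duplicate gene id {dup!r}")
    return ExpressionMatrix(np.vstack(rows), genes, conditions)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the tab-delimited layout accepted by read_matrix."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.condition_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def _check_indices(bic: Bicluster, matrix: ExpressionMatrix) -> None:
    m, n = matrix.shape
    if bic.rows.min() < 0 or bic.rows.max() >= m:
        raise IndexError("bicluster row index out of range")
    if bic.cols.min() < 0 or bic.cols.max() >= n:
        raise IndexError("bicluster column index out of range")


def _ordered(biclusters: list[Bicluster]) -> list[Bicluster]:
    # descending score (unscored treated as -inf), ties by discovery order
    keyed = [
        (-(b.score if b.score is not None else float("-inf")), i)
        for i, b in enumerate(biclusters)
    ]
    return [biclusters[i] for _, i in sorted(keyed)]


def write_biclusters(
    biclusters: list[Bicluster], matrix: ExpressionMatrix, path
) -> None:
    """Write a QUBIC-style plain-text blocks file.

    One record per bicluster: rank, score, shape, then gene and condition
    names.  Records are ordered by descending score, ties by discovery order.
    """
    ordered = _ordered(biclusters)
    with open(path, "w") as fh:
        fh.write(f"# blocks: {len(ordered)}\n")
        for rank, b in enumerate(ordered, start=1):
            _check_indices(b, matrix)
            score = float("nan") if b.score is None else b.score
            fh.write(
                f"BC{rank:03d}\tscore={score:.4f}\tsize={b.n_rows}x{b.n_cols}\n"
            )
            fh.write(
                " genes: " + " ".join(matrix.gene_ids[i] for i in b.rows) + "\n"
            )
            fh.write(
                " conds: "
                + " ".join(matrix.condition_ids[j] for j in b.cols)
                + "\n"
            )


def read_biclusters(path, matrix: ExpressionMatrix) -> list[Bicluster]:
    """Parse a blocks file back into biclusters (indices via the matrix labels)."""
    gene_idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    cond_idx = {c: j for j, c in enumerate(matrix.condition_ids)}
    out: list[Bicluster] = []
    score = None
    rows = cols = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("BC"):
                score = float(line.split("score=")[1].split("\t")[0])
            elif line.startswith(" genes:"):
                rows = [gene_idx[g] for g in line.split(":", 1)[1].split()]
            elif line.startswith(" conds:"):
                cols = [cond_idx[c] for c in line.split(":", 1)[1].split()]
                out.append(Bicluster(np.array(rows), np.array(cols), score=score))
    return out


def write_biclusters_json(
    biclusters: list[Bicluster], matrix: ExpressionMatrix, path
) -> None:
    """Machine-readable twin of the blocks file (names and 0-based indices)."""
    recs = []
    for b in _ordered(biclusters):
        _check_indices(b, matrix)
        recs.append(
            {
                "score": None if b.score is None else float(b.score),
                "genes": [matrix.gene_ids[i] for i in b.rows],
                "conditions": [matrix.condition_ids[j] for j in b.cols],
                "rows": [int(i) for i in b.rows],
                "cols": [int(j) for j in b.cols],
            }
        )
    with open(path, "w") as fh:
        json.dump({"biclusters": recs}, fh, indent=1)
        fh.write("\n")
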