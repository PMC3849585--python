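"""Expression-matrix containers and file I/O.

The central container is :class:`ExpressionMatrix`: a probesets x samples
matrix of non-negative, natural-scale (anti-logged) normalized intensities
with unique row and column identifiers.  Row identifiers in ``.expression``
files concatenate the gene symbol and the probeset id (``ACTB_200801_x_at``);
:func:`split_row_identifier` recovers the two parts.

Three dialects are read and written:

``expression``
    Tab-separated; first column a unique row id (symbol + probeset id),
    optional non-numeric annotation columns, then one numeric column per
    sample.  Values must be non-negative.
``tsv``
    Generic TSV: first column row ids, every other column numeric.
``geo_series_matrix``
    GEO series-matrix format: metadata lines prefixed ``!``, the matrix
    delimited by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``.
    Series matrices are commonly deposited on log2 scale, so the reader takes
    an optional ``transform`` to anti-log (or log) the values on entry.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Trailing Affymetrix probeset id, e.g. ``200801_x_at``, ``1552257_a_at``,
#: ``AFFX-HUMISGF3A/M97935_at``.  Gene symbols only rarely contain
#: underscores, and probeset suffixes are regular, so splitting on the last
#: match is reliable.
_PROBESET_RE = re.compile(r"(?:AFFX-[^_]+|\d+)(?:_[a-z])?_at$")


class ExpressionFormatError(ValueError):
    """Structural problem with an expression file (duplicates, emptiness)."""


class ExpressionParseError(ValueError):
    """A cell failed to parse; the message names the offending coordinates."""


def split_row_identifier(row_id: str) -> tuple[str, str]:
    """Split a concatenated ``symbol_probesetid`` row identifier.

    Returns ``(probeset_id, gene_symbol)``.  If no trailing Affymetrix-style
    probeset id is found the whole identifier is treated as the probeset id
    and the symbol is empty.
    """
    m = _PROBESET_RE.search(row_id)
    if m is None:
        return row_id, ""
    start = m.start()
    if start == 0:
        return row_id, ""
    # drop the separating underscore
    return row_id[start:], row_id[: start - 1]


@dataclass
class ExpressionMatrix:
    """Probesets x samples matrix of non-negative natural-scale intensities.

    Parameters
    ----------
    probeset_ids
        Unique row identifiers.
    gene_symbols
        Per-row gene symbol; may be empty strings.
    values
        2-D float array, shape ``(len(probeset_ids), len(sample_ids))``,
        finite and >= 0.
    sample_ids
        Unique column identifiers.
    """

    probeset_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionFormatError("values must be a 2-D array")
        n_rows, n_cols = self.values.shape
        if n_rows != len(self.probeset_ids):
            raise ExpressionFormatError(
                f"{n_rows} rows but {len(self.probeset_ids)} probeset ids"
            )
        if n_cols != len(self.sample_ids):
            raise ExpressionFormatError(
                f"{n_cols} columns but {len(self.sample_ids)} sample ids"
            )
        if len(self.gene_symbols) != len(self.probeset_ids):
            raise ExpressionFormatError("gene_symbols length must match probeset_ids")
        if n_rows == 0 or n_cols == 0:
            raise ExpressionFormatError("empty expression matrix")
        if len(set(self.probeset_ids)) != n_rows:
            raise ExpressionFormatError("duplicate probeset ids")
        if len(set(self.sample_ids)) != n_cols:
            raise ExpressionFormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionParseError(
                f"non-finite value at row {self.probeset_ids[i]!r}, "
                f"column {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ExpressionParseError(
                f"negative value {self.values[i, j]} at row "
                f"{self.probeset_ids[i]!r}, column {self.sample_ids[j]!r}"
            )

    @property
    def n_probesets(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row_identifiers(self) -> list[str]:
        """Concatenated ``symbol_probesetid`` identifiers (symbol optional)."""
        return [
            f"{sym}_{pid}" if sym else pid
            for sym, pid in zip(self.gene_symbols, self.probeset_ids)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by probeset id."""
        return pd.DataFrame(self.values, index=self.probeset_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Standard per-sample annotation: series, cell class, chip, replicate."""

    sample_id: str
    series_id: str
    cell_class: str
    chip_description: str = ""
    replicate_no: int = 1

    def __post_init__(self) -> None:
        self.replicate_no = int(self.replicate_no)
        if self.replicate_no < 1:
            raise ValueError(f"replicate_no must be >= 1, got {self.replicate_no}")


def _apply_transform(values: np.ndarray, transform: str | None) -> np.ndarray:
    if transform is None:
        return values
    if transform == "antilog2":
        return np.exp2(values)
    if transform == "log2":
        if np.any(values <= 0):
            raise ExpressionParseError("log2 transform requires strictly positive values")
        return np.log2(values)
    raise ValueError(f"unknown transform {transform!r}")


def _parse_table(
    text_rows: list[list[str]], dialect: str, path: str
) -> tuple[list[str], list[str], np.ndarray]:
    header, *rows = text_rows
    if not rows:
        raise ExpressionFormatError(f"{path}: no data rows")
    row_ids = [r[0] for r in rows]
    # annotation columns (expression dialect): leading non-numeric columns
    # after the id column; the first column whose first-row cell parses as a
    # number starts the data block.
    n_cols = len(header)
    first_data_col = 1
    if dialect == "expression":
        for j in range(1, n_cols):
            try:
                float(rows[0][j])
            except (ValueError, IndexError):
                first_data_col = j + 1
            else:
                first_data_col = j
                break
        else:
            raise ExpressionFormatError(f"{path}: no numeric data columns")
    sample_ids = header[first_data_col:]
    if not sample_ids:
        raise ExpressionFormatError(f"{path}: no sample columns")
    values = np.empty((len(rows), len(sample_ids)), dtype=float)
    for i, r in enumerate(rows):
        if len(r) != n_cols:
            raise ExpressionFormatError(
                f"{path}: row {row_ids[i]!r} has {len(r)} fields, expected {n_cols}"
            )
        for j, cell in enumerate(r[first_data_col:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ExpressionParseError(
                    f"{path}: non-numeric value {cell!r} at row {row_ids[i]!r}, "
                    f"column {sample_ids[j]!r}"
                ) from None
    return row_ids, sample_ids, values


def read_expression_file(
    path, dialect: str = "expression", transform: str | None = None
) -> ExpressionMatrix:
    """Read an expression matrix.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``expression``, ``tsv`` or ``geo_series_matrix`` (see module docs).
    transform
        ``None`` (values used as-is, the default: correlations are computed
        on natural-scale values), ``antilog2`` for matrices deposited on log2
        scale, or ``log2``.
    """
    if dialect not in ("expression", "tsv", "geo_series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    if dialect == "geo_series_matrix":
        try:
            begin = next(
                i for i, l in enumerate(lines)
                if l.lower().startswith("!series_matrix_table_begin")
            )
            end = next(
                i for i, l in enumerate(lines)
                if l.lower().startswith("!series_matrix_table_end")
            )
        except StopIteration:
            raise ExpressionFormatError(
                f"{path}: missing series_matrix_table_begin/end markers"
            ) from None
        table_lines = lines[begin + 1 : end]
    else:
        table_lines = [l for l in lines if l.strip()]
    if not table_lines:
        raise ExpressionFormatError(f"{path}: empty matrix")
    rows = [l.rstrip("\n").split("\t") for l in table_lines]
    # GEO quotes identifiers
    if dialect == "geo_series_matrix":
        rows = [[cell.strip('"') for cell in r] for r in rows]
    row_ids, sample_ids, values = _parse_table(rows, dialect, str(path))
    values = _apply_transform(values, transform)

    probeset_ids, gene_symbols = [], []
    for rid in row_ids:
        pid, sym = split_row_identifier(rid)
        probeset_ids.append(pid)
        gene_symbols.append(sym)
    if len(set(probeset_ids)) != len(probeset_ids):
        # symbol/probeset splitting collided; fall back to raw row ids
        probeset_ids, gene_symbols = row_ids, [""] * len(row_ids)
    if len(set(probeset_ids)) != len(probeset_ids):
        raise ExpressionFormatError(f"{path}: duplicate row identifiers")
    return ExpressionMatrix(probeset_ids, gene_symbols, values, sample_ids)


#: Numeric precision of written expression files.  Six significant decimals
#: round-trip typical normalized intensities bit-stably through repr/float.
_VALUE_FORMAT = "%.6g"


def write_expression_file(matrix: ExpressionMatrix, path) -> None:
    """Write ``matrix`` in the ``.expression`` dialect (id column + samples).

    Values are formatted with 6 significant digits; a file written from a
    matrix previously read back is byte-stable at that precision.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("ID\t" + "\t".join(matrix.sample_ids) + "\n")
        for rid, row in zip(matrix.row_identifiers(), matrix.values):
            fh.write(rid + "\t" + "\t".join(_VALUE_FORMAT % v for v in row) + "\n")


def read_annotation_file(path) -> list[SampleAnnotation]:
    """Read a 5-column sample annotation TSV (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "series_id", "cell_class", "chip_description", "replicate_no"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ExpressionFormatError(f"{path}: missing annotation columns {missing}")
    return [
        SampleAnnotation(
            sample_id=r.sample_id,
            series_id=r.series_id,
            cell_class=r.cell_class,
            chip_description=r.chip_description if pd.notna(r.chip_description) else "",
            replicate_no=int(r.replicate_no),
        )
        for r in df.itertuples()
    ]


def write_annotation_file(annotations: list[SampleAnnotation], path) -> None:
    pd.DataFrame(
        [
            (a.sample_id, a.series_id, a.cell_class, a.chip_description, a.replicate_no)
            for a in annotations
        ],
        columns=["sample_id", "series_id", "cell_class", "chip_description", "replicate_no"],
    ).to_csv(path, sep="\t", index=False)


def _annotation_index(
    matrix: ExpressionMatrix, annotations: list[SampleAnnotation]
) -> dict[str, SampleAnnotation]:
    by_id = {a.sample_id: a for a in annotations}
    unannotated = [s for s in matrix.sample_ids if s not in by_id]
    if unannotated:
        raise ValueError(f"samples without annotation: {unannotated}")
    return by_id


def average_replicates(
    matrix: ExpressionMatrix, annotations: list[SampleAnnotation]
) -> ExpressionMatrix:
    """Collapse replicate columns to their arithmetic mean.

    Replicates are samples sharing ``(series_id, cell_class)``.  Output
    columns are ordered by first occurrence of each group and named
    ``series_id:cell_class``.  Averaging is done on the natural scale, the
    same scale on which correlations are computed.
    """
    by_id = _annotation_index(matrix, annotations)
    groups: dict[tuple[str, str], list[int]] = {}
    for j, sid in enumerate(matrix.sample_ids):
        a = by_id[sid]
        groups.setdefault((a.series_id, a.cell_class), []).append(j)
    new_ids = [f"{series}:{cls}" for series, cls in groups]
    new_values = np.column_stack(
        [matrix.values[:, cols].mean(axis=1) for cols in groups.values()]
    )
    return ExpressionMatrix(
        list(matrix.probeset_ids), list(matrix.gene_symbols), new_values, new_ids
    )


def flag_outlier_samples(
    matrix: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    min_median_r: float,
) -> list[str]:
    """Flag samples poorly correlated with others of the same cell class.

    A sample is flagged when its median Pearson correlation to the other
    samples of its ``cell_class`` falls below ``min_median_r``.  This is a
    deliberately simple surrogate for chip-level quality control: it catches
    arrays whose global expression profile differs inexplicably from
    supposedly similar cells.  Classes with a single sample are skipped with
    a warning (there is nothing to compare against).
    """
    by_id = _annotation_index(matrix, annotations)
    if min_median_r <= 0:
        return []
    classes: dict[str, list[int]] = {}
    for j, sid in enumerate(matrix.sample_ids):
        classes.setdefault(by_id[sid].cell_class, []).append(j)

    flagged: list[str] = []
    for cls in sorted(classes):
        cols = classes[cls]
        if len(cols) < 2:
            logger.warning(
                "cell class %r has a single sample %r; outlier check skipped",
                cls, matrix.sample_ids[cols[0]],
            )
            continue
        sub = matrix.values[:, cols]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        for local_i, j in enumerate(cols):
            others = np.delete(corr[local_i], local_i)
            med = np.nanmedian(others)
            if np.isnan(med) or med < min_median_r:
                flagged.append(matrix.sample_ids[j])
    return sorted(flagged, key=matrix.sample_ids.index)
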