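"""Delimited-text I/O and curation for genotype, phenotype and kinship tables.

Genotype files are plain delimited text (comma or tab, auto-detected): the
header row carries marker IDs, the first column carries line IDs, and cells
are allele dosages of the counted allele.  Two codings are accepted on input,
``dosage012`` ({0,1,2}) and ``symmetric101`` ({-1,0,1}); internally everything
is canonical dosage {0,1,2} so that the allele frequency of marker *k* is
simply half its mean dosage.  Missing cells (a configurable token, "NA" by
default, or an empty cell) are tracked in a boolean mask, removed by
:func:`curate` when too frequent, and otherwise filled in by
:func:`impute_population_mean`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenotypeFormatError",
    "GenotypeValidationError",
    "read_genotype_table",
    "read_phenotype_table",
    "curate",
    "impute_population_mean",
    "write_square_matrix",
    "read_square_matrix",
]


class GenotypeFormatError(ValueError):
    """A cell of a genotype file could not be parsed."""


class GenotypeValidationError(ValueError):
    """Structurally invalid genotype data (duplicate IDs, bad values, ...)."""


def _check_unique(ids: list[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise GenotypeValidationError(f"duplicate {what} IDs: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Bi-allelic dosage matrix (lines x markers) with provenance mask.

    ``values`` holds the dosage of the counted allele: integers in {0,1,2}
    before imputation, reals in [0,2] after mean imputation.  ``missing_mask``
    marks cells that were missing in the source file; imputation fills the
    values but keeps the mask for provenance.
    """

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GenotypeValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise GenotypeValidationError(
                f"ID lengths ({len(self.line_ids)}, {len(self.marker_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise GenotypeValidationError("missing_mask shape mismatch")
        observed = self.values[~self.missing_mask]
        if observed.size and (np.nanmin(observed) < 0 or np.nanmax(observed) > 2):
            raise GenotypeValidationError("observed dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        """True if no cell is currently unobserved (NaN)."""
        return bool(np.isfinite(self.values).all())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)


_CODINGS = {
    "dosage012": (np.array([0.0, 1.0, 2.0]), 0.0),
    "symmetric101": (np.array([-1.0, 0.0, 1.0]), 1.0),
}


def _detect_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_genotype_table(
    path: str, coding: str = "dosage012", missing_token: str = "NA"
) -> GenotypeMatrix:
    """Read a delimited genotype table into canonical {0,1,2} dosage coding.

    Parameters
    ----------
    path : str
        Delimited text file; header row = marker IDs, first column = line IDs.
    coding : {"dosage012", "symmetric101"}
        Declared coding of the cells.  ``symmetric101`` input is shifted by +1.
    missing_token : str
        Cell content marking a missing genotype; empty cells are always missing.
    """
    if coding not in _CODINGS:
        raise ValueError(f"unknown coding {coding!r}; use 'dosage012' or 'symmetric101'")
    allowed, shift = _CODINGS[coding]
    sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique([h.strip() for h in header], "marker")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    line_ids = [str(i) for i in df.index]
    marker_ids = [str(c).strip() for c in df.columns]
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(raw):
        cell = cell.strip() if isinstance(cell, str) else cell
        if cell == missing_token or cell == "":
            mask[i, j] = True
            values[i, j] = np.nan
            continue
        try:
            x = float(cell)
        except (TypeError, ValueError):
            raise GenotypeFormatError(
                f"unparseable cell {cell!r} at line {line_ids[i]!r}, "
                f"marker {marker_ids[j]!r}"
            ) from None
        if not np.any(np.abs(allowed - x) < 1e-9):
            raise GenotypeValidationError(
                f"value {x!r} at line {line_ids[i]!r}, marker {marker_ids[j]!r} "
                f"is outside the declared coding {coding!r}"
            )
        values[i, j] = x + shift
    return GenotypeMatrix(values, line_ids, marker_ids, mask)


def read_phenotype_table(path: str) -> pd.Series:
    """Read a two-column (line ID, value) phenotype table as a float Series."""
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={0: str})
    if df.shape[1] < 2:
        raise GenotypeFormatError(f"phenotype file {path!r} needs two columns")
    s = pd.Series(pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(),
                  index=[str(x) for x in df.iloc[:, 0]], name=str(df.columns[1]))
    _check_unique(list(s.index), "line")
    return s


def curate(
    G: GenotypeMatrix,
    max_marker_missing: float = 0.10,
    max_line_missing: float = 0.15,
) -> GenotypeMatrix:
    """Drop markers, then lines, with too much missing data.

    Markers with missing fraction strictly greater than ``max_marker_missing``
    are removed first; then lines whose missing fraction over the *surviving*
    markers strictly exceeds ``max_line_missing`` are removed.  Survivor order
    is preserved, and the pass is single-shot (no iteration), so the operation
    is idempotent.
    """
    mask = G.missing_mask
    marker_keep = mask.mean(axis=0) <= max_marker_missing
    if not marker_keep.any():
        raise GenotypeValidationError("curation removed every marker")
    mask2 = mask[:, marker_keep]
    line_keep = mask2.mean(axis=1) <= max_line_missing
    if not line_keep.any():
        raise GenotypeValidationError("curation removed every line")
    return GenotypeMatrix(
        G.values[np.ix_(line_keep, marker_keep)],
        [lid for lid, k in zip(G.line_ids, line_keep) if k],
        [mid for mid, k in zip(G.marker_ids, marker_keep) if k],
        mask[np.ix_(line_keep, marker_keep)],
    )


def impute_population_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing cell by its marker's mean observed dosage.

    The missing mask is preserved for provenance.  Each marker's mean dosage
    (hence its allele frequency) is unchanged by the imputation.
    """
    values = G.values.copy()
    values[G.missing_mask] = np.nan
    n_obs = (~G.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [mid for mid, n in zip(G.marker_ids, n_obs) if n == 0]
        raise GenotypeValidationError(
            f"markers with no observed genotypes (curate first): {bad[:5]}"
        )
    col_means = np.nansum(values, axis=0) / n_obs
    rows, cols = np.nonzero(G.missing_mask)
    values[rows, cols] = col_means[cols]
    return replace(G, values=values, missing_mask=G.missing_mask.copy())


def write_square_matrix(M: np.ndarray, ids: list[str], path: str) -> None:
    """Write a square matrix with IDs on both axes; round-trip lossless."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise GenotypeValidationError(f"matrix is not square: shape {M.shape}")
    if len(ids) != M.shape[0]:
        raise GenotypeValidationError(
            f"{len(ids)} IDs for a {M.shape[0]}x{M.shape[0]} matrix"
        )
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(M, index=ids, columns=ids).to_csv(path, sep=sep, float_format="%.17g")


def read_square_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    """Read a square delimited matrix written by :func:`write_square_matrix`."""
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise GenotypeValidationError(f"file {path!r} is not a square matrix")
    return M, [str(i) for i in df.index]
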