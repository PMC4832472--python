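"""Reading, writing, validation and binarization of single-cell genotype matrices.

The central data structure is :class:`GenotypeMatrix`: an ``n x m`` matrix
``D = (d_kl)`` of observed mutation calls, where ``k`` indexes single cells
and ``l`` indexes somatic variant sites.  Entries take values 0 (unmutated),
1 (mutated) or NA (no call, e.g. amplification failure at the locus).

Internally the matrix is always held cells-as-rows, matching the ``d_kl``
indexing of the model (cell first, site second).  On disk, both orientations
are supported; the common single-cell-SNV dialect puts sites as rows, which
is the default for both reading and writing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NA",
    "GenotypeMatrix",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "binarize",
]

#: Internal sentinel for a missing call.  The value matrix is int8; 0 and 1
#: are observed genotypes, -1 is NA.
NA: int = -1

#: Tokens accepted as NA on input.  The single-cell ecosystem uses both "NA"
#: and "3" for missing entries; empty fields and "?" are also tolerated.
NA_TOKENS = frozenset({"NA", "na", "", "?", "3"})

ORIENTATIONS = ("cells-as-rows", "sites-as-rows")


class GenotypeParseError(ValueError):
    """Raised when a genotype file contains entries outside {0, 1, NA}."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Observed binary genotypes of single cells at somatic variant sites.

    Parameters
    ----------
    cells : tuple of str
        Unique cell identifiers, one per row.
    sites : tuple of str
        Unique variant-site identifiers, one per column.
    values : numpy.ndarray
        ``(n_cells, n_sites)`` int8 array over {0, 1, -1}; -1 encodes NA.
    """

    cells: tuple[str, ...]
    sites: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        values.setflags(write=False)
        object.__setattr__(self, "cells", tuple(str(c) for c in self.cells))
        object.__setattr__(self, "sites", tuple(str(s) for s in self.sites))
        object.__setattr__(self, "values", values)
        self._validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == NA

    def _validate(self) -> None:
        n, m = len(self.cells), len(self.sites)
        if n < 1 or m < 1:
            raise ValueError("genotype matrix needs at least one cell and one site")
        if self.values.shape != (n, m):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n} cells x {m} sites"
            )
        if len(set(self.cells)) != n:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.sites)) != m:
            raise ValueError("duplicate site identifiers")
        bad = ~np.isin(self.values, (0, 1, NA))
        if bad.any():
            k, l = map(int, np.argwhere(bad)[0])
            raise GenotypeParseError(
                f"invalid genotype value {self.values[k, l]} at cell "
                f"{self.cells[k]!r}, site {self.sites[l]!r}"
            )
        all_na = (self.values == NA).all(axis=0)
        if all_na.any():
            names = [self.sites[j] for j in np.flatnonzero(all_na)]
            warnings.warn(
                f"{len(names)} site(s) have no observed entries (all NA): "
                f"{', '.join(names[:5])}{'...' if len(names) > 5 else ''}",
                UserWarning,
                stacklevel=3,
            )

    def to_frame(self) -> pd.DataFrame:
        """Cells-as-rows DataFrame with pandas NA for missing entries."""
        df = pd.DataFrame(self.values, index=list(self.cells), columns=list(self.sites))
        return df.astype("Int8").mask(df == NA)

    def subset_cells(self, cells: list[str]) -> "GenotypeMatrix":
        idx = [self.cells.index(c) for c in cells]
        return GenotypeMatrix(tuple(cells), self.sites, self.values[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.cells == other.cells
            and self.sites == other.sites
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.cells, self.sites, self.values.tobytes()))


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_token(token: object) -> int:
    text = "" if token is None else str(token).strip()
    if text in NA_TOKENS:
        return NA
    if text in ("0", "0.0"):
        return 0
    if text in ("1", "1.0"):
        return 1
    raise GenotypeParseError(text)


def read_genotypes(path: str | Path, orientation: str = "sites-as-rows") -> GenotypeMatrix:
    """Read a delimited genotype matrix.

    TSV or CSV is chosen by file extension (``.csv`` means comma, anything
    else tab).  The file must carry one header row and one leading identifier
    column; body entries must be 0, 1 or an NA token (``NA``/``na``/``?``/
    ``3``/empty).

    Parameters
    ----------
    path : str or Path
        File to read.
    orientation : {"sites-as-rows", "cells-as-rows"}
        How the file is laid out.  The returned matrix is always
        cells-as-rows.
    """
    path = Path(path)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False
    )
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=np.int8)
    for (i, j), token in np.ndenumerate(raw):
        try:
            values[i, j] = _parse_token(token)
        except GenotypeParseError:
            raise GenotypeParseError(
                f"invalid entry {str(token)!r} at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r} of {path}"
            ) from None
    if orientation == "sites-as-rows":
        return GenotypeMatrix(tuple(col_ids), tuple(row_ids), values.T)
    return GenotypeMatrix(tuple(row_ids), tuple(col_ids), values)


def write_genotypes(
    G: GenotypeMatrix, path: str | Path, orientation: str = "sites-as-rows"
) -> None:
    """Write a genotype matrix as delimited text; NA entries become ``"NA"``.

    ``read_genotypes(path, orientation)`` after ``write_genotypes(G, path,
    orientation)`` reproduces ``G`` exactly.
    """
    path = Path(path)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    text = np.where(G.values == NA, "NA", G.values.astype(str))
    df = pd.DataFrame(text, index=list(G.cells), columns=list(G.sites))
    if orientation == "sites-as-rows":
        df = df.T
    df.to_csv(path, sep=_sep_for(path))


_BINARIZE_MAP = {
    "hom-ref": 0,
    "het": 1,
    "hom-alt": 1,
    "0": 0,
    "1": 1,
    "2": 1,  # numeric genotype coding: 2 = homozygous alternate
}


def binarize(
    raw: pd.DataFrame | np.ndarray,
    cells: list[str] | None = None,
    sites: list[str] | None = None,
) -> GenotypeMatrix:
    """Collapse 4-state genotype calls to the binary mutated/unmutated alphabet.

    Homozygous reference maps to 0; heterozygous and homozygous alternate
    both map to 1 (a mutant allele is present either way); NA stays NA.
    Accepted codes per entry: ``hom-ref``/``het``/``hom-alt`` or the numeric
    coding 0/1/2, plus the usual NA tokens.

    ``raw`` is cells-as-rows; identifiers come from the DataFrame index and
    columns, or from ``cells``/``sites`` for a plain array.
    """
    if isinstance(raw, pd.DataFrame):
        cells = [str(c) for c in raw.index]
        sites = [str(s) for s in raw.columns]
        arr = raw.to_numpy()
    else:
        arr = np.asarray(raw)
        if cells is None:
            cells = [f"cell{i + 1}" for i in range(arr.shape[0])]
        if sites is None:
            sites = [f"site{j + 1}" for j in range(arr.shape[1])]
    values = np.empty(arr.shape, dtype=np.int8)
    for (i, j), token in np.ndenumerate(arr):
        text = "" if token is None else str(token).strip()
        if text in NA_TOKENS and text != "3":
            # "3" is reserved for hom-alt ambiguity safety: in 4-state input,
            # 3 is not a defined genotype code, so reject it rather than
            # silently treating it as missing.
            values[i, j] = NA
        elif text in _BINARIZE_MAP:
            values[i, j] = _BINARIZE_MAP[text]
        else:
            raise GenotypeParseError(
                f"unknown genotype code {text!r} at cell {cells[i]!r}, "
                f"site {sites[j]!r}"
            )
    return GenotypeMatrix(tuple(cells), tuple(sites), values)
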