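"""Labelled site-by-feature matrices.

Two thin containers hold the data every analysis in this package starts
from: a :class:`CountMatrix` of non-negative integer abundances
(sites x species, sites x clades, or sites x map cells) and a
:class:`PresenceMatrix` of binary occurrences (map cells x species).
Both validate their invariants on construction — unique labels, no
negative entries, no all-zero rows — so downstream model code can assume
clean input.

CSV layout is the field's convention: first column holds the row ids,
the header row holds the feature ids, cells are integers. Round-trips
are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "PresenceMatrix", "LabelledMatrix"]


def _as_id_list(ids: Sequence, n: int, prefix: str) -> list[str]:
    if ids is None:
        return [f"{prefix}{i}" for i in range(n)]
    out = [str(x) for x in ids]
    if len(out) != n:
        raise ValueError(f"expected {n} {prefix} ids, got {len(out)}")
    if len(set(out)) != len(out):
        dupes = sorted({x for x in out if out.count(x) > 1})
        raise ValueError(f"duplicate ids: {dupes[:10]}")
    return out


@dataclass
class LabelledMatrix:
    """Shared behaviour for labelled integer matrices."""

    values: np.ndarray
    row_ids: list[str] = field(default=None)  # type: ignore[assignment]
    col_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("matrix entries must be integers")
            arr = np.round(arr).astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise ValueError("matrix entries must be non-negative")
        self.values = arr
        self.row_ids = _as_id_list(self.row_ids, arr.shape[0], "row")
        self.col_ids = _as_id_list(self.col_ids, arr.shape[1], "col")
        zero_rows = np.flatnonzero(arr.sum(axis=1) == 0)
        if zero_rows.size:
            labels = [self.row_ids[i] for i in zero_rows[:10]]
            raise ValueError(f"all-zero rows not allowed: {labels}")
        self._validate()

    def _validate(self) -> None:  # overridden by subclasses
        pass

    # -- basic views -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def transpose(self) -> "LabelledMatrix":
        """Swap rows and features (the transposed-matrix analysis)."""
        return type(self)(self.values.T.copy(), list(self.col_ids), list(self.row_ids))

    # -- I/O ----------------------------------------------------------
    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep=sep)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None):
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelledMatrix):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and np.array_equal(self.values, other.values)
        )


class CountMatrix(LabelledMatrix):
    """Non-negative integer abundance matrix (rows on sites or cells)."""

    @property
    def row_totals(self) -> np.ndarray:
        """Per-row total counts (census effort per site)."""
        return self.values.sum(axis=1)


class PresenceMatrix(LabelledMatrix):
    """Binary presence-absence matrix; each row records at least one presence."""

    def _validate(self) -> None:
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"presence matrix must be binary; entry ({self.row_ids[r]}, "
                f"{self.col_ids[c]}) = {self.values[r, c]}"
            )
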