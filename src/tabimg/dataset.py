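"""In-memory container for numeric tables and delimited-text I/O.

A table holds M samples (rows) by N features (columns).  Columns are the
objects being laid out on an image grid, so feature names must be unique;
values must be finite (imputation of missing values is an upstream concern
and is deliberately not handled here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TabularDataset"]


@dataclass
class TabularDataset:
    """An M-by-N numeric matrix with sample identifiers and feature names.

    Parameters
    ----------
    values
        Real matrix of shape (M, N); rows are samples, columns features.
    sample_ids
        M unique-ish row labels (uniqueness is not enforced; they are
        carried through to image exports).
    feature_names
        N unique column labels.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 samples and 2 features, got {m}x{n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite; impute or drop missing data upstream")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(m)]
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.feature_names) != n:
            raise ValueError("feature_names length does not match number of columns")
        if len(set(self.feature_names)) != n:
            raise ValueError("feature names must be unique")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, indices: np.ndarray) -> "TabularDataset":
        """Return a new dataset keeping the given feature columns (in the given order)."""
        idx = np.asarray(indices, dtype=int)
        return TabularDataset(
            self.values[:, idx],
            sample_ids=list(self.sample_ids),
            feature_names=[self.feature_names[j] for j in idx],
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TabularDataset":
        return cls(
            df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_names,
        )

    @classmethod
    def read_csv(cls, path, sep: str | None = None, id_column: bool | None = None) -> "TabularDataset":
        """Read a delimited table (CSV/TSV, header row required).

        ``sep=None`` sniffs the delimiter.  ``id_column=None`` autodetects a
        leading sample-ID column: if the first column is non-numeric it is
        used as the row index.
        """
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        if df.shape[1] == 0:
            raise ValueError(f"no columns parsed from {path!r}")
        first = df.columns[0]
        use_id = id_column
        if use_id is None:
            use_id = not pd.api.types.is_numeric_dtype(df[first])
        if use_id:
            df = df.set_index(first)
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric data in table {path!r}: {exc}") from exc
        return cls(values, sample_ids=[str(i) for i in df.index],
                   feature_names=[str(c) for c in df.columns])

    def write_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep)
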