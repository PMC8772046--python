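"""Delimited-text readers and writers for expression matrices and labels.

Matrices are stored genes x samples: first row holds sample identifiers,
first column gene identifiers.  Both tab- and comma-separated dialects
are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

_DELIMS = {"tab": "\t", "comma": ","}


@dataclass
class ExpressionMatrix:
    """m x n real matrix of features x samples with identifiers."""

    values: NDArray[np.float64]
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D")
        m, n = self.values.shape
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise ValueError(
                f"identifier counts ({len(self.gene_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _resolve_delim(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _DELIMS:
            raise ValueError(f"dialect must be one of {sorted(_DELIMS)}, got {dialect!r}")
        return _DELIMS[dialect]
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, dialect: str | None = None,
                    impute_missing: bool = False) -> ExpressionMatrix:
    """Load a genes x samples matrix from delimited text.

    Non-numeric cells raise a parse error naming the offending gene and
    sample; missing values are rejected unless ``impute_missing`` fills
    them with the gene mean.  Duplicate gene ids are always an error.
    """
    path = Path(path)
    sep = _resolve_delim(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene ids in {path.name}: {dupes}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gi, sj = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[gi]!r}, sample {df.columns[sj]!r}: "
            f"{df.iat[gi, sj]!r}"
        )
    if numeric.isna().any().any():
        if not impute_missing:
            n_missing = int(numeric.isna().sum().sum())
            raise ValueError(
                f"{n_missing} missing values in {path.name}; "
                "enable impute_missing to fill with gene means"
            )
        numeric = numeric.apply(lambda row: row.fillna(row.mean()), axis=1)

    return ExpressionMatrix(
        values=numeric.values.astype(float),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def write_expression(X: ExpressionMatrix, path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _resolve_delim(path, dialect)
    X.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path) -> tuple[list[str], NDArray[np.int64]]:
    """Two-column delimited text: sample_id, label."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, label")
    ids = [str(s) for s in df.iloc[:, 0]]
    _, labels = np.unique(df.iloc[:, 1].astype(str), return_inverse=True)
    return ids, labels.astype(np.int64)


def write_labels(sample_ids, labels, path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_ranking(ranking, path) -> None:
    """Gene ranking as delimited text: gene_id, score, rank."""
    order = ranking.order
    pd.DataFrame(
        {
            "gene_id": [ranking.gene_ids[i] for i in order],
            "score": ranking.scores[order],
            "rank": np.arange(1, len(order) + 1),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_history(history: list[dict], path) -> None:
    pd.DataFrame(history).to_csv(path, sep=",", index=False, float_format="%.17g")
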