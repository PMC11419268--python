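"""Feature-by-sample data matrices and their on-disk text representation.

The canonical orientation throughout the package is *features in rows,
samples in columns* (the EWAS convention for methylation beta matrices: one
row per CpG probe, one column per individual). Estimators in
:mod:`paca.estimators` follow the scikit-learn convention instead
(samples in rows) and transpose internally.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("paca")

__all__ = ["DataMatrix", "read_matrix", "write_matrix", "align_features"]


def _find_duplicates(ids) -> list:
    return [name for name, count in Counter(ids).items() if count > 1]


@dataclass
class DataMatrix:
    """A validated real-valued feature-by-sample matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
        Finite 64-bit float values; beta values in [0, 1] are typical for
        DNA methylation but any real matrix is accepted.
    feature_ids : sequence of str
        Unique row identifiers (e.g. CpG probe ids).
    sample_ids : sequence of str
        Unique column identifiers (e.g. individual ids).
    """

    values: np.ndarray
    feature_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(
                f"values must be 2-dimensional, got shape {self.values.shape}"
            )
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValidationError(
                f"need at least 2 features and 2 samples, got {m} x {n}"
            )
        if len(self.feature_ids) != m:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {m} rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValidationError(f"duplicated {kind} id(s): {dups[:5]}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "non-finite value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        """Build from a features-in-rows DataFrame (index = feature ids)."""
        return cls(df.to_numpy(dtype=np.float64), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    def samples_by_features(self) -> pd.DataFrame:
        """The transposed (scikit-learn oriented) view used by estimators."""
        return pd.DataFrame(
            self.values.T, index=self.sample_ids, columns=self.feature_ids
        )


def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    stem = str(path)
    if stem.endswith(".gz"):
        stem = stem[:-3]
    return "," if stem.endswith(".csv") else "\t"


def _read_header_ids(path: str, sep: str) -> list:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline().rstrip("\r\n")
    if not first:
        raise ValidationError(f"empty file: {path}")
    return first.split(sep)[1:]


def read_matrix(path, sep: str | None = None, samples_in_rows: bool = False) -> DataMatrix:
    """Read a delimited text matrix (TSV default, CSV by extension, gzip ok).

    First column holds feature ids, the header row holds sample ids. With
    ``samples_in_rows=True`` the file is transposed after reading.
    """
    sep = _infer_sep(path, sep)
    header_ids = _read_header_ids(path, sep)
    dups = _find_duplicates(header_ids)
    if dups:
        raise ValidationError(f"duplicated column id(s) in {path}: {dups[:5]}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=np.float64,
                         compression="infer", float_precision="round_trip")
    except (ValueError, TypeError):
        # re-read untyped to locate and report the first offending cell
        df = pd.read_csv(path, sep=sep, index_col=0, compression="infer",
                         float_precision="round_trip")
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise ValidationError(
                    f"non-numeric value {df.at[row, col]!r} at feature "
                    f"{row!r}, sample {col!r} in {path}"
                ) from None
        df = df.astype(np.float64)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed (ragged?) table in {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty file: {path}") from exc
    if samples_in_rows:
        df = df.T
    dm = DataMatrix.from_dataframe(df)
    logger.info("read matrix %s: %d features x %d samples",
                path, dm.n_features, dm.n_samples)
    return dm


def write_matrix(matrix: DataMatrix, path, sep: str | None = None) -> None:
    """Write a :class:`DataMatrix` as delimited text (gzip by extension).

    Floats are written with full (shortest round-trip) precision, so a
    read-back reproduces the values exactly.
    """
    sep = _infer_sep(path, sep)
    matrix.to_dataframe().to_csv(path, sep=sep, compression="infer")


def align_features(x: DataMatrix, y: DataMatrix, policy: str = "intersect"):
    """Reorder two matrices to a common, lexicographically sorted feature list.

    policy="strict" demands identical feature sets; "intersect" keeps the
    (nonempty) intersection and logs what was dropped.
    """
    if policy not in ("intersect", "strict"):
        raise ValidationError(f"unknown alignment policy {policy!r}")
    fx, fy = set(x.feature_ids), set(y.feature_ids)
    if policy == "strict" and fx != fy:
        diff = sorted(fx.symmetric_difference(fy))
        raise ValidationError(
            f"feature sets differ under strict policy; {len(diff)} "
            f"mismatched id(s), e.g. {diff[:5]}"
        )
    common = sorted(fx & fy)
    if not common:
        raise ValidationError("feature sets have an empty intersection")
    dropped_x, dropped_y = len(fx) - len(common), len(fy) - len(common)
    if dropped_x or dropped_y:
        logger.warning("align_features dropped %d case and %d control features",
                       dropped_x, dropped_y)

    def _take(dm: DataMatrix) -> DataMatrix:
        pos = {f: i for i, f in enumerate(dm.feature_ids)}
        idx = [pos[f] for f in common]
        return DataMatrix(dm.values[idx, :], common, dm.sample_ids)

    return _take(x), _take(y)
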