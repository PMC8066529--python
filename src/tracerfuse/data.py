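"""Region-labelled bio-tracer tables: I/O, preprocessing, and PCA.

The central exchange object is :class:`BioTracerTable` — a samples × tracers
matrix of real-valued measurements (stable-isotope δ values, fatty-acid
percentages, ...) with one geographic-region label per sample. Preprocessing
follows standard chemometric practice for provenance work: fatty-acid weights
are converted to percent composition, rare fatty acids are filtered out, and
all tracers are centred and scaled (z-scored) before any inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "BioTracerTable",
    "PcaBasis",
    "read_table",
    "write_table",
    "fa_percent_composition",
    "prevalence_filter",
    "center_scale",
    "pca_fit",
    "pca_project",
]


@dataclass
class BioTracerTable:
    """A samples × tracers measurement matrix with a region label per sample.

    Parameters
    ----------
    values
        DataFrame of shape (n_samples, n_tracers); the index holds opaque
        sample identifiers, columns are tracer names.
    region
        Series of region labels aligned with ``values.index``.
    tracer_class
        Per-tracer tag, one of ``{"isotope", "fatty_acid", "other"}``.
    scaled
        Whether :func:`center_scale` has been applied.
    """

    values: pd.DataFrame
    region: pd.Series
    tracer_class: pd.Series = None
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.tracer_class is None:
            self.tracer_class = pd.Series("other", index=self.values.columns)
        self.region = pd.Series(self.region, index=self.values.index)
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(f"missing tracer values for samples {bad}")
        if self.region.isna().any():
            raise ValueError("every sample needs exactly one region label")
        if len(self.values) == 0:
            raise ValueError("table has no samples")

    # ---- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_tracers(self) -> int:
        return self.values.shape[1]

    @property
    def tracer_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def regions(self) -> list[str]:
        """Region labels in first-appearance order (the fixed class order)."""
        return list(dict.fromkeys(self.region))

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def region_counts(self) -> dict[str, int]:
        return {r: int((self.region == r).sum()) for r in self.regions}

    # ---- subsetting ----------------------------------------------------------
    def select_tracers(self, subset: Sequence[int] | Sequence[str]) -> "BioTracerTable":
        """Restrict to a tracer subset given by column indices or names."""
        names = self._subset_names(subset)
        return BioTracerTable(
            values=self.values[names].copy(),
            region=self.region.copy(),
            tracer_class=self.tracer_class[names].copy(),
            scaled=self.scaled,
        )

    def select_samples(self, idx: Sequence) -> "BioTracerTable":
        """Restrict to samples by positional indices."""
        idx = np.asarray(idx)
        return BioTracerTable(
            values=self.values.iloc[idx].copy(),
            region=self.region.iloc[idx].copy(),
            tracer_class=self.tracer_class.copy(),
            scaled=self.scaled,
        )

    def _subset_names(self, subset: Sequence[int] | Sequence[str] | None) -> list[str]:
        if subset is None:
            return self.tracer_names
        names = []
        for s in subset:
            if isinstance(s, (int, np.integer)):
                names.append(self.values.columns[s])
            else:
                if s not in self.values.columns:
                    raise KeyError(f"tracer {s!r} not in table")
                names.append(s)
        return names


@dataclass
class PcaBasis:
    """An orthonormal PCA rotation of the tracer space.

    ``component_loadings`` is (n_tracers × n_components) with orthonormal
    columns; ``explained_variance_fraction`` is non-increasing and sums to 1.
    """

    component_loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    mean: np.ndarray = field(default=None)
    tracer_names: list[str] = field(default=None)

    def __post_init__(self) -> None:
        L = self.component_loadings
        if not np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        f = self.explained_variance_fraction
        if not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise ValueError("explained variance fractions must sum to 1")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.component_loadings.shape[1])]
        return pd.DataFrame(self.component_loadings, index=self.tracer_names, columns=cols)


# ---- I/O --------------------------------------------------------------------


def read_table(
    path,
    region_column: str = "region",
    tracer_columns: Sequence[str] | None = None,
    id_column: str | None = None,
    tracer_class: dict | None = None,
    drop_incomplete: bool = False,
) -> BioTracerTable:
    """Load a region-labelled tracer table from CSV.

    The CSV must have a header row; ``region_column`` holds the region label.
    All other columns (or the explicit ``tracer_columns``) are parsed as
    numeric tracers. A non-numeric or blank tracer cell is fatal and reported
    with its row index, unless ``drop_incomplete`` is set, in which case
    incomplete rows are dropped and logged.
    """
    df = pd.read_csv(path)
    if region_column not in df.columns:
        raise ValueError(f"region column {region_column!r} not found in {path}")
    if id_column is not None and id_column in df.columns:
        df = df.set_index(id_column)
    if tracer_columns is None:
        tracer_columns = [c for c in df.columns if c != region_column]
    missing = [c for c in tracer_columns if c not in df.columns]
    if missing:
        raise ValueError(f"tracer columns {missing} not found in {path}")

    values = df[list(tracer_columns)].apply(pd.to_numeric, errors="coerce")
    bad_rows = values.index[values.isna().any(axis=1)]
    if len(bad_rows):
        if drop_incomplete:
            logger.warning("dropping %d incomplete rows: %s", len(bad_rows), list(bad_rows))
            values = values.drop(index=bad_rows)
            df = df.drop(index=bad_rows)
        else:
            raise ValueError(
                f"non-numeric or missing tracer value(s) in row(s) {list(bad_rows)}"
            )

    cls = pd.Series("other", index=list(tracer_columns))
    if tracer_class:
        for name, tag in tracer_class.items():
            if name in cls.index:
                cls[name] = tag
    table = BioTracerTable(values=values, region=df[region_column].astype(str), tracer_class=cls)
    logger.info(
        "loaded %d samples × %d tracers; per-region counts: %s",
        table.n_samples, table.n_tracers, table.region_counts(),
    )
    return table


def write_table(table: BioTracerTable, path, region_column: str = "region") -> None:
    """Round-trip writer: tracers plus the region column, CSV with header."""
    out = table.values.copy()
    out.insert(0, region_column, table.region.values)
    out.to_csv(path, index=False)


# ---- preprocessing ----------------------------------------------------------


def fa_percent_composition(weights: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Convert per-sample fatty-acid weights (μg/g) to percent composition.

    Each row is normalised to sum to 100. Rows must be non-negative with a
    strictly positive total.
    """
    arr = np.asarray(weights, dtype=float)
    if np.any(arr < 0):
        raise ValueError("fatty-acid weights must be non-negative")
    totals = arr.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if len(zero):
        raise ValueError(f"all-zero fatty-acid row(s) at index {zero.tolist()}")
    pct = 100.0 * arr / totals[:, None]
    if isinstance(weights, pd.DataFrame):
        return pd.DataFrame(pct, index=weights.index, columns=weights.columns)
    return pct


def prevalence_filter(
    percent_table: pd.DataFrame | np.ndarray,
    threshold_percent: float = 1.0,
    statistic: str = "mean",
) -> list:
    """Retain tracers whose typical percentage exceeds a threshold.

    A fatty acid is retained iff its ``statistic`` (mean by default; "min" and
    "any" are available) percentage across samples is strictly greater than
    ``threshold_percent``. Returns retained column names (or indices for a
    bare array), in input order.
    """
    if isinstance(percent_table, pd.DataFrame):
        cols = list(percent_table.columns)
        arr = percent_table.to_numpy(dtype=float)
    else:
        arr = np.asarray(percent_table, dtype=float)
        cols = list(range(arr.shape[1]))
    if statistic == "mean":
        stat = arr.mean(axis=0)
    elif statistic == "min":
        stat = arr.min(axis=0)
    elif statistic == "any":
        stat = arr.max(axis=0)
    else:
        raise ValueError(f"unknown prevalence statistic {statistic!r}")
    return [c for c, s in zip(cols, stat) if s > threshold_percent]


def center_scale(table: BioTracerTable) -> BioTracerTable:
    """Z-score each tracer column (mean 0, sample s.d. 1, n−1 denominator).

    Scaling is computed over all samples in the table. For a leakage-free
    protocol, scale the training table and apply its parameters to the test
    table yourself; the sweep engine's default mirrors whole-dataset scaling.
    """
    sd = table.values.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        raise ValueError(f"zero-variance tracer column(s): {dead}")
    z = (table.values - table.values.mean(axis=0)) / sd
    return replace(table, values=z, region=table.region.copy(), scaled=True)


# ---- PCA --------------------------------------------------------------------


def pca_fit(table: BioTracerTable) -> PcaBasis:
    """Fit a full-rank PCA rotation of the (scaled) tracer space."""
    pca = PCA(n_components=table.n_tracers)
    pca.fit(table.matrix)
    return PcaBasis(
        component_loadings=pca.components_.T,
        explained_variance_fraction=pca.explained_variance_ratio_,
        mean=pca.mean_,
        tracer_names=table.tracer_names,
    )


def pca_project(table: BioTracerTable, basis: PcaBasis, k: int | None = None) -> BioTracerTable:
    """Project a table onto the first ``k`` principal axes.

    The derived tracers are named ``PC1..PCk`` and tagged ``other``; they are
    mutually uncorrelated and ordered by explained variance.
    """
    d = basis.component_loadings.shape[1]
    if k is None:
        k = d
    if k > d or k < 1:
        raise ValueError(f"k={k} out of range for a {d}-component basis")
    centred = table.matrix - basis.mean
    scores = centred @ basis.component_loadings[:, :k]
    cols = [f"PC{i + 1}" for i in range(k)]
    values = pd.DataFrame(scores, index=table.values.index, columns=cols)
    return BioTracerTable(
        values=values,
        region=table.region.copy(),
        tracer_class=pd.Series("other", index=cols),
        scaled=table.scaled,
    )
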