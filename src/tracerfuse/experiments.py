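"""Train/test split experiments: combination, noise, PCA and sample-fusion sweeps.

The experimental protocol mirrors standard repeated-holdout evaluation for
provenance classifiers: stratified random splits (by default 20 training and
10 test samples per region), a classifier fitted on a tracer subset, and a
confusion matrix pooled over splits. Sweeps vary the subset size p (up to 500
subsets per p, all of them when fewer exist), the training noise level, the
number of leading PCA axes, the number of same-region test samples fused per
decision, and the training-set size.

Performance is the diagonal of the row-normalised confusion matrix; overall
performance is the unweighted mean of that diagonal (uniform prior over
regions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import classifiers
from .data import BioTracerTable, center_scale, pca_fit, pca_project

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "ConfusionSummary",
    "split",
    "fuse_posteriors",
    "evaluate_subset",
    "combination_sweep",
    "multi_sample_performance",
    "noise_sweep",
    "pca_sweep",
    "training_size_sweep",
    "DEFAULT_SIGMA_GRID",
]

#: log-spaced noise grid spanning the study range 1e-4 .. 10
DEFAULT_SIGMA_GRID = np.logspace(-4, 1, 9)


@dataclass
class SplitSpec:
    """Stratified holdout design: per-region train and test counts."""

    n_train_per_region: int = 20
    n_test_per_region: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_per_region < 1 or self.n_test_per_region < 1:
            raise ValueError("train and test counts must be ≥ 1")


@dataclass
class ConfusionSummary:
    """Row-normalised confusion matrix with per-region and overall performance."""

    matrix: np.ndarray
    class_labels: list[str]
    n_replicates: int
    n_failed: int = 0
    per_split_overall: np.ndarray | None = field(default=None, repr=False)

    @property
    def per_region_performance(self) -> dict[str, float]:
        return {r: float(self.matrix[i, i]) for i, r in enumerate(self.class_labels)}

    @property
    def overall_performance(self) -> float:
        return float(np.mean(np.diag(self.matrix)))

    @property
    def overall_se(self) -> float:
        """Standard error of the mean overall performance across splits."""
        s = self.per_split_overall
        if s is None or len(s) < 2:
            return float("nan")
        return float(np.std(s, ddof=1) / np.sqrt(len(s)))


def split(table: BioTracerTable, spec: SplitSpec) -> tuple[BioTracerTable, BioTracerTable]:
    """Stratified random train/test split, reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    return _split_with_rng(table, spec, rng)


def _split_with_rng(table, spec, rng):
    region_arr = table.region.to_numpy()
    train_idx, test_idx = [], []
    need = spec.n_train_per_region + spec.n_test_per_region
    for r in table.regions:
        pos = np.nonzero(region_arr == r)[0]
        if len(pos) < need:
            raise ValueError(
                f"region {r!r} has {len(pos)} samples; "
                f"{spec.n_train_per_region}+{spec.n_test_per_region} requested"
            )
        perm = rng.permutation(pos)
        train_idx.append(perm[: spec.n_train_per_region])
        test_idx.append(perm[spec.n_train_per_region : need])
    return (table.select_samples(np.concatenate(train_idx)),
            table.select_samples(np.concatenate(test_idx)))


def fuse_posteriors(posteriors: np.ndarray, rule: str = "product") -> np.ndarray:
    """Combine per-sample posteriors for k same-region samples into one.

    ``product`` sums log-posteriors (the independence product rule) and
    renormalises; ``vote`` returns the majority-argmax as a one-hot vector,
    ties broken by class order.
    """
    p = np.atleast_2d(np.asarray(posteriors, dtype=float))
    if rule == "product":
        logp = np.log(np.maximum(p, 1e-300)).sum(axis=0)
        logp -= logsumexp(logp)
        return np.exp(logp)
    if rule == "vote":
        votes = np.bincount(np.argmax(p, axis=1), minlength=p.shape[1])
        out = np.zeros(p.shape[1])
        out[np.argmax(votes)] = 1.0
        return out
    raise ValueError(f"unknown fusion rule {rule!r}")


# ---- the split-replication core ---------------------------------------------


def _run_splits(
    table: BioTracerTable,
    subset,
    method: str,
    n_splits: int,
    seed: int,
    split_spec: SplitSpec | None = None,
    fit_kwargs: dict | None = None,
    noise_sigma: float = 0.0,
    k_combine: int = 1,
    fusion_rule: str = "product",
) -> ConfusionSummary:
    spec = split_spec or SplitSpec()
    fit_kwargs = dict(fit_kwargs or {})
    if k_combine > spec.n_test_per_region:
        raise ValueError(
            f"k={k_combine} exceeds {spec.n_test_per_region} test samples per region"
        )
    rng = np.random.default_rng(seed)
    labels = table.regions
    r_index = {r: i for i, r in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    per_split = []
    n_failed = 0
    for _ in range(n_splits):
        train, test = _split_with_rng(table, spec, rng)
        if noise_sigma > 0:
            noisy = train.values + rng.normal(0.0, noise_sigma, size=train.values.shape)
            train = BioTracerTable(values=noisy, region=train.region.copy(),
                                   tracer_class=train.tracer_class.copy(),
                                   scaled=train.scaled)
        if method == "mlp" and "seed" not in fit_kwargs:
            fit_kwargs = {**fit_kwargs, "seed": int(rng.integers(2**31))}
        try:
            model = classifiers.fit(train, subset, method, **fit_kwargs)
            proba = model.predict_proba(test)
        except Exception as err:  # a failed split is skipped, not fatal
            logger.warning("split failed (%s); skipping", err)
            n_failed += 1
            continue
        model_order = [model.class_labels.index(r) for r in labels]
        proba = proba[:, model_order]
        split_counts = np.zeros_like(counts)
        test_regions = test.region.to_numpy()
        for r in labels:
            pos = np.nonzero(test_regions == r)[0]
            if k_combine > 1:
                pos = rng.permutation(pos)
                groups = [pos[i : i + k_combine]
                          for i in range(0, len(pos) - k_combine + 1, k_combine)]
            else:
                groups = [[i] for i in pos]
            for g in groups:
                fused = fuse_posteriors(proba[g], rule=fusion_rule)
                split_counts[r_index[r], int(np.argmax(fused))] += 1
        counts += split_counts
        row = split_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            per_split.append(np.nanmean(np.diag(split_counts / row)))
    if counts.sum() == 0:
        raise RuntimeError("every split failed; nothing to aggregate")
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return ConfusionSummary(matrix=matrix, class_labels=labels,
                            n_replicates=n_splits - n_failed, n_failed=n_failed,
                            per_split_overall=np.asarray(per_split))


def evaluate_subset(
    table: BioTracerTable,
    subset,
    method: str = "lda",
    n_splits: int = 200,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
    fit_kwargs: dict | None = None,
) -> ConfusionSummary:
    """Confusion summary for one tracer subset, pooled over random splits."""
    return _run_splits(table, subset, method, n_splits, seed,
                       split_spec=split_spec, fit_kwargs=fit_kwargs)


# ---- sweeps ------------------------------------------------------------------


def _sample_subsets(d: int, p: int, max_combos: int, rng: np.random.Generator):
    """All C(d,p) subsets if few enough, else a uniform draw without replacement."""
    total = math.comb(d, p)
    all_combos = list(combinations(range(d), p))
    if total <= max_combos:
        return all_combos
    idx = rng.permutation(total)[:max_combos]
    return [all_combos[i] for i in idx]


def _record(summary: ConfusionSummary, **meta) -> dict:
    rec = dict(meta)
    rec["overall"] = summary.overall_performance
    rec["overall_se"] = summary.overall_se
    for r, v in summary.per_region_performance.items():
        rec[f"perf_{r}"] = v
    rec["n_failed"] = summary.n_failed
    return rec


def combination_sweep(
    table: BioTracerTable,
    method: str = "lda",
    p_values=(1, 2, 3),
    max_combos: int = 500,
    n_splits: int = 200,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
    fit_kwargs: dict | None = None,
    noise_sigma: float = 0.0,
) -> pd.DataFrame:
    """Evaluate up to ``max_combos`` tracer subsets at every size p.

    Returns a tidy frame with one row per (p, subset): overall and per-region
    performance, its across-split standard error, and the subset members.
    """
    rng = np.random.default_rng(seed)
    d = table.n_tracers
    records = []
    for p in p_values:
        if p > d:
            raise ValueError(f"p={p} exceeds {d} tracers")
        for sub in _sample_subsets(d, p, max_combos, rng):
            summary = _run_splits(table, list(sub), method, n_splits,
                                  seed=int(rng.integers(2**31)),
                                  split_spec=split_spec, fit_kwargs=fit_kwargs,
                                  noise_sigma=noise_sigma)
            names = [table.tracer_names[j] for j in sub]
            records.append(_record(summary, method=method, p=p,
                                   subset=";".join(names),
                                   noise_sigma=noise_sigma, k_combined=1))
    return pd.DataFrame.from_records(records)


def multi_sample_performance(
    table: BioTracerTable,
    subset,
    method: str = "lda",
    k_values=(1, 2, 3),
    n_splits: int = 200,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
    fit_kwargs: dict | None = None,
    fusion_rule: str = "product",
) -> pd.DataFrame:
    """Performance when k same-region test samples are fused per decision.

    Fusion follows the independence product rule (sum of log-posteriors) by
    default; ``fusion_rule="vote"`` uses majority voting instead. ``k=1``
    reduces exactly to :func:`evaluate_subset`.
    """
    records = []
    names = table._subset_names(subset)
    for k in k_values:
        summary = _run_splits(table, subset, method, n_splits, seed,
                              split_spec=split_spec, fit_kwargs=fit_kwargs,
                              k_combine=int(k), fusion_rule=fusion_rule)
        records.append(_record(summary, method=method, p=len(names),
                               subset=";".join(names), noise_sigma=0.0,
                               k_combined=int(k)))
    return pd.DataFrame.from_records(records)


def noise_sweep(
    table: BioTracerTable,
    method: str = "lda",
    p_values=(1, 2, 3),
    sigma_grid=None,
    max_combos: int = 500,
    n_splits: int = 200,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Combination sweep with Gaussian noise injected into every training value.

    The test set is left untouched, so the sweep measures how tolerant each
    method is to corrupted reference data. The table should be scaled so sigma
    is interpretable (1 ≈ one within-region standard deviation).
    """
    grid = DEFAULT_SIGMA_GRID if sigma_grid is None else np.asarray(sigma_grid, float)
    frames = []
    for i, sigma in enumerate(grid):
        frames.append(combination_sweep(table, method, p_values, max_combos,
                                        n_splits, seed=seed + i,
                                        split_spec=split_spec,
                                        fit_kwargs=fit_kwargs,
                                        noise_sigma=float(sigma)))
    return pd.concat(frames, ignore_index=True)


def pca_sweep(
    table: BioTracerTable,
    method: str = "lda",
    k_values=(1, 2, 3),
    n_splits: int = 200,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Evaluate the first k principal-component axes as the tracer set.

    The rotation is fitted once on the full (scaled) table, matching a
    whole-dataset PCA ordering of uncorrelated axes by variance captured.
    """
    work = table if table.scaled else center_scale(table)
    basis = pca_fit(work)
    projected = pca_project(work, basis)
    records = []
    rng = np.random.default_rng(seed)
    for k in k_values:
        if k > projected.n_tracers:
            raise ValueError(f"k={k} exceeds {projected.n_tracers} components")
        summary = _run_splits(projected, list(range(k)), method, n_splits,
                              seed=int(rng.integers(2**31)),
                              split_spec=split_spec, fit_kwargs=fit_kwargs)
        records.append(_record(summary, method=method, p=int(k),
                               subset=";".join(projected.tracer_names[:k]),
                               noise_sigma=0.0, k_combined=1))
    return pd.DataFrame.from_records(records)


def training_size_sweep(
    table: BioTracerTable,
    subset,
    method: str = "lda",
    n_train_grid=(5, 10, 20),
    n_test_per_region: int = 10,
    n_splits: int = 200,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Performance as a function of per-region training-set size."""
    records = []
    names = table._subset_names(subset)
    rng = np.random.default_rng(seed)
    for n_train in n_train_grid:
        spec = SplitSpec(n_train_per_region=int(n_train),
                         n_test_per_region=n_test_per_region)
        summary = _run_splits(table, subset, method, n_splits,
                              seed=int(rng.integers(2**31)), split_spec=spec,
                              fit_kwargs=fit_kwargs)
        records.append(_record(summary, method=method, p=len(names),
                               subset=";".join(names), noise_sigma=0.0,
                               k_combined=1, n_train_per_region=int(n_train)))
    return pd.DataFrame.from_records(records)
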