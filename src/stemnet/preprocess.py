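"""Count filtering, TMM/log-CPM normalization and batch-effect removal.

The expression filter keeps genes with more than ``min_reads`` reads
(strictly greater) in at least ``min_samples`` samples.  Normalization
follows the trimmed-mean-of-M-values scheme: a reference sample is the one
whose upper-quartile count fraction is closest to the mean upper quartile,
per-sample scaling factors are precision-weighted doubly-trimmed means of
the gene-wise log-ratios (30% trim on M, 5% on A), normalized to geometric
mean one, and expression is log2(CPM + 1) on the effective library sizes.
Nuisance factors (year, block) are then estimated gene-wise by ordinary
least squares under sum-to-zero contrasts and subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import CountMatrix, ExpressionMatrix, SampleTable, ValidationError

__all__ = [
    "filter_low_expression",
    "tmm_factors",
    "normalize_counts",
    "BatchEstimate",
    "estimate_batch_effects",
]


def filter_low_expression(
    counts: CountMatrix, min_reads: int = 3, min_samples: int = 20
) -> CountMatrix:
    """Keep genes with count > ``min_reads`` in at least ``min_samples``
    samples.  The boundary is strict: a gene with exactly ``min_reads`` reads
    everywhere is removed."""
    if min_reads < 1 or min_samples < 1:
        raise ValueError("min_reads and min_samples must be positive integers")
    n_samples = counts.shape[1]
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {n_samples} available samples"
        )
    mask = (counts.counts.to_numpy() > min_reads).sum(axis=1) >= min_samples
    return CountMatrix(counts.counts.loc[mask])


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-sample trimmed-mean-of-M-values scaling factors (geometric mean 1)."""
    mat = counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero_lib = np.flatnonzero(lib == 0)
    if zero_lib.size:
        raise ValidationError(
            f"all-zero sample: {counts.sample_ids[zero_lib[0]]!r}"
        )
    frac = mat / lib[None, :]
    f75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, nr = mat[:, ref], lib[ref]

    factors = np.ones(mat.shape[1])
    for s in range(mat.shape[1]):
        y, n = mat[:, s], lib[s]
        keep = (y > 0) & (yr > 0)
        if not keep.any():
            continue
        p, pr = y[keep] / n, yr[keep] / nr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        # asymptotic (delta-method) variance of M; weights are its inverse
        v = (n - y[keep]) / (n * y[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        if np.max(np.abs(m)) < 1e-6:
            continue
        k = m.size
        lo_m = np.floor(k * logratio_trim) + 1
        hi_m = k + 1 - lo_m
        lo_a = np.floor(k * sum_trim) + 1
        hi_a = k + 1 - lo_a
        rm, ra = rankdata(m), rankdata(a)
        trimmed = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not trimmed.any():
            continue
        with np.errstate(divide="ignore"):
            w = 1.0 / v[trimmed]
        factors[s] = 2.0 ** (np.sum(m[trimmed] * w) / np.sum(w))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def normalize_counts(counts: CountMatrix, method: str = "tmm_log_cpm") -> ExpressionMatrix:
    """Normalize raw counts to log2(CPM + 1) on TMM-effective library sizes."""
    if method not in ("tmm_log_cpm", "log_cpm"):
        raise ValueError(f"unknown normalization method {method!r}")
    if counts.shape[1] < 2:
        raise ValidationError("normalization requires at least 2 samples")
    lib = counts.counts.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(f"all-zero sample: {counts.sample_ids[zero[0]]!r}")
    if method == "tmm_log_cpm":
        factors = tmm_factors(counts).to_numpy()
    else:
        factors = np.ones_like(lib)
    eff_lib = lib * factors
    cpm = counts.counts.to_numpy(dtype=float) / eff_lib[None, :] * 1e6
    values = pd.DataFrame(
        np.log2(cpm + 1.0), index=counts.counts.index, columns=counts.counts.columns
    )
    return ExpressionMatrix(values)


@dataclass
class BatchEstimate:
    """Per-gene sum-to-zero level coefficients for one nuisance factor."""

    factor: str
    coefficients: pd.DataFrame  # genes x levels; rows sum to zero
    global_magnitude: float  # root-mean-square coefficient across genes

    def level_effect(self, level: str) -> pd.Series:
        """The level's effect relative to the mean of the other levels.

        For a planted additive offset on exactly one level this contrast
        recovers the offset itself (the raw sum-to-zero coefficient recovers
        only (L-1)/L of it for L levels)."""
        others = [c for c in self.coefficients.columns if c != level]
        return self.coefficients[level] - self.coefficients[others].mean(axis=1)


def _sum_to_zero_design(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(values.astype(str).unique())
    codes = pd.Categorical(values.astype(str), categories=levels).codes
    k = len(levels)
    x = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        x[codes == j, j] = 1.0
        x[codes == k - 1, j] = -1.0
    return x, levels


def estimate_batch_effects(
    expr: ExpressionMatrix,
    samples: SampleTable,
    factors: tuple[str, ...] = ("year", "block"),
) -> tuple[list[BatchEstimate], ExpressionMatrix]:
    """Estimate and subtract additive nuisance-factor effects, gene-wise.

    Fits, for every gene, an ordinary-least-squares model of expression on
    the sum-to-zero-coded nuisance factors (jointly), leaving biological
    factors un-modeled.  Returns the per-factor coefficient tables and the
    adjusted expression matrix with the fitted batch terms removed.
    """
    meta = samples.table.loc[expr.sample_ids]
    blocks: list[tuple[str, np.ndarray, list[str]]] = []
    for factor in factors:
        if factor not in meta.columns:
            raise ValidationError(f"unknown design factor {factor!r}")
        col = meta[factor].astype(str)
        if col.nunique() < 2:
            raise ValidationError(f"factor {factor!r} has fewer than 2 levels")
        stage = meta["stage"].astype(str)
        for level in col.unique():
            in_level = col == level
            stages_here = set(stage[in_level])
            if len(stages_here) == 1 and set(stage[stage == next(iter(stages_here))].index) == set(col[in_level].index):
                warnings.warn(
                    f"factor {factor!r} level {level!r} is confounded with stage "
                    f"{next(iter(stages_here))!r}; estimation proceeds",
                    stacklevel=2,
                )
        x, levels = _sum_to_zero_design(col)
        blocks.append((factor, x, levels))

    design = np.column_stack(
        [np.ones(len(meta))] + [x for _, x, _ in blocks]
    )
    y = expr.values.to_numpy().T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)

    estimates: list[BatchEstimate] = []
    col0 = 1
    batch_fit = np.zeros_like(y)
    for factor, x, levels in blocks:
        k = len(levels)
        beta = coef[col0 : col0 + k - 1]  # (k-1) x genes
        full = np.vstack([beta, -beta.sum(axis=0, keepdims=True)])  # k x genes
        table = pd.DataFrame(full.T, index=expr.values.index, columns=levels)
        estimates.append(
            BatchEstimate(
                factor=factor,
                coefficients=table,
                global_magnitude=float(np.sqrt(np.mean(full**2))),
            )
        )
        batch_fit += x @ beta
        col0 += k - 1

    adjusted = ExpressionMatrix(
        pd.DataFrame(
            (y - batch_fit).T, index=expr.values.index, columns=expr.values.columns
        )
    )
    return estimates, adjusted
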