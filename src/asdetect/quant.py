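"""Counting, normalisation and differential expression for antisense units
and sense genes.

The differential-expression engine is a conditional exact test for
negative-binomial counts: replicate counts are summed per condition, and
the observed split of the pooled total between the two conditions is
compared with its null distribution given the total. With dispersion 0 the
null is exactly binomial with proportion equal to the library-size share;
with positive dispersion the null is the normalised product of two
negative-binomial masses. The two-sided p-value doubles the smaller tail
and is capped at 1. Fold changes use library-size-normalised condition
sums with a pseudocount so zero counts stay finite.

Thresholds follow the study design this package targets: an absolute fold
change of at least 2 and p < 0.05 call a feature up or down; gene-set
enrichment uses Benjamini–Hochberg adjusted p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from asdetect.core import ClassifiedRead

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Cut-offs used across the analysis.

    fc_threshold : minimum fold change (not log scale) to call up/down.
    p_threshold : p-value cut-off for the antisense/sense screens.
    enrichment_q : adjusted-p cut-off for over-representation terms.
    pseudocount : added to condition sums in the fold-change ratio.
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    enrichment_q: float = 0.05
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    log2fc: float
    pvalue: float
    qvalue: float
    status: str  # up | down | ns


@dataclass
class CountMatrix:
    """Feature-by-sample integer counts with per-sample condition labels."""

    counts: pd.DataFrame  # features x samples
    conditions: dict[str, str]  # sample_id -> condition label
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.reindex(self.counts.columns).astype(float)
            if self.lib_sizes.isna().any():
                raise ValueError("lib_sizes missing for some samples")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions[s] == condition]


def count_reads(
    features: Sequence,
    reads_by_sample: Mapping[str, Sequence[ClassifiedRead]],
    conditions: Mapping[str, str],
    min_overlap_frac: float = 0.5,
    lib_sizes: Mapping[str, float] | None = None,
) -> CountMatrix:
    """Count reads per feature and sample.

    A read increments a feature when it overlaps it by at least
    ``min_overlap_frac`` of the read length and its inferred transcript
    strand equals the feature strand. ``features`` may be transcript
    models or gene features (anything with chrom/start/end/strand and a
    ``feature_id`` or ``gene_id``).

    ``lib_sizes`` defaults to the per-sample total of reads supplied here;
    pass explicit totals (e.g. all mapped reads) to normalise against the
    full library.
    """
    from intervaltree import IntervalTree

    ids = [getattr(f, "feature_id", None) or getattr(f, "gene_id") for f in features]
    trees: dict[tuple[str, str], IntervalTree] = {}
    for f, fid in zip(features, ids):
        trees.setdefault((f.chrom, f.strand), IntervalTree()).addi(f.start, f.end, fid)

    samples = list(reads_by_sample)
    data: dict[str, dict[str, int]] = {s: dict.fromkeys(ids, 0) for s in samples}
    for sample, reads in reads_by_sample.items():
        col = data[sample]
        for r in reads:
            tree = trees.get((r.record.chrom, r.transcript_strand))
            if tree is None:
                continue
            min_bp = min_overlap_frac * r.record.length
            for iv in tree.overlap(r.record.start, r.record.end):
                overlap = min(r.record.end, iv.end) - max(r.record.start, iv.begin)
                if overlap >= min_bp:
                    col[iv.data] += 1
    mat = pd.DataFrame(data, dtype=int).reindex(index=ids, columns=samples)
    sizes = None
    if lib_sizes is not None:
        sizes = pd.Series({s: float(lib_sizes[s]) for s in samples})
    return CountMatrix(counts=mat, conditions=dict(conditions), lib_sizes=sizes)


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size x 1e6, per sample."""
    if (matrix.lib_sizes <= 0).any():
        bad = matrix.lib_sizes[matrix.lib_sizes <= 0].index.tolist()
        raise ValueError(f"zero library size for samples {bad}")
    return matrix.counts.div(matrix.lib_sizes, axis=1) * 1e6


def estimate_dispersion(
    matrix: CountMatrix,
    prior: float = 0.1,
    clip: bool = True,
) -> np.ndarray:
    """Per-feature method-of-moments negative-binomial dispersion.

    Counts are first rescaled to the mean library size so replicate
    variance is not inflated by depth differences. For each condition with
    at least two replicates the moment estimate (var - mean) / mean^2 is
    formed per feature and pooled across conditions with df weights.
    Features whose variance does not exceed the mean get dispersion 0
    (Poisson limit). With a single replicate everywhere, every feature is
    assigned ``prior`` and a warning is logged.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    scale = matrix.lib_sizes.mean() / matrix.lib_sizes.to_numpy()
    adj = counts * scale  # features x samples

    cond_of = matrix.conditions
    by_cond: dict[str, list[int]] = {}
    for j, s in enumerate(matrix.sample_ids):
        by_cond.setdefault(cond_of[s], []).append(j)

    num = np.zeros(counts.shape[0])
    den = 0.0
    for cols in by_cond.values():
        n = len(cols)
        if n < 2:
            continue
        sub = adj[:, cols]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(mean > 0, (var - mean) / np.square(mean), 0.0)
        num += (n - 1) * phi
        den += n - 1
    if den == 0:
        logger.warning(
            "no condition has >= 2 replicates; using prior dispersion %.3g", prior
        )
        return np.full(counts.shape[0], prior)
    phi = num / den
    return np.maximum(phi, 0.0) if clip else phi


def common_dispersion(matrix: CountMatrix, prior: float = 0.1) -> float:
    """One dispersion shared by all features: the mean of the unclipped
    per-feature moment estimates, floored at 0. Averaging before clipping
    avoids the upward bias that clipping noisy per-feature values at zero
    would introduce."""
    phi = estimate_dispersion(matrix, prior=prior, clip=False)
    return float(max(np.nanmean(phi), 0.0))


def moderated_dispersion(
    matrix: CountMatrix, prior_df: float = 10.0, prior: float = 0.1
) -> np.ndarray:
    """Per-feature dispersion shrunk toward the common value.

    Weighted average of the feature's own moment estimate (weight: its
    residual degrees of freedom) and the common dispersion (weight:
    ``prior_df``), floored at 0. With a handful of replicates the
    per-feature moments are far too noisy to use alone and the common
    value alone understates genuinely variable features; shrinkage is the
    standard compromise for count data.
    """
    phi_feature = estimate_dispersion(matrix, prior=prior, clip=False)
    phi_common = common_dispersion(matrix, prior=prior)
    by_cond: dict[str, int] = {}
    for s in matrix.sample_ids:
        by_cond[matrix.conditions[s]] = by_cond.get(matrix.conditions[s], 0) + 1
    resid_df = sum(max(n - 1, 0) for n in by_cond.values())
    phi = (prior_df * phi_common + resid_df * phi_feature) / (prior_df + resid_df)
    return np.maximum(phi, 0.0)


def nb_exact_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    lib_sizes: tuple[float, float] | None = None,
    dispersion: float = 0.0,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Exact conditional test of condition B vs condition A for one feature.

    Parameters
    ----------
    counts_a, counts_b
        Per-replicate counts in the reference (A) and contrast (B)
        condition.
    lib_sizes
        Summed library sizes ``(L_a, L_b)``; equal when omitted.
    dispersion
        Per-replicate NB dispersion (variance = mu + dispersion * mu^2).
        The replicate sum of r iid NB(m, phi) draws is NB(r*m, phi/r), so
        the dispersion applied to each condition sum is divided by that
        condition's replicate count. 0 gives the binomial split test.
    pseudocount
        Added to each normalised condition sum in the fold-change ratio.

    Returns
    -------
    (log2fc, pvalue)
        log2 fold change of B over A and the two-sided exact p-value
        (smaller tail doubled, capped at 1). Both condition sums zero
        gives (0.0, 1.0).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be nonnegative")
    if lib_sizes is None:
        la, lb = 1.0, 1.0
    else:
        la, lb = float(lib_sizes[0]), float(lib_sizes[1])
        if la <= 0 or lb <= 0:
            raise ValueError("library sizes must be positive")
    sum_a, sum_b = float(a.sum()), float(b.sum())
    total = int(round(sum_a + sum_b))
    log2fc = float(
        np.log2(((sum_b + pseudocount) / lb) / ((sum_a + pseudocount) / la))
    )
    if total == 0:
        return 0.0, 1.0

    frac_b = lb / (la + lb)
    k_obs = int(round(sum_b))
    if dispersion <= 0:
        lower = stats.binom.cdf(k_obs, total, frac_b)
        upper = stats.binom.sf(k_obs - 1, total, frac_b)
    else:
        phi_a = dispersion / max(len(a), 1)
        phi_b = dispersion / max(len(b), 1)
        mu_b = total * frac_b
        mu_a = total - mu_b
        k = np.arange(total + 1)
        ra, rb = 1.0 / phi_a, 1.0 / phi_b
        logw = stats.nbinom.logpmf(k, rb, rb / (rb + mu_b)) + stats.nbinom.logpmf(
            total - k, ra, ra / (ra + mu_a)
        )
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        lower = float(w[: k_obs + 1].sum())
        upper = float(w[k_obs:].sum())
    pvalue = float(min(1.0, 2.0 * min(lower, upper)))
    return log2fc, pvalue


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    log2fc: float, pvalue: float, thresholds: Thresholds | None = None
) -> str:
    """Call up / down / ns from a log2 fold change and p-value."""
    t = thresholds or Thresholds()
    cut = np.log2(t.fc_threshold)
    if pvalue < t.p_threshold:
        if log2fc >= cut:
            return "up"
        if log2fc <= -cut:
            return "down"
    return "ns"


def differential_expression(
    matrix: CountMatrix,
    condition_a: str,
    condition_b: str,
    thresholds: Thresholds | None = None,
    dispersion: float | str = "moderated",
) -> pd.DataFrame:
    """Per-feature exact-test differential expression of B vs A.

    ``dispersion`` is a float applied to all features, or an estimation
    mode: ``"moderated"`` (per-feature moments shrunk toward the common
    value — the default), ``"common"`` (one shared moment estimate) or
    ``"per-feature"`` (raw moments, very noisy at few replicates).
    Returns a DataFrame indexed by feature with columns log2fc, pvalue,
    qvalue and status. q-values are BH-adjusted across the features
    tested; the up/down screen applies the raw-p threshold.
    """
    t = thresholds or Thresholds()
    cols_a = matrix.samples_of(condition_a)
    cols_b = matrix.samples_of(condition_b)
    if not cols_a or not cols_b:
        raise ValueError(
            f"conditions {condition_a!r}/{condition_b!r} need >= 1 sample each"
        )
    la = float(matrix.lib_sizes[cols_a].sum())
    lb = float(matrix.lib_sizes[cols_b].sum())

    if isinstance(dispersion, str):
        if dispersion == "moderated":
            phi = moderated_dispersion(matrix)
        elif dispersion == "common":
            phi = np.full(len(matrix.feature_ids), common_dispersion(matrix))
        elif dispersion == "per-feature":
            phi = estimate_dispersion(matrix)
        else:
            raise ValueError(f"unknown dispersion mode {dispersion!r}")
    else:
        phi = np.full(len(matrix.feature_ids), float(dispersion))

    rows = []
    counts = matrix.counts
    for i, fid in enumerate(matrix.feature_ids):
        a = counts.loc[fid, cols_a].to_numpy()
        b = counts.loc[fid, cols_b].to_numpy()
        log2fc, p = nb_exact_test(a, b, (la, lb), phi[i], t.pseudocount)
        rows.append((fid, log2fc, p))
    df = pd.DataFrame(rows, columns=["feature_id", "log2fc", "pvalue"]).set_index(
        "feature_id"
    )
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["status"] = [
        classify_de(fc, p, t) for fc, p in zip(df["log2fc"], df["pvalue"])
    ]
    return df


def pearson_corr(expression: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between samples (columns) of an expression
    matrix; zero-variance samples yield NaN entries, which are flagged
    with a warning."""
    if expression.shape[0] < 2:
        raise ValueError("need >= 2 features for a correlation")
    corr = expression.corr(method="pearson")
    if corr.isna().any().any():
        logger.warning("zero-variance sample(s): undefined correlation entries")
    return corr


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_below: int = 10
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact when both samples have at most ``exact_below`` observations and
    no ties; otherwise the tie-corrected normal approximation with
    continuity correction. Degenerate input (all pooled values identical)
    returns 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= exact_below and y.size <= exact_below and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
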