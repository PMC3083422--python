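"""Per-mouse quantification and group statistics.

Covers the validation arm of the study: relative qPCR quantification by the
ΔΔCT method against a housekeeping reference and a sham calibrator group,
background-normalized densitometry, Ki67 positive-cell frequencies with a
distribution-free confidence interval for the median, whisker-box
summaries, one-way ANOVA with the Tukey HSD post-hoc test, and the
cross-platform (array vs qPCR) Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateDataError",
    "WhiskerSummary",
    "TukeyResult",
    "ddct_fold",
    "whisker_summary",
    "one_way_anova",
    "tukey_hsd",
    "densitometry_normalize",
    "ki67_frequency",
    "platform_correlation",
]

log = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Raised when inputs carry no usable variance/information."""


# ---------------------------------------------------------------------------
# ΔΔCT


def ddct_fold(
    qpcr: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Relative quantification by the ΔΔCT method.

    Technical duplicates are averaged per (mouse, gene); ΔCt is the target
    minus reference Ct per mouse; ΔΔCt subtracts the mean ΔCt over the
    calibrator (sham) mice; the fold change is 2^(−ΔΔCt), assuming an
    amplification efficiency of exactly 2.  Mice lacking a reference Ct are
    excluded and counted in the log.

    ``qpcr`` is long-format with columns mouse_id, group, gene and the
    duplicate columns ct_rep1, ct_rep2 (ct_rep2 may be missing/NaN).

    Returns one row per mouse: mouse_id, group, gene, dct, ddct, fold.
    """
    needed = {"mouse_id", "group", "gene"}
    if not needed.issubset(qpcr.columns):
        raise ValueError(f"qpcr table must have columns {sorted(needed)}")
    rep_cols = [c for c in qpcr.columns if c.startswith("ct_rep")]
    if not rep_cols:
        raise ValueError("qpcr table has no ct_rep* columns")
    ct = qpcr.assign(ct=qpcr[rep_cols].mean(axis=1, skipna=True))
    if calibrator_group not in set(ct["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from the table")

    target = ct.loc[ct["gene"] == target_gene, ["mouse_id", "group", "ct"]]
    reference = ct.loc[ct["gene"] == reference_gene, ["mouse_id", "ct"]].rename(
        columns={"ct": "ct_ref"}
    )
    if target.empty:
        raise ValueError(f"target gene {target_gene!r} absent from the table")
    merged = target.merge(reference, on="mouse_id", how="left")
    missing_ref = merged["ct_ref"].isna()
    if missing_ref.any():
        log.info("ddct_fold: excluded %d mice without reference-gene Ct", int(missing_ref.sum()))
        merged = merged.loc[~missing_ref]
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    calib = merged.loc[merged["group"] == calibrator_group, "dct"]
    if calib.empty:
        raise ValueError(f"no usable calibrator mice for {target_gene!r}")
    merged["ddct"] = merged["dct"] - calib.mean()
    merged["fold"] = 2.0 ** (-merged["ddct"])
    merged["gene"] = target_gene
    return merged[["mouse_id", "group", "gene", "dct", "ddct", "fold"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# whisker boxes


@dataclass(frozen=True)
class WhiskerSummary:
    """Tukey box-and-whisker summary (1.5×IQR whiskers)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))


def whisker_summary(values) -> WhiskerSummary:
    """Median, quartiles (linear interpolation), 1.5×IQR whiskers, outliers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateDataError("whisker_summary needs at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return WhiskerSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
    )


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def _validate_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate([a - a.mean() for a in arrays])
    if np.allclose(pooled, 0.0):
        raise DegenerateDataError("zero within-group variance")
    return arrays


def one_way_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p)."""
    arrays = _validate_groups(groups)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise comparisons at family-wise level alpha."""

    pairs: tuple[tuple[int, int], ...]       # all (i, j), i < j
    mean_diff: np.ndarray                     # mean_i - mean_j per pair
    significant: tuple[tuple[int, int], ...]  # subset with |q| > q_crit
    q_crit: float
    alpha: float


@lru_cache(maxsize=128)
def _q_crit(alpha: float, n_groups: int, dof: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, n_groups, dof))


def tukey_hsd(groups, alpha: float = 0.05) -> TukeyResult:
    """Tukey (Tukey–Kramer) HSD post-hoc test.

    A pair (i, j) is significant when |mean_i − mean_j| exceeds
    q_{1−alpha; k, ν} · sqrt(MSW/2 · (1/n_i + 1/n_j)), with MSW the pooled
    within-group mean square and ν its degrees of freedom.  The critical
    value of the studentized range is cached, so repeated calls (e.g. in
    simulations) cost only arithmetic.
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    ns = np.array([a.size for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    dof = int(ns.sum()) - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / dof
    qc = _q_crit(alpha, k, dof)

    pairs, diffs, sig = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            pairs.append((i, j))
            diffs.append(diff)
            if se > 0 and abs(diff) / se > qc:
                sig.append((i, j))
    return TukeyResult(pairs=tuple(pairs), mean_diff=np.array(diffs),
                       significant=tuple(sig), q_crit=qc, alpha=alpha)


# ---------------------------------------------------------------------------
# densitometry / Ki67


def densitometry_normalize(table: pd.DataFrame) -> pd.Series:
    """Subtract the slide-level mean background staining, flooring at 0.

    One slide per mouse: the mean of the ``background`` column within each
    ``mouse_id`` is subtracted from every ``density`` of that mouse.
    """
    for col in ("mouse_id", "density", "background"):
        if col not in table.columns:
            raise ValueError(f"densitometry table must have a {col!r} column")
    if table["background"].isna().any():
        raise ValueError("missing background values")
    bg = table.groupby("mouse_id")["background"].transform("mean")
    return (table["density"] - bg).clip(lower=0.0).rename("density_norm")


def _median_ci_order_statistic(values: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """Distribution-free CI for the median via binomial order statistics.

    Returns (low, high, achieved_coverage).  For very small n the nominal
    level may be unattainable; the widest interval (min, max) is then
    returned with its actual coverage.
    """
    x = np.sort(values)
    n = x.size
    alpha = 1.0 - conf
    # largest l with P(Binom(n, 1/2) <= l-1) <= alpha/2
    ls = np.arange(1, n // 2 + 1)
    cdf = stats.binom.cdf(ls - 1, n, 0.5)
    ok = ls[cdf <= alpha / 2.0]
    if ok.size == 0:
        coverage = 1.0 - 2.0 * stats.binom.cdf(0, n, 0.5)
        log.warning("median CI: nominal %.0f%% coverage unattainable with n=%d "
                    "(achieved %.1f%%)", conf * 100, n, coverage * 100)
        return float(x[0]), float(x[-1]), float(coverage)
    l = int(ok[-1])
    coverage = 1.0 - 2.0 * float(stats.binom.cdf(l - 1, n, 0.5))
    return float(x[l - 1]), float(x[n - l]), coverage


def ki67_frequency(positive, total, conf: float = 0.95) -> dict:
    """Positive-cell frequencies per scored area and a CI for their median.

    ``positive`` and ``total`` are per-area counts; the confidence interval
    of the median frequency across areas uses the distribution-free
    order-statistic (sign-test inversion) method.
    """
    positive = np.asarray(positive, dtype=float)
    total = np.asarray(total, dtype=float)
    if positive.shape != total.shape or positive.size == 0:
        raise ValueError("positive and total must be matching non-empty arrays")
    if np.any(total <= 0):
        raise ValueError("total counts must be > 0 in every area")
    if np.any(positive < 0) or np.any(positive > total):
        raise ValueError("positive counts must be in [0, total]")
    freq = positive / total
    low, high, coverage = _median_ci_order_statistic(freq, conf)
    return {
        "frequencies": freq,
        "median": float(np.median(freq)),
        "ci_low": low,
        "ci_high": high,
        "ci_coverage": coverage,
    }


# ---------------------------------------------------------------------------
# cross-platform correlation


def platform_correlation(array_log2fc, qpcr_log2fc) -> tuple[float, float]:
    """Pearson correlation between matched array and qPCR log2 fold changes."""
    x = np.asarray(array_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 matched pairs of equal length")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateDataError("zero variance in one platform's values")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
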