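"""Two-channel microarray pipeline: filtering, normalization, selection.

The pipeline consumes GenePix-like spot tables (foreground/background per
channel plus a status flag), removes unreliable spots, removes the
intensity-dependent dye bias by a global lowess fit of the log-ratio M
against the mean log-intensity A, aggregates replicates per condition, and
applies the modulated-gene selection rule: at least a 1.5-fold mean change
in at least two conditions, with replicate consistency confirmed by a
Student t-test at P < 0.05 (no multiple-testing correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .synthetic import StudyDesign

__all__ = [
    "FormatError",
    "NormalizationError",
    "ExpressionMatrix",
    "read_two_channel_tsv",
    "write_two_channel_tsv",
    "filter_spots",
    "lowess_normalize",
    "aggregate_conditions",
    "select_modulated",
    "export_heat_matrix",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["spot_id", "gene_id", "F_sample", "B_sample", "F_ref", "B_ref", "flag"]
NUMERIC_COLUMNS = ["F_sample", "B_sample", "F_ref", "B_ref", "flag"]


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


class NormalizationError(RuntimeError):
    """Raised when normalization preconditions are not met."""


# ---------------------------------------------------------------------------
# IO


def read_two_channel_tsv(path: str | Path) -> pd.DataFrame:
    """Read a GenePix-like spot table, reporting malformed rows by line.

    Expected tab-separated columns: spot_id, gene_id, F_sample, B_sample,
    F_ref, B_ref, flag.  Leading ``#`` comment lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if table.empty:
        log.warning("%s: empty data section", path)
        return table.astype({c: float for c in NUMERIC_COLUMNS})
    n_comment_before = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment_before += 1
            else:
                break
    for col in NUMERIC_COLUMNS:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: header line and 1-based numbering; plus leading comments
            line_no = row + 2 + n_comment_before
            raise FormatError(f"{path}: non-numeric value {table[col].iloc[row]!r} "
                              f"in column {col!r} at line {line_no}")
        table[col] = converted
    table["flag"] = table["flag"].astype(int)
    return table


def write_two_channel_tsv(array: pd.DataFrame, path: str | Path,
                          header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        array[REQUIRED_COLUMNS].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_spots(array: pd.DataFrame, low_signal_k: float = 2.0,
                 saturation_level: float = 65535.0) -> pd.Series:
    """Boolean retention mask excluding artifacts, saturated and dim spots.

    A spot is excluded iff its flag is negative (scanner-flagged artifact),
    either channel foreground reaches the saturation level, or both channel
    foregrounds fall below background + ``low_signal_k`` × background SD
    (SD taken per array and channel).
    """
    flagged = array["flag"] < 0
    saturated = (array["F_sample"] >= saturation_level) | (array["F_ref"] >= saturation_level)
    b_s_sd = float(array["B_sample"].std(ddof=1)) if len(array) > 1 else 0.0
    b_r_sd = float(array["B_ref"].std(ddof=1)) if len(array) > 1 else 0.0
    dim = (array["F_sample"] < array["B_sample"] + low_signal_k * b_s_sd) & (
        array["F_ref"] < array["B_ref"] + low_signal_k * b_r_sd
    )
    return ~(flagged | saturated | dim)


def lowess_normalize(array: pd.DataFrame, mask: pd.Series | None = None,
                     span: float = 0.3, iterations: int = 3) -> pd.Series:
    """Global lowess normalization of the log-ratio against intensity.

    M = log2(F_sample/F_ref) and A = ½·log2(F_sample·F_ref) are computed on
    retained spots; the lowess trend of M on A (fraction ``span``,
    ``iterations`` robustifying passes, fitted globally across the array) is
    subtracted.  Returns the normalized M′ indexed like ``array`` with NaN
    on excluded spots.
    """
    if mask is None:
        mask = pd.Series(True, index=array.index)
    retained = array.loc[mask.to_numpy()]
    if len(retained) < 50:
        raise NormalizationError(f"only {len(retained)} retained spots; >= 50 required")
    m = np.log2(retained["F_sample"].to_numpy() / retained["F_ref"].to_numpy())
    a = 0.5 * np.log2(retained["F_sample"].to_numpy() * retained["F_ref"].to_numpy())
    # delta collapses near-duplicate abscissae; pure speed optimization
    delta = 0.01 * (a.max() - a.min())
    fit = _sm_lowess(m, a, frac=span, it=iterations, delta=delta, return_sorted=False)
    out = pd.Series(np.nan, index=array.index, name="M_norm")
    out.loc[mask.to_numpy()] = m - fit
    return out


# ---------------------------------------------------------------------------
# aggregation


@dataclass(frozen=True)
class ExpressionMatrix:
    """Per-gene log2 ratios: replicate values and per-condition means.

    ``replicates`` has a gene index and a (condition, replicate) MultiIndex
    on columns; only genes observed in every replicate are retained.
    """

    replicates: pd.DataFrame
    conditions: tuple[str, ...]

    @property
    def means(self) -> pd.DataFrame:
        m = self.replicates.T.groupby(level=0).mean().T
        return m[list(self.conditions)]

    @property
    def genes(self) -> pd.Index:
        return self.replicates.index


def aggregate_conditions(
    normalized: Mapping[tuple[str, int], pd.Series],
    design: StudyDesign,
    gene_ids: Mapping[tuple[str, int], pd.Series],
) -> ExpressionMatrix:
    """Collapse normalized spot ratios to a gene × (condition, replicate) matrix.

    Duplicate spots of a gene within an array are averaged; genes missing
    (filtered out or absent) in any replicate are dropped from selection and
    counted in the log.
    """
    columns = {}
    for cond in design.condition_labels:
        for rep in range(1, design.replicates_per_condition + 1):
            key = (cond, rep)
            if key not in normalized:
                raise ValueError(f"missing normalized replicate {key}")
            per_gene = (
                pd.DataFrame({"gene_id": gene_ids[key].to_numpy(), "m": normalized[key].to_numpy()})
                .dropna()
                .groupby("gene_id")["m"]
                .mean()
            )
            columns[key] = per_gene
    table = pd.DataFrame(columns)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["condition", "replicate"])
    n_total = len(table)
    complete = table.dropna()
    dropped = n_total - len(complete)
    if dropped:
        log.info("aggregate_conditions: dropped %d/%d genes missing in >= 1 replicate",
                 dropped, n_total)
    return ExpressionMatrix(replicates=complete.sort_index(),
                            conditions=tuple(design.condition_labels))


# ---------------------------------------------------------------------------
# selection


def select_modulated(
    expr: ExpressionMatrix,
    fold_threshold: float = 1.5,
    min_conditions: int = 2,
    alpha: float = 0.05,
    t_mode: str = "pooled",
) -> pd.DataFrame:
    """Modulated-gene selection: fold-change gate plus replicate t-test.

    A gene is selected iff (a) |mean log2 ratio| >= log2(fold_threshold) in
    at least ``min_conditions`` conditions (up- and down-modulation both
    count) and (b) in each such passing condition a two-sided one-sample
    Student t-test of the replicate log2 ratios against 0 gives p < alpha.
    No multiple-testing correction is applied.

    ``t_mode`` selects the variance estimate of the t-test:

    * ``"pooled"`` (default) — the gene's replicate variance is pooled
      across all conditions (df = n_conditions × (replicates − 1)), i.e.
      replicate consistency is judged against the gene's overall technical
      scatter;
    * ``"per_condition"`` — each condition uses only its own replicates
      (df = replicates − 1).

    Genes with fewer than 2 replicate values in a passing condition cannot
    be tested; they are excluded and counted in the log.

    Returns a DataFrame indexed by gene with per-condition log2fc columns,
    per-condition p-values, and ``n_passing``.
    """
    if t_mode not in ("pooled", "per_condition"):
        raise ValueError(f"unknown t_mode {t_mode!r}")
    conds = list(expr.conditions)
    means = expr.means
    thr = np.log2(fold_threshold)
    passing = means.abs() >= thr
    n_passing = passing.sum(axis=1)

    reps = expr.replicates
    n_rep = {c: reps[c].shape[1] for c in conds}
    xbar = means.to_numpy()
    sd = np.column_stack([reps[c].std(axis=1, ddof=1).to_numpy() for c in conds])
    counts = np.array([n_rep[c] for c in conds], dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        if t_mode == "pooled":
            df_per = counts - 1.0
            pooled_var = (np.nan_to_num(sd, nan=0.0) ** 2 * df_per).sum(axis=1) / df_per.sum()
            se = np.sqrt(pooled_var)[:, None] / np.sqrt(counts)[None, :]
            dof = np.full_like(se, df_per.sum())
        else:
            se = sd / np.sqrt(counts)[None, :]
            dof = np.broadcast_to((counts - 1.0)[None, :], se.shape)
        tstat = xbar / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvals = pd.DataFrame(pvals, index=means.index, columns=conds)

    untestable = (np.array([n_rep[c] for c in conds]) < 2).any()
    candidates = n_passing >= min_conditions
    if untestable:
        log.info("select_modulated: %d candidate genes untestable (< 2 replicates), excluded",
                 int(candidates.sum()))
        selected = pd.Series(False, index=means.index)
    else:
        cond_ok = (~passing) | (pvals < alpha)
        bad_p = pvals.isna() & passing
        selected = candidates & cond_ok.all(axis=1) & ~bad_p.any(axis=1)

    out = means.copy()
    out.columns = [f"log2fc_{c}" for c in conds]
    for c in conds:
        out[f"p_{c}"] = pvals[c]
    out["n_passing"] = n_passing
    out = out.loc[selected].copy()
    out.index.name = "gene_id"
    return out.sort_index()


def export_heat_matrix(expr: ExpressionMatrix, dendrogram, clip: float = 3.0) -> pd.DataFrame:
    """Per-condition mean log2 ratios in dendrogram leaf order, clipped for display.

    Values are clipped to [-clip, +clip] (the display scale); the clustering
    itself always runs on unclipped values.
    """
    means = expr.means
    order = [dendrogram.labels[i] for i in dendrogram.leaf_order()]
    return means.loc[order].clip(lower=-clip, upper=clip)
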