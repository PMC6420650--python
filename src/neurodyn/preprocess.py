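"""Single-cell RNA-seq QC filtering, normalization and differential expression.

QC follows the study's five per-cell criteria with strict inequalities as
stated (genome mapping rate > 70%, mitochondrial fraction < 20%, mRNA
mapping rate > 80%, ERCC ratio < 10%, detected genes > 5000) plus an ERCC
spike-in correlation filter (Pearson r >= 0.9 against a leave-one-out mean
log profile). Differential expression is a two-sided rank-sum test on
log2(normalized + 1) with Benjamini-Hochberg adjustment, called significant
at adjusted p < 0.01 and fold change > 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from neurodyn.errors import ComputationError, SchemaError

logger = logging.getLogger(__name__)

ERCC_PREFIX = "ERCC-"

QC_METRICS = ["genome_map_rate", "mito_fraction", "mrna_map_rate", "ercc_ratio", "n_genes"]


@dataclass
class QCThresholds:
    """Per-cell QC cutoffs (all comparisons strict, as worded in the study)."""

    min_genome_map_rate: float = 0.70
    max_mito_fraction: float = 0.20
    min_mrna_map_rate: float = 0.80
    max_ercc_ratio: float = 0.10
    min_n_genes: int = 5000
    min_ercc_correlation: float = 0.9


def apply_qc_filters(qc: pd.DataFrame, th: QCThresholds | None = None) -> pd.DataFrame:
    """Evaluate the five metric criteria per cell.

    Returns a table (cell, passed, reasons) where ``reasons`` is a
    ';'-joined list of every violated criterion (empty for passing cells).
    """
    th = th or QCThresholds()
    missing = [c for c in QC_METRICS if c not in qc.columns]
    if missing:
        raise SchemaError(f"qc table missing columns: {', '.join(missing)}")
    cell_col = "cell" if "cell" in qc.columns else qc.columns[0]
    checks = {
        "genome_map_rate": qc["genome_map_rate"] > th.min_genome_map_rate,
        "mito_fraction": qc["mito_fraction"] < th.max_mito_fraction,
        "mrna_map_rate": qc["mrna_map_rate"] > th.min_mrna_map_rate,
        "ercc_ratio": qc["ercc_ratio"] < th.max_ercc_ratio,
        "n_genes": qc["n_genes"] > th.min_n_genes,
    }
    ok = pd.DataFrame(checks)
    reasons = ok.apply(lambda row: ";".join(c for c in QC_METRICS if not row[c]), axis=1)
    return pd.DataFrame(
        {"cell": qc[cell_col], "passed": ok.all(axis=1), "reasons": reasons}
    )


def ercc_correlation_filter(
    matrix: pd.DataFrame, r_min: float = 0.9, mode: str = "loo_mean"
) -> pd.DataFrame:
    """Flag cells whose ERCC spike-in profile deviates from the rest.

    For each cell, the Pearson correlation between its log2(count + 1) ERCC
    vector and a reference profile is computed; the cell passes iff
    r >= r_min. ``mode`` picks the reference: 'loo_mean' (default) uses the
    mean log profile of all other cells; 'pairwise_mean' uses the mean of
    pairwise correlations to all other cells.
    """
    ercc = matrix.loc[[g for g in matrix.index if str(g).startswith(ERCC_PREFIX)]]
    if ercc.shape[0] < 8:
        raise ComputationError(
            f"need >= 8 ERCC channels for the correlation filter, found {ercc.shape[0]}"
        )
    if ercc.shape[1] < 3:
        raise ComputationError("need >= 3 cells for the ERCC correlation filter")
    logx = np.log2(ercc.to_numpy(dtype=float) + 1.0)
    n = logx.shape[1]
    rows = []
    for j in range(n):
        v = logx[:, j]
        if np.ptp(v) == 0:
            rows.append((ercc.columns[j], np.nan, False, "degenerate"))
            continue
        others = np.delete(logx, j, axis=1)
        if mode == "loo_mean":
            ref = others.mean(axis=1)
            if np.ptp(ref) == 0:
                rows.append((ercc.columns[j], np.nan, False, "degenerate"))
                continue
            r = float(stats.pearsonr(v, ref)[0])
        elif mode == "pairwise_mean":
            rs = []
            for k in range(others.shape[1]):
                if np.ptp(others[:, k]) > 0:
                    rs.append(stats.pearsonr(v, others[:, k])[0])
            r = float(np.mean(rs)) if rs else np.nan
        else:
            raise ComputationError(f"unknown ERCC filter mode {mode!r}")
        rows.append((ercc.columns[j], r, bool(r >= r_min), ""))
    return pd.DataFrame(rows, columns=["cell", "r", "passed", "reasons"])


def _split_ercc(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    is_ercc = matrix.index.astype(str).str.startswith(ERCC_PREFIX)
    return matrix.loc[~is_ercc], matrix.loc[is_ercc]


def _check_lengths(matrix: pd.DataFrame, lengths: pd.Series) -> pd.Series:
    lengths = pd.Series(lengths)
    missing = matrix.index.difference(lengths.index)
    if len(missing):
        raise SchemaError(f"missing gene lengths for: {list(missing[:5])}")
    sub = lengths.loc[matrix.index]
    if (sub <= 0).any():
        raise SchemaError("gene lengths must be positive")
    return sub


def rpkm_normalize(matrix: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million: counts * 1e9 / (length * libsize).

    The per-cell library size is computed over endogenous (non-ERCC) genes
    only; ERCC rows, if present, are normalized with the same library size.
    """
    endo, _ = _split_ercc(matrix)
    libsize = endo.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ComputationError(f"zero library size for cells: {list(zero.index[:5])}")
    lens = _check_lengths(matrix, lengths)
    out = matrix.to_numpy(dtype=float) * 1e9
    out /= lens.to_numpy()[:, None]
    out /= libsize.to_numpy()[None, :]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def tpm_normalize(matrix: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; every cell's endogenous column sums to 1e6.

    Rates (counts/length) are renormalized over endogenous genes; ERCC rows
    are scaled with the same per-cell factor.
    """
    endo, _ = _split_ercc(matrix)
    lens = _check_lengths(matrix, lengths)
    rate = matrix.to_numpy(dtype=float) / lens.to_numpy()[:, None]
    endo_mask = ~matrix.index.astype(str).str.startswith(ERCC_PREFIX)
    denom = rate[endo_mask.to_numpy() if hasattr(endo_mask, "to_numpy") else endo_mask].sum(axis=0)
    zero = np.nonzero(denom == 0)[0]
    if len(zero):
        raise ComputationError(
            f"zero library size for cells: {list(matrix.columns[zero][:5])}"
        )
    return pd.DataFrame(
        rate / denom[None, :] * 1e6, index=matrix.index, columns=matrix.columns
    )


def differential_expression(
    matrix: pd.DataFrame,
    cells_a: list[str],
    cells_b: list[str],
    min_fc: float = 2.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided rank-sum differential expression between two cell groups.

    ``matrix`` is a normalized genes x cells layer. Genes expressed in
    neither group are excluded before testing. Fold change is computed on
    group means of the normalized values with pseudocount 1; significance
    requires BH-adjusted p < alpha and fold change > min_fc.
    """
    overlap = set(cells_a) & set(cells_b)
    if overlap:
        raise ComputationError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ComputationError("each group needs >= 3 cells")
    a = matrix[list(cells_a)].to_numpy(dtype=float)
    b = matrix[list(cells_b)].to_numpy(dtype=float)
    expressed = (a > 0).any(axis=1) | (b > 0).any(axis=1)
    if not expressed.any():
        logger.warning("no gene expressed in either group; empty DE result")
        return pd.DataFrame(
            columns=["gene", "log2fc", "statistic", "pvalue", "padj", "direction", "significant"]
        )
    genes = matrix.index[expressed]
    la = np.log2(a[expressed] + 1.0)
    lb = np.log2(b[expressed] + 1.0)
    stat, pval = stats.mannwhitneyu(la, lb, axis=1, alternative="two-sided", method="asymptotic")
    # constant genes give nan p under the normal approximation; they carry
    # no evidence, set p = 1
    pval = np.where(np.isnan(pval), 1.0, pval)
    log2fc = np.log2(a[expressed].mean(axis=1) + 1.0) - np.log2(b[expressed].mean(axis=1) + 1.0)
    padj = multipletests(pval, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "statistic": stat,
            "pvalue": pval,
            "padj": padj,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    )
    out["significant"] = (out["padj"] < alpha) & (np.abs(out["log2fc"]) > np.log2(min_fc))
    return out.reset_index(drop=True)


def stage_specific_genes(
    matrix: pd.DataFrame,
    stage_labels: pd.Series,
    alpha: float = 0.01,
    min_fc: float = 2.0,
) -> dict[str, set[str]]:
    """One-vs-rest DE per stage; specific = significant and up in the stage."""
    stage_labels = pd.Series(stage_labels)
    stages = list(dict.fromkeys(stage_labels))
    if len(stages) < 2:
        raise ComputationError("stage-specific genes need >= 2 stages")
    out: dict[str, set[str]] = {}
    for stage in stages:
        cells_in = stage_labels.index[stage_labels == stage].tolist()
        cells_out = stage_labels.index[stage_labels != stage].tolist()
        if len(cells_in) < 3:
            logger.warning("stage %s has < 3 cells, skipped", stage)
            continue
        de = differential_expression(matrix, cells_in, cells_out, min_fc=min_fc, alpha=alpha)
        out[stage] = set(de.loc[de["significant"] & (de["direction"] == "up"), "gene"])
    return out
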