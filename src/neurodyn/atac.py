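"""Stage-ordered ATAC peak-set algebra.

Peaks are rows of a DataFrame with columns ``chrom, start, end, name,
summit`` (0-based half-open; summit is an offset from ``start``). The
temporal-dynamics vocabulary follows the staged-differentiation design:

* novel       — overlaps no peak in the union of all earlier stages
                (first-stage peaks are all novel by definition);
* conserved   — the complement of novel within a stage;
* gained/lost — present/absent relative to the immediately preceding stage;
* stage-specific — overlaps no peak of any other stage.

Overlap means >= ``min_overlap`` shared base pairs (default 1) between
half-open intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from neurodyn.errors import ComputationError, ConfigError, SchemaError

logger = logging.getLogger(__name__)


def _check_peaks(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise SchemaError(f"peak table missing column {col}")
    if "name" not in df.columns:
        df = df.copy()
        df["name"] = [f"peak{i}" for i in range(len(df))]
    if "summit" not in df.columns:
        df = df.copy()
        df["summit"] = (df["end"] - df["start"]) // 2
    return df


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transitively merge possibly-overlapping intervals (sorted output)."""
    if len(starts) == 0:
        return starts, ends
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    keep_s = [s[0]]
    keep_e = [e[0]]
    for i in range(1, len(s)):
        if s[i] < keep_e[-1]:  # overlap (half-open, >=1 bp shared)
            keep_e[-1] = max(keep_e[-1], e[i])
        else:
            keep_s.append(s[i])
            keep_e.append(e[i])
    return np.array(keep_s), np.array(keep_e)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame, min_overlap: int = 1) -> np.ndarray:
    """Boolean mask: which query peaks share >= min_overlap bp with subject."""
    query = _check_peaks(query)
    subject = _check_peaks(subject)
    out = np.zeros(len(query), dtype=bool)
    for chrom, sub in subject.groupby("chrom"):
        ms, me = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        qmask = (query["chrom"] == chrom).to_numpy()
        if not qmask.any():
            continue
        qs = query.loc[qmask, "start"].to_numpy()
        qe = query.loc[qmask, "end"].to_numpy()
        # candidate merged intervals for [qs, qe) form the index range
        # [lo, hi): lo = first interval ending after qs, hi = first interval
        # starting at/after qe
        lo = np.searchsorted(me, qs, side="right")
        hi = np.searchsorted(ms, qe, side="left")
        if min_overlap == 1:
            hit = hi > lo
        else:
            hit = np.zeros(len(qs), dtype=bool)
            for i in range(len(qs)):
                sl = slice(lo[i], hi[i])
                if lo[i] < hi[i]:
                    ov = np.minimum(me[sl], qe[i]) - np.maximum(ms[sl], qs[i])
                    hit[i] = bool(np.any(ov >= min_overlap))
        out[qmask] = hit
    return out


def merge_peak_sets(sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of all peak intervals, transitively merged ('standard peak set')."""
    frames = [_check_peaks(s) for s in sets if len(s)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "summit"])
    allp = pd.concat(frames, ignore_index=True)
    rows = []
    for chrom in sorted(allp["chrom"].unique()):
        sub = allp[allp["chrom"] == chrom]
        ms, me = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        for s, e in zip(ms, me):
            rows.append((chrom, int(s), int(e)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["name"] = [f"merged_{i}" for i in range(len(out))]
    out["summit"] = (out["end"] - out["start"]) // 2
    return out


def reproducible_peaks(rep1: pd.DataFrame, rep2: pd.DataFrame, min_overlap: int = 1) -> pd.DataFrame:
    """Replicate-overlap reproducibility between two biological replicates.

    Every rep1 peak sharing >= min_overlap bp with a rep2 peak is widened to
    the union interval with its overlapping partner(s); the resulting
    intervals are merged to a sorted, non-overlapping set with midpoint
    summits.
    """
    rep1 = _check_peaks(rep1)
    rep2 = _check_peaks(rep2)
    if len(rep1) == 0 or len(rep2) == 0:
        logger.warning("reproducible_peaks: empty replicate, returning empty set")
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "summit"])
    unions = []
    for chrom, sub2 in rep2.groupby("chrom"):
        s2 = sub2["start"].to_numpy()
        e2 = sub2["end"].to_numpy()
        sub1 = rep1[rep1["chrom"] == chrom]
        for s1, e1 in zip(sub1["start"].to_numpy(), sub1["end"].to_numpy()):
            ov = np.minimum(e2, e1) - np.maximum(s2, s1)
            partners = ov >= min_overlap
            if partners.any():
                unions.append((chrom, min(s1, s2[partners].min()), max(e1, e2[partners].max())))
    if not unions:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "summit"])
    udf = pd.DataFrame(unions, columns=["chrom", "start", "end"])
    return merge_peak_sets([udf])


def classify_novel_peaks(
    stage_order: list[str],
    peaks_by_stage: dict[str, pd.DataFrame],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Label every peak novel or conserved against the union of earlier stages.

    First-stage peaks are all novel. Returns a tidy table (stage, name,
    chrom, start, end, label).
    """
    unknown = [s for s in stage_order if s not in peaks_by_stage]
    if unknown:
        raise SchemaError(f"stages not in peak collection: {unknown}")
    rows = []
    seen: list[pd.DataFrame] = []
    for si, stage in enumerate(stage_order):
        peaks = _check_peaks(peaks_by_stage[stage])
        if si == 0 or not seen:
            novel = np.ones(len(peaks), dtype=bool)
        else:
            prior = pd.concat(seen, ignore_index=True)
            novel = ~overlaps_any(peaks, prior, min_overlap)
        lab = np.where(novel, "novel", "conserved")
        for (_, p), l in zip(peaks.iterrows(), lab):
            rows.append((stage, p["name"], p["chrom"], p["start"], p["end"], l))
        if len(peaks):
            seen.append(peaks)
    return pd.DataFrame(rows, columns=["stage", "name", "chrom", "start", "end", "label"])


def classify_gained_lost(
    stage_t: pd.DataFrame, stage_prev: pd.DataFrame, min_overlap: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gained = stage-t peaks absent from the previous stage; lost = the converse."""
    stage_t = _check_peaks(stage_t)
    stage_prev = _check_peaks(stage_prev)
    gained = stage_t[~overlaps_any(stage_t, stage_prev, min_overlap)].reset_index(drop=True)
    lost = stage_prev[~overlaps_any(stage_prev, stage_t, min_overlap)].reset_index(drop=True)
    return gained, lost


def find_stage_specific_peaks(
    peaks_by_stage: dict[str, pd.DataFrame], min_overlap: int = 1
) -> dict[str, pd.DataFrame]:
    """Per stage, the peaks overlapping no peak of any other stage."""
    if len(peaks_by_stage) < 2:
        raise SchemaError("stage-specific peaks need >= 2 stages")
    out = {}
    for stage, peaks in peaks_by_stage.items():
        peaks = _check_peaks(peaks)
        others = [p for s, p in peaks_by_stage.items() if s != stage and len(p)]
        if not others or len(peaks) == 0:
            out[stage] = peaks.reset_index(drop=True)
            continue
        other = pd.concat([_check_peaks(p) for p in others], ignore_index=True)
        out[stage] = peaks[~overlaps_any(peaks, other, min_overlap)].reset_index(drop=True)
    return out


def _signed_tss_distance(center: int, tss: int, strand: str) -> int:
    d = center - tss
    return -d if strand == "-" else d


def nearest_tss(
    peaks: pd.DataFrame, genes: pd.DataFrame, on_missing: str = "error"
) -> pd.DataFrame:
    """Nearest gene TSS to each peak center (start + summit).

    Ties on |distance| are broken by the lexicographically smaller gene id.
    ``on_missing`` controls behaviour for peaks on chromosomes without
    genes: 'error' raises, 'unassigned' emits NaN rows (logged).
    """
    peaks = _check_peaks(peaks)
    rows = []
    by_chrom = {c: g.sort_values("tss") for c, g in genes.groupby("chrom")}
    for _, p in peaks.iterrows():
        center = int(p["start"]) + int(p["summit"])
        g = by_chrom.get(p["chrom"])
        if g is None or len(g) == 0:
            if on_missing == "error":
                raise ComputationError(f"no genes on chromosome {p['chrom']}")
            logger.warning("peak %s: no genes on %s, unassigned", p["name"], p["chrom"])
            rows.append((p["name"], None, np.nan))
            continue
        dist = np.abs(g["tss"].to_numpy() - center)
        dmin = dist.min()
        cands = g[dist == dmin]
        best = cands.loc[cands["gene_id"].idxmin()] if len(cands) > 1 else cands.iloc[0]
        rows.append(
            (p["name"], best["gene_id"], _signed_tss_distance(center, int(best["tss"]), best["strand"]))
        )
    return pd.DataFrame(rows, columns=["name", "gene_id", "distance"])


def annotate_peak_location(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    exons: pd.DataFrame | None = None,
    promoter_window: tuple[int, int] = (2000, 2000),
) -> pd.DataFrame:
    """Classify each peak center as promoter / exon / intron / distal_intergenic.

    Precedence is promoter > exon > intron > distal. The promoter is
    [TSS - up, TSS + down) in strand orientation. Without an exon table the
    gene body is treated as a single exon, so no center classifies as
    intronic. Also reports the signed strand-aware nearest-TSS distance.
    """
    peaks = _check_peaks(peaks)
    up, down = promoter_window
    missing = set(peaks["chrom"]) - set(genes["chrom"])
    if missing:
        raise ComputationError(f"chromosomes absent from gene annotation: {sorted(missing)}")
    nt = nearest_tss(peaks, genes)
    cats = []
    gene_by_chrom = {c: g for c, g in genes.groupby("chrom")}
    exon_by_chrom = {c: g for c, g in exons.groupby("chrom")} if exons is not None else {}
    for (_, p), (_, hit) in zip(peaks.iterrows(), nt.iterrows()):
        center = int(p["start"]) + int(p["summit"])
        g = gene_by_chrom[p["chrom"]]
        d = np.where(
            g["strand"].to_numpy() == "-",
            g["tss"].to_numpy() - center,
            center - g["tss"].to_numpy(),
        )
        if np.any((d >= -up) & (d < down)):
            cats.append("promoter")
            continue
        in_body = (g["start"].to_numpy() <= center) & (center < g["end"].to_numpy())
        if exons is None:
            cats.append("exon" if in_body.any() else "distal_intergenic")
            continue
        ex = exon_by_chrom.get(p["chrom"])
        in_exon = (
            ex is not None
            and bool(np.any((ex["start"].to_numpy() <= center) & (center < ex["end"].to_numpy())))
        )
        if in_exon:
            cats.append("exon")
        elif in_body.any():
            cats.append("intron")
        else:
            cats.append("distal_intergenic")
    out = nt.copy()
    out["category"] = cats
    return out


def tss_proximity_profile(
    peaks: pd.DataFrame, genes: pd.DataFrame, window: int = 10000, bin: int = 500
) -> pd.DataFrame:
    """Histogram of signed nearest-TSS distances of peak centers in [-window, window)."""
    if window % bin != 0:
        raise ConfigError(f"window {window} must be a multiple of bin {bin}")
    nt = nearest_tss(peaks, genes, on_missing="unassigned")
    d = nt["distance"].dropna().to_numpy()
    edges = np.arange(-window, window + bin, bin)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def replicate_signal_correlation(signal1, signal2) -> float:
    """Pearson correlation of per-peak read counts between two replicates."""
    x = np.asarray(signal1, dtype=float)
    y = np.asarray(signal2, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ComputationError("signals must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("constant signal vector: correlation undefined")
    return float(stats.pearsonr(x, y)[0])
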