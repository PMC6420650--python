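"""Subpopulation TF profiles, stage-to-stage correlation and the dominant path.

Neighboring differentiation stages are connected by the Pearson correlation
of subpopulation-level mean log2(normalized + 1) TF expression profiles;
the dominant lineage path is picked greedily stage by stage, following the
maximal-correlation edge from the current path node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from neurodyn.errors import ComputationError, SchemaError

logger = logging.getLogger(__name__)


def compute_subpop_profiles(
    matrix: pd.DataFrame, cells: pd.DataFrame, tf_list: list[str]
) -> pd.DataFrame:
    """Mean log2(normalized + 1) per TF per subpopulation.

    ``cells`` needs columns cell, stage, subpop. Returns a TF x subpopulation
    DataFrame; column-level metadata (stage of each subpop) is available via
    ``attrs['stage_of']``.
    """
    if not tf_list:
        raise SchemaError("tf_list is empty")
    missing = [t for t in tf_list if t not in matrix.index]
    if missing:
        raise SchemaError(f"TFs absent from matrix: {missing[:10]}")
    for c in ("cell", "stage", "subpop"):
        if c not in cells.columns:
            raise SchemaError(f"cells table missing column {c}")
    logm = np.log2(matrix.loc[tf_list] + 1.0)
    profiles = {}
    stage_of = {}
    for (stage, sp), grp in cells.groupby(["stage", "subpop"], sort=False):
        members = [c for c in grp["cell"] if c in logm.columns]
        if len(members) < 3:
            raise ComputationError(f"subpopulation {sp} has fewer than 3 cells")
        profiles[sp] = logm[members].mean(axis=1)
        stage_of[sp] = stage
    out = pd.DataFrame(profiles)
    out.attrs["stage_of"] = stage_of
    return out


@dataclass
class LineageGraph:
    edges: pd.DataFrame  # stage_from, subpop_from, subpop_to, r
    dominant_path: list[str]


def connect_neighboring_stages(
    profiles: pd.DataFrame,
    stage_order: list[str],
    stage_of: dict[str, str] | None = None,
    start: str | None = None,
) -> LineageGraph:
    """Full bipartite Pearson-r matrices between adjacent stages + greedy path.

    All pairwise correlations between subpopulations of neighboring stages
    are emitted. The dominant path starts at ``start`` (or, when the first
    stage holds several subpopulations and no start is given, at the
    first-stage subpopulation carrying the strongest single edge into stage
    two) and greedily follows the maximal-r edge into each next stage.
    """
    stage_of = stage_of or profiles.attrs.get("stage_of")
    if stage_of is None:
        raise SchemaError("stage_of mapping required (profiles.attrs or argument)")
    if len(stage_order) < 2:
        raise ComputationError("need >= 2 stages")
    by_stage = {
        s: [sp for sp in profiles.columns if stage_of[sp] == s] for s in stage_order
    }
    for s, sps in by_stage.items():
        if not sps:
            raise ComputationError(f"stage {s} has no subpopulation profiles")
    for sp in profiles.columns:
        if np.ptp(profiles[sp].to_numpy()) == 0:
            raise ComputationError(f"profile {sp} is constant; correlation undefined")

    rows = []
    rmat: dict[tuple[str, str], float] = {}
    for a, b in zip(stage_order[:-1], stage_order[1:]):
        for sa in by_stage[a]:
            for sb in by_stage[b]:
                r = float(stats.pearsonr(profiles[sa], profiles[sb])[0])
                rows.append((a, sa, sb, r))
                rmat[(sa, sb)] = r
    edges = pd.DataFrame(rows, columns=["stage_from", "subpop_from", "subpop_to", "r"])

    first = by_stage[stage_order[0]]
    if start is None:
        if len(first) == 1:
            start = first[0]
        else:
            nxt = by_stage[stage_order[1]]
            start = max(first, key=lambda sa: max(rmat[(sa, sb)] for sb in nxt))
    elif start not in first:
        raise ComputationError(f"start {start!r} is not a first-stage subpopulation")
    path = [start]
    for b in stage_order[1:]:
        cur = path[-1]
        path.append(max(by_stage[b], key=lambda sb: rmat[(cur, sb)]))
    return LineageGraph(edges=edges, dominant_path=path)


def select_variable_genes(
    matrix: pd.DataFrame, n_bins: int = 20, z_cutoff: float = 1.0
) -> list[str]:
    """Dispersion-based variable-gene selection.

    Genes are binned by mean expression; within each bin the z-score of the
    log dispersion (variance/mean) is computed, and genes with z > z_cutoff
    are selected. Deterministic for a fixed matrix.
    """
    if matrix.shape[1] < 2:
        raise ComputationError("need >= 2 cells")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    ok = (mean > 0) & (var > 0)
    if ok.sum() == 0:
        return []
    disp = np.zeros_like(mean)
    disp[ok] = var[ok] / mean[ok]
    log_mean = np.log1p(mean[ok])
    log_disp = np.log(disp[ok])
    n_eff = min(n_bins, max(1, ok.sum() // 2))
    if n_eff < n_bins:
        logger.warning("reducing dispersion bins from %d to %d", n_bins, n_eff)
    bins = pd.cut(log_mean, bins=n_eff, labels=False, duplicates="drop")
    z = np.zeros_like(log_disp)
    for b in np.unique(bins):
        sel = bins == b
        mu = log_disp[sel].mean()
        sd = log_disp[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        z[sel] = (log_disp[sel] - mu) / sd if sd > 0 else 0.0
    genes = matrix.index[ok]
    return [g for g, zz in zip(genes, z) if zz > z_cutoff]
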