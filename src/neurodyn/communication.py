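"""Ligand-receptor communication networks within each differentiation stage.

A ligand (receptor) counts as expressed in a subpopulation when its mean
TPM over member cells is strictly above the threshold (default 1). An
interaction edge (source subpop, target subpop, ligand, receptor) exists
when the source expresses the ligand and the target the receptor;
autocrine edges (source = target) are included by default. Subpopulation-
specific ligands/receptors are called by one-vs-rest differential
expression at adjusted p < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from neurodyn.errors import ComputationError, SchemaError
from neurodyn.preprocess import differential_expression

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["stage", "source", "target", "ligand", "receptor", "ligand_tpm", "receptor_tpm"]


def _check_lr(lr_db: pd.DataFrame) -> pd.DataFrame:
    for c in ("ligand", "receptor"):
        if c not in lr_db.columns:
            raise SchemaError(f"L-R table missing column {c}")
    bad = lr_db["ligand"] == lr_db["receptor"]
    if bad.any():
        raise SchemaError("L-R table has ligand == receptor rows")
    return lr_db.drop_duplicates(subset=["ligand", "receptor"])


def expressed_ligands_receptors(
    tpm: pd.DataFrame,
    cells: pd.DataFrame,
    lr_db: pd.DataFrame,
    threshold: float = 1.0,
) -> dict[str, dict]:
    """Per-subpopulation expressed ligand/receptor sets and their mean TPM.

    Returns {subpop: {"ligands": {gene: mean_tpm}, "receptors": {...}}}.
    Genes absent from the matrix or the L-R table are ignored.
    """
    lr_db = _check_lr(lr_db)
    ligands = [g for g in dict.fromkeys(lr_db["ligand"]) if g in tpm.index]
    receptors = [g for g in dict.fromkeys(lr_db["receptor"]) if g in tpm.index]
    out: dict[str, dict] = {}
    for sp, grp in cells.groupby("subpop", sort=False):
        members = [c for c in grp["cell"] if c in tpm.columns]
        if not members:
            raise ComputationError(f"subpopulation {sp} has no cells in the matrix")
        means = tpm[members].mean(axis=1)
        out[sp] = {
            "ligands": {g: float(means[g]) for g in ligands if means[g] > threshold},
            "receptors": {g: float(means[g]) for g in receptors if means[g] > threshold},
        }
    return out


def infer_lr_interactions(
    expressed: dict[str, dict],
    lr_db: pd.DataFrame,
    stage: str = "",
    include_autocrine: bool = True,
) -> pd.DataFrame:
    """Enumerate directed interaction edges among one stage's subpopulations."""
    lr_db = _check_lr(lr_db)
    rows = []
    subpops = list(expressed)
    for _, pair in lr_db.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        for si in subpops:
            if lig not in expressed[si]["ligands"]:
                continue
            for sj in subpops:
                if si == sj and not include_autocrine:
                    continue
                if rec in expressed[sj]["receptors"]:
                    rows.append(
                        (
                            stage, si, sj, lig, rec,
                            expressed[si]["ligands"][lig],
                            expressed[sj]["receptors"][rec],
                        )
                    )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return edges.sort_values(["source", "target", "ligand", "receptor"]).reset_index(drop=True)


def subpop_specific_lr(
    matrix: pd.DataFrame,
    cells: pd.DataFrame,
    lr_db: pd.DataFrame,
    alpha: float = 0.05,
    min_fc: float = 2.0,
) -> dict[str, dict[str, set[str]]]:
    """Ligands/receptors specifically expressed in each subpopulation.

    One-vs-rest rank-sum differential expression within the stage,
    restricted to L-R genes; specific = significantly up at BH-adjusted
    p < alpha (and fold change > min_fc). Stages with a single
    subpopulation yield empty sets (logged).
    """
    lr_db = _check_lr(lr_db)
    lr_genes = [
        g
        for g in dict.fromkeys(pd.concat([lr_db["ligand"], lr_db["receptor"]]))
        if g in matrix.index
    ]
    sub = matrix.loc[lr_genes]
    out: dict[str, dict[str, set[str]]] = {}
    ligset = set(lr_db["ligand"])
    recset = set(lr_db["receptor"])
    subpops = list(dict.fromkeys(cells["subpop"]))
    if len(subpops) < 2:
        logger.warning("single subpopulation; no specificity calls possible")
        return {sp: {"ligands": set(), "receptors": set()} for sp in subpops}
    for sp in subpops:
        cells_in = cells.loc[cells["subpop"] == sp, "cell"].tolist()
        cells_out = cells.loc[cells["subpop"] != sp, "cell"].tolist()
        de = differential_expression(sub, cells_in, cells_out, min_fc=min_fc, alpha=alpha)
        up = set(de.loc[de["significant"] & (de["direction"] == "up"), "gene"])
        out[sp] = {"ligands": up & ligset, "receptors": up & recset}
    return out


def stage_interaction_summary(
    edges_by_stage: dict[str, pd.DataFrame],
    expressed_by_stage: dict[str, dict[str, dict]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage counts and per-subpopulation receptor in-degree.

    Distinct genes are counted once per stage. Receptor in-degree of a
    subpopulation = number of its distinct receptors participating in at
    least one edge.
    """
    rows = []
    indeg_rows = []
    for stage, edges in edges_by_stage.items():
        if expressed_by_stage is not None and stage in expressed_by_stage:
            exp = expressed_by_stage[stage]
            n_lig = len({g for d in exp.values() for g in d["ligands"]})
            n_rec = len({g for d in exp.values() for g in d["receptors"]})
        else:
            n_lig = edges["ligand"].nunique() if len(edges) else 0
            n_rec = edges["receptor"].nunique() if len(edges) else 0
        n_int = len(edges.drop_duplicates(subset=["source", "target", "ligand", "receptor"])) if len(edges) else 0
        rows.append((stage, n_lig, n_rec, n_int))
        if len(edges):
            for sp, grp in edges.groupby("target"):
                indeg_rows.append((stage, sp, grp["receptor"].nunique()))
    summary = pd.DataFrame(
        rows, columns=["stage", "n_expressed_ligands", "n_expressed_receptors", "n_interactions"]
    )
    indegree = pd.DataFrame(indeg_rows, columns=["stage", "subpop", "receptor_in_degree"])
    return summary, indegree
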