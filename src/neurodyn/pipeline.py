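"""End-to-end orchestration from input files to all result tables.

Interchange between steps is plain text (TSV/BED/FASTA) so every stage can
be run, inspected and diffed independently. A manifest with input/output
hashes and per-step row counts makes reruns verifiable: the same config and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from neurodyn import atac, communication, lineage, preprocess, regulome, synthetic
from neurodyn import io as ndio
from neurodyn.errors import NeurodynError
from neurodyn.preprocess import QCThresholds

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str = ""
    out_dir: str = "neurodyn_out"
    stages: tuple[str, ...] = synthetic.DEFAULT_STAGES
    seed: int = 1
    simulate: bool = True  # generate inputs into out_dir/inputs when input_dir is empty
    qc: QCThresholds = field(default_factory=QCThresholds)
    de_alpha: float = 0.01
    de_min_fc: float = 2.0
    network_alpha: float = 0.05
    tpm_threshold: float = 1.0
    degree_threshold: int = 5
    scan_p_threshold: float = 1e-4
    promoter_window: tuple[int, int] = (2000, 2000)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QCThresholds(**raw.pop("qc", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "promoter_window" in raw:
            raw["promoter_window"] = tuple(raw["promoter_window"])
        return cls(qc=qc, **raw)


class PipelineStepError(NeurodynError):
    def __init__(self, step: str, cause: Exception):
        super().__init__(f"step '{step}' failed: {cause}")
        self.step = step
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def step_qc(inp: Path, out: Path, th: QCThresholds) -> dict:
    qc = ndio.read_table(inp / "qc.tsv", required=["cell"] + preprocess.QC_METRICS)
    metric_pass = preprocess.apply_qc_filters(qc, th)
    ercc = ndio.read_matrix_tsv(inp / "qc_ercc.tsv")
    corr_pass = preprocess.ercc_correlation_filter(ercc, r_min=th.min_ercc_correlation)
    merged = metric_pass.merge(corr_pass, on="cell", suffixes=("", "_ercc"))
    merged["passed"] = merged["passed"] & merged["passed_ercc"]
    reasons = []
    for _, row in merged.iterrows():
        r = [x for x in row["reasons"].split(";") if x]
        if not row["passed_ercc"]:
            r.append("ercc_correlation" if row["reasons_ercc"] == "" else "degenerate")
        reasons.append(";".join(r))
    merged["reasons"] = reasons
    result = merged[["cell", "passed", "reasons"]]
    ndio.write_table(result, out / "qc_pass.tsv")
    return {"cells": len(result), "passing": int(result["passed"].sum())}


def step_normalize(inp: Path, out: Path) -> dict:
    counts = ndio.read_matrix_tsv(inp / "counts.tsv")
    genes = ndio.read_genes_bed(inp / "genes.bed")
    qc_pass = ndio.read_table(out / "qc_pass.tsv", required=["cell", "passed"])
    keep = qc_pass.loc[qc_pass["passed"], "cell"].tolist()
    counts = counts[[c for c in counts.columns if c in set(keep)]]
    lengths = pd.Series(genes["length"].to_numpy(), index=genes["gene_id"])
    # spike-ins are normalized with the endogenous library; nominal 100 bp
    for g in counts.index:
        if str(g).startswith(preprocess.ERCC_PREFIX) and g not in lengths.index:
            lengths[g] = 100
    rpkm = preprocess.rpkm_normalize(counts, lengths)
    tpm = preprocess.tpm_normalize(counts, lengths)
    ndio.write_matrix_tsv(rpkm.round(4), out / "rpkm.tsv")
    ndio.write_matrix_tsv(tpm.round(4), out / "tpm.tsv")
    return {"genes": counts.shape[0], "cells_kept": counts.shape[1]}


def _endogenous(matrix: pd.DataFrame) -> pd.DataFrame:
    mask = ~matrix.index.astype(str).str.startswith(preprocess.ERCC_PREFIX)
    return matrix.loc[mask]


def step_stage_de(inp: Path, out: Path, cfg: PipelineConfig) -> dict:
    rpkm = _endogenous(ndio.read_matrix_tsv(out / "rpkm.tsv"))
    cells = ndio.read_table(inp / "cells.tsv", required=["cell", "stage", "subpop"])
    cells = cells[cells["cell"].isin(rpkm.columns)]
    labels = pd.Series(cells["stage"].to_numpy(), index=cells["cell"])
    specific = preprocess.stage_specific_genes(
        rpkm, labels, alpha=cfg.de_alpha, min_fc=cfg.de_min_fc
    )
    rows = [(s, g) for s in cfg.stages for g in sorted(specific.get(s, ()))]
    ndio.write_table(pd.DataFrame(rows, columns=["stage", "gene"]), out / "stage_specific_genes.tsv")
    for a, b in zip(cfg.stages[:-1], cfg.stages[1:]):
        ca = cells.loc[cells["stage"] == a, "cell"].tolist()
        cb = cells.loc[cells["stage"] == b, "cell"].tolist()
        de = preprocess.differential_expression(rpkm, cb, ca, min_fc=cfg.de_min_fc, alpha=cfg.de_alpha)
        ndio.write_table(de.round(6), out / f"de_{b}_vs_{a}.tsv")
    return {"stage_specific_total": len(rows)}


def step_atac(inp: Path, out: Path, cfg: PipelineConfig) -> dict:
    reproducible = {}
    for stage in cfg.stages:
        rep1 = ndio.read_peaks_bed(inp / f"peaks_{stage}_rep1.bed")
        rep2 = ndio.read_peaks_bed(inp / f"peaks_{stage}_rep2.bed")
        rp = atac.reproducible_peaks(rep1, rep2)
        rp["name"] = [f"{stage}_r{i:04d}" for i in range(len(rp))]
        reproducible[stage] = rp
        ndio.write_peaks_bed(rp, out / f"reproducible_{stage}.bed")
    standard = atac.merge_peak_sets(list(reproducible.values()))
    ndio.write_peaks_bed(standard, out / "standard_peaks.bed")

    dynamics = atac.classify_novel_peaks(list(cfg.stages), reproducible)
    gl_rows = []
    for a, b in zip(cfg.stages[:-1], cfg.stages[1:]):
        gained, lost = atac.classify_gained_lost(reproducible[b], reproducible[a])
        gl_rows += [(b, n, "gained") for n in gained["name"]]
        gl_rows += [(a, n, "lost_to_" + b) for n in lost["name"]]
    specific = atac.find_stage_specific_peaks(reproducible)
    sp_rows = [(s, n) for s, df in specific.items() for n in df["name"]]
    ndio.write_table(dynamics, out / "dynamics.tsv")
    ndio.write_table(pd.DataFrame(gl_rows, columns=["stage", "name", "label"]), out / "gained_lost.tsv")
    ndio.write_table(pd.DataFrame(sp_rows, columns=["stage", "name"]), out / "stage_specific_peaks.tsv")

    genes = ndio.read_genes_bed(inp / "genes.bed")
    cats = atac.annotate_peak_location(standard, genes, promoter_window=cfg.promoter_window)
    ndio.write_table(cats, out / "categories.tsv")
    profile = atac.tss_proximity_profile(standard, genes, window=10000, bin=500)
    ndio.write_table(profile, out / "tss_profile.tsv")
    n_novel = int((dynamics["label"] == "novel").sum())
    return {"standard_peaks": len(standard), "novel_total": n_novel}


def step_motifs(inp: Path, out: Path, cfg: PipelineConfig) -> dict:
    standard = ndio.read_peaks_bed(out / "standard_peaks.bed")
    seqs = ndio.read_fasta(inp / "genome.fa")
    genes = ndio.read_genes_bed(inp / "genes.bed")
    pwms = regulome.load_pwms(ndio.read_pfm(inp / "motifs.pfm"))
    peak_seqs = synthetic.extract_peak_sequences(standard, seqs)
    hit_rows = []
    for pwm in pwms:
        for name in standard["name"]:
            hits = regulome.scan_motif(peak_seqs[name], pwm, cfg.scan_p_threshold)
            for _, h in hits.iterrows():
                hit_rows.append((name, pwm.motif_id, int(h["offset"]), h["strand"],
                                 round(float(h["score"]), 4), float(h["pvalue"])))
    hits_df = pd.DataFrame(hit_rows, columns=["peak", "motif", "offset", "strand", "score", "pvalue"])
    ndio.write_table(hits_df, out / "hits.tsv")
    targets = regulome.predict_tf_targets(standard, peak_seqs, pwms, genes, cfg.scan_p_threshold)
    ndio.write_table(targets, out / "tf_targets.tsv")
    return {"hits": len(hits_df), "target_pairs": len(targets)}


def step_network(inp: Path, out: Path, cfg: PipelineConfig) -> dict:
    tf_list = [l.strip() for l in (inp / "tf_list.txt").read_text().splitlines() if l.strip()]
    edges = ndio.read_table(inp / "tf_edges.tsv", required=["tf_a", "tf_b"])
    frames = []
    for a, b in zip(cfg.stages[:-1], cfg.stages[1:]):
        de = ndio.read_table(out / f"de_{b}_vs_{a}.tsv")
        if len(de) == 0:
            continue
        de = de[de["gene"].isin(tf_list)]
        sig = de[(de["padj"] < cfg.network_alpha) & (de["log2fc"].abs() > 1)]
        frames.append(sig[["gene", "direction"]])
    diff = (
        pd.concat(frames).drop_duplicates(subset="gene")
        if frames
        else pd.DataFrame(columns=["gene", "direction"])
    )
    net = regulome.build_regulatory_network(diff, edges, degree_threshold=cfg.degree_threshold)
    edge_rows = [(a, b) for a, b in net.graph.edges]
    ndio.write_table(pd.DataFrame(sorted(edge_rows), columns=["tf_a", "tf_b"]), out / "network.tsv")
    ndio.write_table(net.nodes, out / "network_nodes.tsv")
    ndio.write_table(pd.DataFrame({"tf": net.key_regulators}), out / "key_regulators.tsv")
    return {"diff_tfs": len(diff), "network_nodes": len(net.nodes), "key_regulators": len(net.key_regulators)}


def step_lineage(inp: Path, out: Path, cfg: PipelineConfig) -> dict:
    rpkm = _endogenous(ndio.read_matrix_tsv(out / "rpkm.tsv"))
    cells = ndio.read_table(inp / "cells.tsv", required=["cell", "stage", "subpop"])
    cells = cells[cells["cell"].isin(rpkm.columns)]
    tf_list = [l.strip() for l in (inp / "tf_list.txt").read_text().splitlines() if l.strip()]
    profiles = lineage.compute_subpop_profiles(rpkm, cells, tf_list)
    graph = lineage.connect_neighboring_stages(profiles, list(cfg.stages))
    ndio.write_matrix_tsv(profiles.round(4), out / "profiles.tsv")
    ndio.write_table(graph.edges.round(4), out / "stage_correlations.tsv")
    (out / "dominant_path.txt").write_text("\n".join(graph.dominant_path) + "\n")
    variable = lineage.select_variable_genes(rpkm)
    ndio.write_table(pd.DataFrame({"gene": sorted(variable)}), out / "variable_genes.tsv")
    return {"profiles": profiles.shape[1], "variable_genes": len(variable)}


def step_communication(inp: Path, out: Path, cfg: PipelineConfig) -> dict:
    tpm = _endogenous(ndio.read_matrix_tsv(out / "tpm.tsv"))
    cells = ndio.read_table(inp / "cells.tsv", required=["cell", "stage", "subpop"])
    cells = cells[cells["cell"].isin(tpm.columns)]
    lr = ndio.read_table(inp / "lr_pairs.tsv", required=["ligand", "receptor"])
    edges_by_stage = {}
    expressed_by_stage = {}
    spec_rows = []
    for stage in cfg.stages:
        sub = cells[cells["stage"] == stage]
        expressed = communication.expressed_ligands_receptors(tpm, sub, lr, cfg.tpm_threshold)
        edges = communication.infer_lr_interactions(expressed, lr, stage=stage)
        edges_by_stage[stage] = edges
        expressed_by_stage[stage] = expressed
        ndio.write_table(edges.round(4), out / f"edges_{stage}.tsv")
        spec = communication.subpop_specific_lr(tpm, sub, lr)
        for sp, d in spec.items():
            for g in sorted(d["ligands"]):
                spec_rows.append((stage, sp, g, "ligand"))
            for g in sorted(d["receptors"]):
                spec_rows.append((stage, sp, g, "receptor"))
    summary, indegree = communication.stage_interaction_summary(edges_by_stage, expressed_by_stage)
    ndio.write_table(summary, out / "comm_summary.tsv")
    ndio.write_table(indegree, out / "receptor_in_degree.tsv")
    ndio.write_table(
        pd.DataFrame(spec_rows, columns=["stage", "subpop", "gene", "role"]),
        out / "specific_lr.tsv",
    )
    return {"interactions_total": int(summary["n_interactions"].sum())}


STEPS = [
    "qc", "normalize", "stage_de", "atac_dynamics",
    "motifs", "network", "lineage", "communication",
]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all steps and write a manifest; any failure names its step."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.input_dir:
        inp = Path(cfg.input_dir)
    elif cfg.simulate:
        inp = out / "inputs"
        synthetic.simulate_all(synthetic.SimConfig(seed=cfg.seed), inp)
    else:
        raise NeurodynError("no input_dir given and simulate disabled")

    runners = {
        "qc": lambda: step_qc(inp, out, cfg.qc),
        "normalize": lambda: step_normalize(inp, out),
        "stage_de": lambda: step_stage_de(inp, out, cfg),
        "atac_dynamics": lambda: step_atac(inp, out, cfg),
        "motifs": lambda: step_motifs(inp, out, cfg),
        "network": lambda: step_network(inp, out, cfg),
        "lineage": lambda: step_lineage(inp, out, cfg),
        "communication": lambda: step_communication(inp, out, cfg),
    }
    manifest: dict = {"config": _config_echo(cfg), "steps": {}, "inputs": {}}
    for f in sorted(inp.iterdir()):
        if f.is_file():
            manifest["inputs"][f.name] = _sha256(f)
    for step in STEPS:
        try:
            info = runners[step]()
        except Exception as exc:  # noqa: BLE001 - step name must surface
            raise PipelineStepError(step, exc) from exc
        manifest["steps"][step] = {"status": "completed", **info}
    manifest["outputs"] = {
        f.name: _sha256(f) for f in sorted(out.iterdir()) if f.is_file() and f.name != "manifest.json"
    }
    ndio.write_json(manifest, out / "manifest.json")
    return manifest


def _config_echo(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["qc"] = asdict(cfg.qc)
    return d
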