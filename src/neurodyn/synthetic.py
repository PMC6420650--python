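"""Synthetic study generator with known ground truth.

Emulates the data structure of a staged neural-differentiation experiment:
an ordered series of stages (default iPSC -> EB -> early rosette -> late
rosette -> NPC), two ATAC replicates per stage with controllable peak
conservation between stages, 2-3 expression subpopulations per stage driven
by overlapping TF programs with a planted dominant lineage path, planted
stage-marker genes and subpopulation-specific ligands/receptors, ERCC
spike-in channels, and per-cell QC metrics with planted single-criterion
failures. Every planted feature is recorded in a truth structure so each
downstream analysis stage can be scored against construction.

Counts follow a negative-binomial model with gene-level dispersion plus
Bernoulli dropout — the standard single-cell RNA-seq stand-in. Identical
configs (including seed) produce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from neurodyn import io as ndio
from neurodyn.errors import ConfigError

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("iPSC", "EB", "RosE", "RosL", "NPC")


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the emulated experiment: 5 ordered stages, 2 ATAC
    replicates per stage, 3 subpopulations of 30 cells per stage (~90 cells
    per stage, matching the scale of the profiled study), several hundred
    peaks per stage with ~70% carry-over between neighboring stages, and a
    4-fold (2 log2 units) planted TF-program effect.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 300
    stages: tuple[str, ...] = DEFAULT_STAGES
    subpops_per_stage: int = 3
    cells_per_subpop: int = 30
    n_peaks_per_stage: int = 300
    conservation_rate: float = 0.7
    replicate_jitter_bp: int = 10
    tf_effect_log2fc: float = 2.0
    dropout_rate: float = 0.2
    n_ercc: int = 40
    seed: int = 0
    # secondary layout knobs
    n_tfs: int = 40
    tf_program_size: int = 12
    n_lr_pairs: int = 30
    lr_specific_per_subpop: int = 2
    n_stage_markers: int = 20
    n_qc_fail: int = 10
    n_motifs: int = 6
    motif_sites_per_motif: int = 4
    motif_dominance: float = 0.97
    peak_width_range: tuple[int, int] = (300, 700)

    def __post_init__(self):
        if not 0.0 <= self.conservation_rate <= 1.0:
            raise ConfigError("conservation_rate must be in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        for f in (
            "n_chroms", "chrom_length", "n_genes", "subpops_per_stage",
            "cells_per_subpop", "n_peaks_per_stage", "n_ercc", "n_tfs",
        ):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f} must be positive")
        if self.subpops_per_stage < 1:
            raise ConfigError("subpops_per_stage must be >= 1")
        needed = (
            self.n_tfs
            + 2 * self.n_lr_pairs
            + len(self.stages) * self.n_stage_markers
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for gene layout ({needed} needed)"
            )
        n_cells = len(self.stages) * self.subpops_per_stage * self.cells_per_subpop
        if self.n_qc_fail >= n_cells:
            raise ConfigError("planted QC failure fraction must be < 1")

    # --- deterministic id layout (shared by independent generators) ---

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def tf_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_tfs]

    def ligand_ids(self) -> list[str]:
        g = self.gene_ids()
        return g[self.n_tfs : self.n_tfs + self.n_lr_pairs]

    def receptor_ids(self) -> list[str]:
        g = self.gene_ids()
        return g[self.n_tfs + self.n_lr_pairs : self.n_tfs + 2 * self.n_lr_pairs]

    def stage_marker_ids(self) -> dict[str, list[str]]:
        g = self.gene_ids()
        base = self.n_tfs + 2 * self.n_lr_pairs
        out = {}
        for i, stage in enumerate(self.stages):
            out[stage] = g[base + i * self.n_stage_markers : base + (i + 1) * self.n_stage_markers]
        return out

    def ercc_ids(self) -> list[str]:
        return [f"ERCC-{i:05d}" for i in range(self.n_ercc)]

    def subpop_ids(self) -> dict[str, list[str]]:
        return {
            s: [f"{s}_s{p + 1}" for p in range(self.subpops_per_stage)]
            for s in self.stages
        }

    def cell_table(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            for sp in self.subpop_ids()[stage]:
                for i in range(self.cells_per_subpop):
                    rows.append((f"{sp}_c{i + 1:03d}", stage, sp))
        return pd.DataFrame(rows, columns=["cell", "stage", "subpop"])

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GenomeAnnotation:
    """Gene models (with TSS and transcript length) plus chromosome sequences."""

    genes: pd.DataFrame
    seqs: dict[str, str] = field(default_factory=dict)


@dataclass
class StagePeakCollection:
    """Consensus peak intervals per stage and the two jittered replicates."""

    consensus: dict[str, pd.DataFrame]
    replicates: dict[tuple[str, int], pd.DataFrame]


def generate_genome(cfg: SimConfig) -> GenomeAnnotation:
    """Random chromosomes and non-colliding gene models.

    TSSs are laid on a 2 kb grid with sub-grid jitter so no two genes share
    a TSS; transcript lengths are uniform in [500, 20000] bp (clipped at
    chromosome ends). Raises if the genes cannot be placed without
    collision.
    """
    rng = cfg._rng(1)
    slot = 2000
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    slots_per_chrom = cfg.chrom_length // slot
    if max(per_chrom) > slots_per_chrom:
        raise ConfigError(
            f"cannot place {max(per_chrom)} genes on a {cfg.chrom_length} bp "
            f"chromosome without TSS collision"
        )
    gene_ids = cfg.gene_ids()
    rows = []
    gi = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        picks = np.sort(rng.choice(slots_per_chrom, size=n_here, replace=False))
        jitter = rng.integers(0, slot // 2, size=n_here)
        tss = picks * slot + jitter
        strands = rng.choice(["+", "-"], size=n_here)
        lengths = rng.integers(500, 20001, size=n_here)
        for t, st, ln in zip(tss, strands, lengths):
            if st == "+":
                start = int(t)
                end = int(min(t + ln, cfg.chrom_length))
            else:
                end = int(t) + 1
                start = int(max(end - ln, 0))
            rows.append((chrom, start, end, gene_ids[gi], end - start, st, int(t)))
            gi += 1
    genes = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "length", "strand", "tss"]
    )
    seqs = {
        c: "".join(rng.choice(list("ACGT"), size=cfg.chrom_length))
        for c in chrom_names
    }
    return GenomeAnnotation(genes=genes, seqs=seqs)


def _place_peaks(rng, n, cfg, occupied, gap):
    """Rejection-sample n intervals avoiding all occupied intervals (+gap)."""
    chrom_names = sorted(occupied)
    widths = rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1, size=n)
    placed = []
    for w in widths:
        for _ in range(2000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            s = int(rng.integers(0, cfg.chrom_length - int(w)))
            e = s + int(w)
            if all(not (s - gap < be and e + gap > bs) for bs, be in occupied[chrom]):
                occupied[chrom].append((s, e))
                placed.append((chrom, s, e))
                break
        else:
            raise ConfigError("cannot place peaks without overlap; genome too crowded")
    return placed


def generate_stage_peaks(
    cfg: SimConfig, genome: GenomeAnnotation
) -> tuple[StagePeakCollection, dict]:
    """Stage-ordered peak sets with exact novel/conserved/gained/lost truth.

    Stage-t consensus peaks are a mixture of carried-over stage-(t-1)
    intervals (fraction ``conservation_rate``) and brand-new intervals
    placed to overlap nothing emitted before, so the construction labels
    are exact. Each stage emits 2 replicates whose boundaries are jittered
    by at most ``replicate_jitter_bp``; summits sit at interval midpoints.
    """
    rng = cfg._rng(2)
    gap = 2 * cfg.replicate_jitter_bp + 10
    occupied = {f"chr{i + 1}": [] for i in range(cfg.n_chroms)}
    consensus: dict[str, pd.DataFrame] = {}
    replicates: dict[tuple[str, int], pd.DataFrame] = {}
    labels: dict[str, str] = {}
    gained: dict[str, list[str]] = {}
    lost: dict[str, list[str]] = {}
    carried_from_prev: dict[str, list[str]] = {}  # stage -> prev-stage ids carried in
    prev_df = None
    prev_stage = None
    for t, stage in enumerate(cfg.stages):
        rows = []
        carried_ids: list[str] = []
        if t == 0:
            n_new = cfg.n_peaks_per_stage
        else:
            n_cons = int(round(cfg.conservation_rate * cfg.n_peaks_per_stage))
            if n_cons > len(prev_df):
                logger.warning(
                    "stage %s: only %d prior peaks for %d requested carried peaks",
                    stage, len(prev_df), n_cons,
                )
                n_cons = len(prev_df)
            n_new = cfg.n_peaks_per_stage - n_cons
            pick = np.sort(rng.choice(len(prev_df), size=n_cons, replace=False))
            for _, p in prev_df.iloc[pick].iterrows():
                rows.append((p["chrom"], p["start"], p["end"], "conserved"))
                carried_ids.append(p["name"])
        for chrom, s, e in _place_peaks(rng, n_new, cfg, occupied, gap):
            rows.append((chrom, s, e, "novel"))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        df["name"] = [f"{stage}_p{i:04d}" for i in range(len(df))]
        df["summit"] = (df["end"] - df["start"]) // 2
        for _, p in df.iterrows():
            labels[p["name"]] = p["label"]
        if t > 0:
            gained[stage] = df.loc[df["label"] == "novel", "name"].tolist()
            lost[prev_stage] = [
                n for n in prev_df["name"] if n not in set(carried_ids)
            ]
            carried_from_prev[stage] = carried_ids
        consensus[stage] = df[["chrom", "start", "end", "name", "summit"]].copy()
        consensus[stage]["stage"] = stage
        for k in (1, 2):
            j = cfg.replicate_jitter_bp
            ds = rng.integers(-j, j + 1, size=len(df)) if j > 0 else np.zeros(len(df), int)
            de = rng.integers(-j, j + 1, size=len(df)) if j > 0 else np.zeros(len(df), int)
            rep = df[["chrom"]].copy()
            rep["start"] = np.maximum(df["start"] + ds, 0)
            rep["end"] = df["end"] + de
            rep["name"] = [f"{stage}_rep{k}_p{i:04d}" for i in range(len(df))]
            rep["summit"] = (rep["end"] - rep["start"]) // 2
            rep["stage"] = stage
            rep["replicate"] = k
            replicates[(stage, k)] = rep.reset_index(drop=True)
        prev_df = df
        prev_stage = stage

    # stage-specific = novel and never carried into the next stage
    stage_specific: dict[str, list[str]] = {}
    for t, stage in enumerate(cfg.stages):
        novel_here = [
            n for n in consensus[stage]["name"] if labels[n] == "novel"
        ]
        if t + 1 < len(cfg.stages):
            carried_next = set(carried_from_prev.get(cfg.stages[t + 1], []))
        else:
            carried_next = set()
        stage_specific[stage] = [n for n in novel_here if n not in carried_next]

    truth = {
        "peak_labels": labels,
        "gained": gained,
        "lost": lost,
        "stage_specific": stage_specific,
    }
    return StagePeakCollection(consensus=consensus, replicates=replicates), truth


def _tf_programs(cfg: SimConfig, rng) -> tuple[dict[str, list[str]], list[str]]:
    """Per-subpopulation TF programs with a planted dominant path.

    Consecutive path subpopulations share ~80% of their program; off-path
    subpopulations share only ~25% with the current path program, so the
    path is the unique highest-correlation chain by construction.
    """
    tfs = np.array(cfg.tf_ids())
    m = cfg.tf_program_size
    k_keep = max(1, int(round(0.8 * m)))
    k_share = int(round(0.25 * m))
    subpops = cfg.subpop_ids()
    path = [
        subpops[s][int(rng.integers(cfg.subpops_per_stage))] for s in cfg.stages
    ]
    programs: dict[str, list[str]] = {}
    path_prog = rng.choice(len(tfs), size=m, replace=False)
    for t, stage in enumerate(cfg.stages):
        if t > 0:
            keep = rng.choice(path_prog, size=k_keep, replace=False)
            outside = np.setdiff1d(np.arange(len(tfs)), path_prog)
            fresh = rng.choice(outside, size=m - k_keep, replace=False)
            path_prog = np.concatenate([keep, fresh])
        programs[path[t]] = sorted(tfs[path_prog])
        for sp in subpops[stage]:
            if sp == path[t]:
                continue
            share = rng.choice(path_prog, size=k_share, replace=False)
            outside = np.setdiff1d(np.arange(len(tfs)), path_prog)
            fresh = rng.choice(outside, size=m - k_share, replace=False)
            programs[sp] = sorted(tfs[np.concatenate([share, fresh])])
    return programs, path


def generate_expression_dataset(
    cfg: SimConfig, genome: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Counts (genes + ERCC x cells), cell annotations, and planted truth.

    Negative-binomial counts with per-subpopulation TF-program shifts of
    ``tf_effect_log2fc``, per-stage marker genes, subpopulation-specific
    ligands/receptors, appended ERCC channels at cell-independent true
    concentrations (log-uniform over 4 orders of magnitude), and Bernoulli
    dropout on endogenous genes.
    """
    rng = cfg._rng(3)
    cells = cfg.cell_table()
    gene_ids = cfg.gene_ids()
    n_g, n_c = len(gene_ids), len(cells)

    programs, path = _tf_programs(cfg, rng)
    markers = cfg.stage_marker_ids()

    # subpopulation-specific ligands/receptors (disjoint within a stage)
    lig, rec = cfg.ligand_ids(), cfg.receptor_ids()
    k = cfg.lr_specific_per_subpop
    if k * cfg.subpops_per_stage > min(len(lig), len(rec)):
        raise ConfigError("not enough L-R genes for the requested specificity layout")
    specific_lr: dict[str, dict[str, list[str]]] = {}
    for stage in cfg.stages:
        lpick = rng.choice(len(lig), size=k * cfg.subpops_per_stage, replace=False)
        rpick = rng.choice(len(rec), size=k * cfg.subpops_per_stage, replace=False)
        for i, sp in enumerate(cfg.subpop_ids()[stage]):
            specific_lr[sp] = {
                "ligands": sorted(np.array(lig)[lpick[i * k : (i + 1) * k]]),
                "receptors": sorted(np.array(rec)[rpick[i * k : (i + 1) * k]]),
            }

    base = 2.0 ** rng.normal(3.0, 1.2, size=n_g)
    # ligand/receptor genes get a moderate baseline floor so a planted
    # fold-change shift is expressible above the +1 pseudocount scale
    lr_idx = [gene_ids.index(g) for g in lig + rec]
    base[lr_idx] = 2.0 ** rng.uniform(3.0, 5.0, size=len(lr_idx))
    size_factor = 2.0 ** rng.normal(0.0, 0.15, size=n_c)
    dispersion = rng.uniform(2.0, 10.0, size=n_g)

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    effect = np.zeros((n_g, n_c))
    boost = cfg.tf_effect_log2fc
    for j, (_, cell) in enumerate(cells.iterrows()):
        sp, stage = cell["subpop"], cell["stage"]
        for g in programs[sp]:
            effect[gene_index[g], j] += boost
        for g in markers[stage]:
            effect[gene_index[g], j] += boost
        for g in specific_lr[sp]["ligands"] + specific_lr[sp]["receptors"]:
            effect[gene_index[g], j] += boost
    mu = base[:, None] * (2.0 ** effect) * size_factor[None, :]
    r = dispersion[:, None]
    counts = rng.negative_binomial(r, r / (r + mu))
    if cfg.dropout_rate > 0:
        counts = np.where(rng.random((n_g, n_c)) < cfg.dropout_rate, 0, counts)

    ercc_conc = 10.0 ** rng.uniform(0, 4, size=cfg.n_ercc)
    ercc_conc *= 400.0 / ercc_conc.sum()  # keep spike-ins a few % of the library
    mu_e = ercc_conc[:, None] * size_factor[None, :]
    r_e = 20.0
    ercc_counts = rng.negative_binomial(r_e, r_e / (r_e + mu_e))

    matrix = pd.DataFrame(
        np.vstack([counts, ercc_counts]),
        index=gene_ids + cfg.ercc_ids(),
        columns=cells["cell"],
    )

    de_genes: dict[str, dict[str, list[str]]] = {}
    for a, b in zip(cfg.stages[:-1], cfg.stages[1:]):
        de_genes[f"{a}|{b}"] = {"up": sorted(markers[b]), "down": sorted(markers[a])}

    truth = {
        "planted_path": path,
        "tf_programs": programs,
        "stage_markers": {s: sorted(v) for s, v in markers.items()},
        "de_genes": de_genes,
        "specific_lr": specific_lr,
        "ercc_concentration": ercc_conc.tolist(),
    }
    return matrix, cells, truth


_QC_FAIL_KINDS = [
    "genome_map_rate", "mito_fraction", "mrna_map_rate",
    "ercc_ratio", "n_genes", "ercc_correlation",
]


def generate_qc_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-cell QC metrics, the ERCC sub-matrix, and planted failures.

    Each of ``n_qc_fail`` designated cells fails exactly one criterion
    (cycling through the six kinds); all other cells sit strictly inside
    every threshold. Cells planted to fail the ERCC correlation get an
    independently permuted spike-in concentration vector.
    """
    rng = cfg._rng(4)
    cells = cfg.cell_table()
    n = len(cells)
    qc = pd.DataFrame(
        {
            "cell": cells["cell"],
            "genome_map_rate": rng.uniform(0.75, 0.95, n),
            "mito_fraction": rng.uniform(0.02, 0.15, n),
            "mrna_map_rate": rng.uniform(0.85, 0.97, n),
            "ercc_ratio": rng.uniform(0.02, 0.08, n),
            "n_genes": rng.integers(5500, 9001, n),
        }
    )
    fail_idx = np.sort(rng.choice(n, size=cfg.n_qc_fail, replace=False))
    fail_reasons: dict[str, str] = {}
    for i, idx in enumerate(fail_idx):
        kind = _QC_FAIL_KINDS[i % len(_QC_FAIL_KINDS)]
        cell = qc.at[idx, "cell"]
        fail_reasons[cell] = kind
        if kind == "genome_map_rate":
            qc.at[idx, "genome_map_rate"] = rng.uniform(0.40, 0.65)
        elif kind == "mito_fraction":
            qc.at[idx, "mito_fraction"] = rng.uniform(0.25, 0.60)
        elif kind == "mrna_map_rate":
            qc.at[idx, "mrna_map_rate"] = rng.uniform(0.50, 0.75)
        elif kind == "ercc_ratio":
            qc.at[idx, "ercc_ratio"] = rng.uniform(0.15, 0.40)
        elif kind == "n_genes":
            qc.at[idx, "n_genes"] = int(rng.integers(500, 4500))

    conc = 10.0 ** rng.uniform(0, 4, size=cfg.n_ercc)
    log_mu = np.log2(conc + 1.0)
    ercc = np.zeros((cfg.n_ercc, n))
    for j in range(n):
        c = qc.at[j, "cell"]
        mu = log_mu.copy()
        if fail_reasons.get(c) == "ercc_correlation":
            mu = rng.permutation(mu)
        noisy = mu + rng.normal(0, 0.25, size=cfg.n_ercc)
        ercc[:, j] = np.maximum(np.round(2.0 ** noisy - 1.0), 0)
    ercc_df = pd.DataFrame(ercc.astype(int), index=cfg.ercc_ids(), columns=qc["cell"])

    truth = {
        "qc_fail_reasons": fail_reasons,
        "qc_pass_cells": sorted(set(qc["cell"]) - set(fail_reasons)),
    }
    return qc, ercc_df, truth


def generate_motif_library(
    cfg: SimConfig, peaks: StagePeakCollection, genome: GenomeAnnotation
) -> tuple[list[tuple[str, np.ndarray]], dict]:
    """PFM library (lengths 4-12) with consensus sites planted into peaks.

    Chromosome sequences in ``genome`` are edited in place so that the
    extracted peak sequences contain the planted sites; offsets are
    recorded relative to the consensus peak start.
    """
    rng = cfg._rng(5)
    allpeaks = pd.concat(peaks.consensus.values(), ignore_index=True)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.seqs.items()}
    lengths = [4 + (i % 9) for i in range(cfg.n_motifs)]
    pfms: list[tuple[str, np.ndarray]] = []
    planted: list[dict] = []
    comp = str.maketrans("ACGT", "TGCA")
    used: dict[str, list[tuple[int, int]]] = {}  # peak -> planted (start, end) spans
    for i, L in enumerate(lengths):
        mid = f"M{i + 1:02d}"
        dom = rng.integers(0, 4, size=L)
        counts = np.full((4, L), (1 - cfg.motif_dominance) * 100 / 3)
        counts[dom, np.arange(L)] = cfg.motif_dominance * 100
        pfms.append((mid, counts))
        consensus = "".join("ACGT"[d] for d in dom)
        pick = rng.choice(len(allpeaks), size=cfg.motif_sites_per_motif, replace=False)
        for pi in pick:
            p = allpeaks.iloc[pi]
            width = int(p["end"]) - int(p["start"])
            if L > width:
                raise ConfigError(f"motif {mid} longer than peak {p['name']}")
            spans = used.setdefault(p["name"], [])
            for _ in range(100):  # avoid overwriting an earlier planted site
                offset = int(rng.integers(0, width - L + 1))
                if all(offset + L <= s or offset >= e for s, e in spans):
                    break
            else:
                raise ConfigError(f"cannot place motif {mid} in peak {p['name']}")
            spans.append((offset, offset + L))
            strand = "+" if rng.random() < 0.5 else "-"
            site = consensus if strand == "+" else consensus.translate(comp)[::-1]
            pos = int(p["start"]) + offset
            seqs[p["chrom"]][pos : pos + L] = site.encode()
            planted.append(
                {
                    "peak": p["name"],
                    "motif": mid,
                    "offset": offset,
                    "strand": strand,
                    "length": L,
                }
            )
    genome.seqs = {c: s.decode() for c, s in seqs.items()}
    return pfms, {"planted_motif_sites": planted}


def generate_interaction_fixtures(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Ligand-receptor pair table and a TF-TF edge table with designated hubs.

    The L-R table pairs the i-th ligand with the i-th receptor of the gene
    layout (covering all planted specific genes); the undirected TF edge
    table contains 3 hub TFs wired to 14 partners each (degree well above
    the key-regulator cutoff even after restriction to a differential
    subset) while all other TFs stay at degree <= 5.
    """
    rng = cfg._rng(6)
    lr = pd.DataFrame(
        {"ligand": cfg.ligand_ids(), "receptor": cfg.receptor_ids(), "source": "synthetic"}
    )
    tfs = cfg.tf_ids()
    n_hubs = min(3, max(1, len(tfs) // 12))
    hub_degree = min(14, len(tfs) - n_hubs)
    hubs = list(rng.choice(tfs, size=n_hubs, replace=False))
    edges: set[tuple[str, str]] = set()
    degree = {t: 0 for t in tfs}
    for h in hubs:
        partners = rng.choice([t for t in tfs if t not in hubs], size=hub_degree, replace=False)
        for p in partners:
            e = tuple(sorted((h, p)))
            if e not in edges:
                edges.add(e)
                degree[h] += 1
                degree[p] += 1
    non_hubs = [t for t in tfs if t not in hubs]
    for _ in range(len(tfs)):
        a, b = rng.choice(non_hubs, size=2, replace=False)
        e = tuple(sorted((a, b)))
        if e not in edges and degree[a] < 4 and degree[b] < 4:
            edges.add(e)
            degree[a] += 1
            degree[b] += 1
    edge_df = pd.DataFrame(sorted(edges), columns=["tf_a", "tf_b"])
    return lr, edge_df, {"hub_tfs": sorted(hubs)}


def extract_peak_sequences(peaks: pd.DataFrame, seqs: dict[str, str]) -> dict[str, str]:
    return {
        p["name"]: seqs[p["chrom"]][int(p["start"]) : int(p["end"])]
        for _, p in peaks.iterrows()
    }


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate the full synthetic study and write every interchange file.

    Emits genes.bed, genome.fa, peaks_<stage>_rep<k>.bed, counts.tsv,
    cells.tsv, qc.tsv, qc_ercc.tsv, motifs.pfm, lr_pairs.tsv, tf_edges.tsv,
    tf_list.txt and truth.json into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(cfg)
    peaks, peak_truth = generate_stage_peaks(cfg, genome)
    matrix, cells, expr_truth = generate_expression_dataset(cfg, genome)
    qc, qc_ercc, qc_truth = generate_qc_table(cfg)
    pfms, motif_truth = generate_motif_library(cfg, peaks, genome)  # edits genome.seqs
    lr, tf_edges, net_truth = generate_interaction_fixtures(cfg)

    ndio.write_genes_bed(genome.genes, outdir / "genes.bed")
    ndio.write_fasta(genome.seqs, outdir / "genome.fa")
    for (stage, k), rep in peaks.replicates.items():
        ndio.write_peaks_bed(rep, outdir / f"peaks_{stage}_rep{k}.bed")
    ndio.write_matrix_tsv(matrix, outdir / "counts.tsv")
    ndio.write_table(cells, outdir / "cells.tsv")
    ndio.write_table(qc, outdir / "qc.tsv")
    ndio.write_matrix_tsv(qc_ercc, outdir / "qc_ercc.tsv")
    ndio.write_pfm(pfms, outdir / "motifs.pfm")
    ndio.write_table(lr, outdir / "lr_pairs.tsv")
    ndio.write_table(tf_edges, outdir / "tf_edges.tsv")
    (outdir / "tf_list.txt").write_text("\n".join(cfg.tf_ids()) + "\n")

    truth = {**peak_truth, **expr_truth, **qc_truth, **motif_truth, **net_truth}
    ndio.write_json(truth, outdir / "truth.json")
    return {
        "genome": genome,
        "peaks": peaks,
        "matrix": matrix,
        "cells": cells,
        "qc": qc,
        "qc_ercc": qc_ercc,
        "pfms": pfms,
        "lr": lr,
        "tf_edges": tf_edges,
        "truth": truth,
        "config": asdict(cfg),
    }
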