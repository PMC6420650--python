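"""Motif scanning, peak target assignment and key-regulator networks.

The scanner scores every window of a sequence on both strands with a
position weight matrix as the sum of per-position log2 odds against an
i.i.d. background, and converts scores to exact p-values: the probability
that a random background sequence of motif length scores at least as high.
Exactness is achieved by discretizing per-position scores on a fixed grid
(default 1e-3 bits) and convolving the per-position score distributions —
the same discretization under which a brute-force enumeration of all 4^k
k-mers yields identical tail probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np
import pandas as pd

from neurodyn.atac import nearest_tss
from neurodyn.errors import ComputationError, ConfigError, SchemaError

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


def encode_sequence(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SchemaError(f"invalid characters in sequence: {sorted(bad)}")
    return np.array([_CODE[b] for b in seq], dtype=np.int64)


@dataclass
class PWM:
    """Position weight matrix over A,C,G,T with an i.i.d. background model.

    ``probs`` is (length, 4); rows must sum to 1. ``grid`` is the score
    discretization (bits) used for exact p-values.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    grid: float = 1e-3

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ConfigError(f"{self.motif_id}: probs must be (L, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError(f"{self.motif_id}: position probabilities must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ConfigError(f"{self.motif_id}: background must sum to 1")

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float | None = None,
        grid: float = 1e-3,
    ) -> "PWM":
        """Build from a 4 x L position-frequency matrix.

        The default pseudocount is 0.25/sqrt(n) with n the column total, a
        light regularizer that keeps log-odds finite for zero counts.
        """
        counts = np.asarray(counts, dtype=float).T  # -> (L, 4)
        n = counts.sum(axis=1, keepdims=True)
        if np.any(n <= 0):
            raise ConfigError(f"{motif_id}: empty count column")
        pc = pseudocount if pseudocount is not None else 0.25 / np.sqrt(n)
        probs = (counts + pc) / (n + 4 * np.asarray(pc))
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(motif_id, probs, bg, grid)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p/background) in bits.

        Zero-probability bases are floored at -30 bits per position (below
        any practical threshold) so degenerate one-base-per-column matrices
        stay finite and the exact-p-value convolution stays tractable.
        """
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[None, :])
        return np.maximum(lo, -30.0)

    @cached_property
    def int_scores(self) -> np.ndarray:
        return np.round(self.log_odds / self.grid).astype(np.int64)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_attainable_pvalue(self) -> float:
        """Exact p-value of the best possible score (floor of the scanner).

        For short motifs this floor can exceed a stringent scan threshold —
        e.g. a length-4 consensus under a uniform background cannot beat
        p = 4^-4 — in which case no window is reportable at that threshold.
        """
        return self.pvalue(int(self.int_scores.max(axis=1).sum()))

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    @cached_property
    def _score_distribution(self) -> tuple[int, np.ndarray]:
        """Exact distribution of the discretized score under the background.

        Returns (minimum integer score, survival array) where survival[k]
        is P(int score >= min + k).
        """
        I = self.int_scores
        mins = I.min(axis=1)
        dist = np.zeros(1)
        dist[0] = 1.0
        for i in range(len(self)):
            span = int(I[i].max() - mins[i])
            new = np.zeros(len(dist) + span)
            for b in range(4):
                off = int(I[i, b] - mins[i])
                new[off : off + len(dist)] += self.background[b] * dist
            dist = new
        sf = np.cumsum(dist[::-1])[::-1]
        return int(mins.sum()), sf

    def pvalue(self, int_score: int) -> float:
        """P(background window scores >= int_score) on the discretized grid."""
        min_int, sf = self._score_distribution
        k = int_score - min_int
        if k < 0:
            return 1.0
        if k >= len(sf):
            return 0.0
        return float(sf[k])

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose exact p-value is <= p_threshold."""
        min_int, sf = self._score_distribution
        idx = np.searchsorted(-sf, -p_threshold, side="left")
        if idx >= len(sf):
            return min_int + len(sf)  # unattainable
        return min_int + int(idx)

    def reverse_complement(self) -> "PWM":
        """Matrix scoring the minus strand of a forward window.

        Probabilities are reversed and complemented; the background is
        complemented, which makes the score distribution of the returned
        matrix under its background identical to this matrix's — hence
        strand-symmetric p-values even for skewed backgrounds.
        """
        if not hasattr(self, "_rc_cache"):
            self._rc_cache = PWM(
                self.motif_id,
                self.probs[::-1, ::-1].copy(),
                self.background[::-1].copy(),
                self.grid,
            )
        return self._rc_cache


def scan_motif(sequence: str, pwm: PWM, p_threshold: float = 1e-4) -> pd.DataFrame:
    """All motif occurrences in ``sequence`` (both strands) with exact p <= threshold.

    Returns a table (offset, strand, score, pvalue); offsets index the
    forward sequence, windows containing N are skipped. A minus-strand hit
    at offset o means the reverse complement of sequence[o:o+L] matches.
    """
    if not 0 < p_threshold < 1:
        raise ConfigError("p_threshold must be in (0, 1)")
    codes = encode_sequence(sequence)
    L = len(pwm)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return pd.DataFrame(columns=["offset", "strand", "score", "pvalue"])
    thr = pwm.score_threshold(p_threshold)
    rows = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        I = mat.int_scores
        lo = mat.log_odds
        # background symmetry note: the reverse-complement matrix is scored
        # against the reverse-complemented background, whose score
        # distribution is identical for complement-symmetric backgrounds;
        # for skewed backgrounds the rc matrix carries its own distribution.
        thr_s = thr if strand == "+" else mat.score_threshold(p_threshold)
        total = np.zeros(n_win, dtype=np.int64)
        fscore = np.zeros(n_win)
        valid = np.ones(n_win, dtype=bool)
        for pos in range(L):
            c = codes[pos : pos + n_win]
            ok = c >= 0
            valid &= ok
            csafe = np.where(ok, c, 0)
            total += I[pos, csafe]
            fscore += lo[pos, csafe]
        for off in np.nonzero(valid & (total >= thr_s))[0]:
            rows.append(
                (int(off), strand, float(fscore[off]), mat.pvalue(int(total[off])))
            )
    out = pd.DataFrame(rows, columns=["offset", "strand", "score", "pvalue"])
    return out.sort_values(["offset", "strand"]).reset_index(drop=True)


def load_pwms(
    pfm_blocks: list[tuple[str, np.ndarray]],
    background: np.ndarray | None = None,
    pseudocount: float | None = None,
) -> list[PWM]:
    return [
        PWM.from_counts(mid, counts, background=background, pseudocount=pseudocount)
        for mid, counts in pfm_blocks
    ]


def assign_nearest_tss_target(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest-TSS-to-summit target per peak (ties -> smaller gene id).

    Peaks on gene-free chromosomes are left unassigned with a logged
    warning.
    """
    return nearest_tss(peaks, genes, on_missing="unassigned")


def predict_tf_targets(
    peaks: pd.DataFrame,
    sequences: dict[str, str],
    pwms: list[PWM],
    genes: pd.DataFrame,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-TF putative target genes via motif-containing peaks.

    A peak containing >= 1 hit of a TF's motif is TF-related; the TF's
    targets are the nearest-TSS genes of its related peaks. Returns a tidy
    (motif_id, gene_id, n_peaks) table.
    """
    missing = [n for n in peaks["name"] if n not in sequences]
    if missing:
        raise SchemaError(f"no sequence provided for peaks: {missing[:5]}")
    targets = assign_nearest_tss_target(peaks, genes).set_index("name")
    rows = []
    for pwm in pwms:
        related = []
        for name in peaks["name"]:
            hits = scan_motif(sequences[name], pwm, p_threshold)
            if len(hits):
                related.append(name)
        genes_hit: dict[str, int] = {}
        for name in related:
            g = targets.loc[name, "gene_id"]
            if g is not None and not (isinstance(g, float) and np.isnan(g)):
                genes_hit[g] = genes_hit.get(g, 0) + 1
        for g, k in sorted(genes_hit.items()):
            rows.append((pwm.motif_id, g, k))
    return pd.DataFrame(rows, columns=["motif_id", "gene_id", "n_peaks"])


@dataclass
class RegulatoryNetwork:
    graph: nx.Graph
    nodes: pd.DataFrame  # tf, direction, degree
    key_regulators: list[str]


def build_regulatory_network(
    diff_tfs: pd.DataFrame,
    edges: pd.DataFrame,
    degree_threshold: int = 5,
    degree_scope: str = "induced",
) -> RegulatoryNetwork:
    """Differential-TF interaction subnetwork and its key regulators.

    The subgraph is induced on the differential TFs; TFs without any
    interaction are removed; key regulators are the nodes whose degree is
    strictly above ``degree_threshold``. ``degree_scope`` chooses whether
    degree is counted on the induced subgraph (default) or on the full
    input edge table.
    """
    tf_col = "tf" if "tf" in diff_tfs.columns else "gene"
    if tf_col not in diff_tfs.columns:
        raise SchemaError("diff_tfs needs a 'tf' or 'gene' column")
    for c in ("tf_a", "tf_b"):
        if c not in edges.columns:
            raise SchemaError(f"edge table missing column {c}")
    tfs = list(dict.fromkeys(diff_tfs[tf_col]))
    directions = dict(zip(diff_tfs[tf_col], diff_tfs.get("direction", ["up"] * len(diff_tfs))))

    full = nx.Graph()
    n_self = 0
    for a, b in edges[["tf_a", "tf_b"]].itertuples(index=False):
        if a == b:
            n_self += 1
            continue
        full.add_edge(a, b)
    if n_self:
        logger.warning("dropped %d self-loop edges", n_self)

    sub = full.subgraph([t for t in tfs if t in full]).copy()
    sub.remove_nodes_from([n for n, d in dict(sub.degree()).items() if d == 0])
    if degree_scope == "induced":
        deg = dict(sub.degree())
    elif degree_scope == "full":
        deg = {n: full.degree(n) for n in sub}
    else:
        raise ConfigError(f"unknown degree_scope {degree_scope!r}")
    nodes = pd.DataFrame(
        {
            "tf": sorted(sub.nodes),
            "direction": [directions.get(t, "up") for t in sorted(sub.nodes)],
            "degree": [deg[t] for t in sorted(sub.nodes)],
        }
    )
    key = sorted(t for t, d in deg.items() if d > degree_threshold)
    return RegulatoryNetwork(graph=sub, nodes=nodes, key_regulators=key)
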