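import numpy as np
import pandas as pd
import pytest

from neurodyn.synthetic import SimConfig, simulate_all


def make_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=10000, width=(20, 200)):
    """Random possibly-overlapping peak table."""
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, max_pos, size=n)
    w = rng.integers(width[0], width[1], size=n)
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": start + w})
    df["name"] = [f"p{i}" for i in range(n)]
    df["summit"] = (df["end"] - df["start"]) // 2
    return df


def overlaps(p, q) -> bool:
    """Half-open interval overlap of two peak rows (>= 1 bp shared)."""
    return p["chrom"] == q["chrom"] and p["start"] < q["end"] and q["start"] < p["end"]


def brute_overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """O(n^2) pairwise-overlap oracle."""
    out = np.zeros(len(query), dtype=bool)
    for i, (_, p) in enumerate(query.iterrows()):
        out[i] = any(overlaps(p, q) for _, q in subject.iterrows())
    return out


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_peaks_per_stage=60,
        cells_per_subpop=8,
        chrom_length=400_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_dataset(small_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return simulate_all(small_cfg, out), out
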