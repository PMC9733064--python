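import numpy as np
import pandas as pd
import pytest

from cfhotspot import WindowGrid, generate_windows


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_fragments():
    """Five fragments on two chromosomes with known coordinates."""
    rows = [
        ("chr1", 100, 266, 166, 60.0),
        ("chr1", 150, 310, 160, 60.0),
        ("chr1", 400, 560, 160, 60.0),
        ("chr2", 120, 300, 180, 60.0),
        ("chr2", 500, 640, 140, 60.0),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length", "mapq"])


@pytest.fixture
def small_grids():
    return generate_windows({"chr1": 1000, "chr2": 1000}, width=200, step=20)


def brute_force_ifs(frags: pd.DataFrame, grid: WindowGrid, chrom: str):
    """Independent per-fragment / per-window double loop for IFS."""
    sub = frags[frags["chrom"] == chrom]
    L = sub["length"].mean()
    n = np.zeros(len(grid), dtype=int)
    lensum = np.zeros(len(grid))
    for frag in sub.itertuples(index=False):
        mid = (frag.start + frag.end) // 2
        for j, ws in enumerate(grid.starts):
            if ws <= mid < ws + grid.width:
                n[j] += 1
                lensum[j] += frag.length
    ifs = np.zeros(len(grid))
    nz = n > 0
    ifs[nz] = n[nz] * (1.0 + (lensum[nz] / n[nz]) / L)
    return n, ifs
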