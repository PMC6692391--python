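import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20190813)


@pytest.fixture
def summary_table():
    """Small sleepiness summary-statistics table with mixed effect signs."""
    return pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4"],
        "EA": ["A", "C", "G", "T"],
        "OA": ["G", "T", "A", "C"],
        "EAF": [0.3, 0.6, 0.25, 0.5],
        "BETA": [0.02, -0.015, 0.01, -0.03],
        "SE": [0.005, 0.004, 0.002, 0.006],
    }).set_index("SNP")


def brute_silhouette(D, labels):
    """Definition-level silhouette oracle (independent of the package)."""
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    out = np.zeros(len(labels))
    for i in range(len(labels)):
        mine = [j for j in range(len(labels))
                if labels[j] == labels[i] and j != i]
        if not mine:
            continue
        a = sum(D[i, j] for j in mine) / len(mine)
        b = min(
            sum(D[i, j] for j in range(len(labels)) if labels[j] == c)
            / sum(1 for j in range(len(labels)) if labels[j] == c)
            for c in set(labels) if c != labels[i]
        )
        out[i] = (b - a) / max(a, b)
    return out
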