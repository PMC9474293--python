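import numpy as np
import pytest

from insulome import io, motifs


@pytest.fixture(scope="session")
def ctcf_pfm():
    return io.load_ctcf_pfm()


@pytest.fixture(scope="session")
def ctcf_pwm(ctcf_pfm):
    return motifs.build_pwm(ctcf_pfm)


@pytest.fixture
def acgg_pwm():
    """A sharp non-palindromic 4-position PWM whose consensus is ACGG."""
    counts = np.array([
        [96, 1, 2, 1],
        [1, 96, 2, 1],
        [2, 1, 96, 1],
        [1, 2, 96, 1],
    ], dtype=float)
    pfm = io.PositionFrequencyMatrix("ACGGtest", counts)
    return motifs.build_pwm(pfm, pseudocount=0.4)


def brute_force_scan(pwm, seq):
    """Independent per-window scorer used as the scanning oracle.

    Returns {(start, strand): score} for every clean window on both strands.
    """
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(pwm)
    seq = seq.upper()
    out = {}
    for start in range(len(seq) - L + 1):
        window = seq[start:start + L]
        if any(b not in idx for b in window):
            continue
        out[(start, "+")] = sum(pwm.log_odds[i, idx[b]]
                                for i, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        out[(start, "-")] = sum(pwm.log_odds[i, idx[b]]
                                for i, b in enumerate(rc))
    return out
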