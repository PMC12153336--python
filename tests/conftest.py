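import numpy as np
import pytest

from igcall import default_reference_pair, simulate_cells, simulate_reads


@pytest.fixture(scope="session")
def panels():
    """The default hg38-like / T2T-like panel pair."""
    return default_reference_pair(seed=0)


@pytest.fixture(scope="session")
def small_cells():
    return simulate_cells(
        60,
        {"IGHG1": 0.4, "IGHG2": 0.4, "IGHA1": 0.1, "IGHA2": 0.1},
        doublet_rate=0.05,
        libsize_log_mean=4.5,
        libsize_log_sd=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reads(panels, small_cells):
    _, panel_b = panels
    return simulate_reads(panel_b, small_cells, read_length=90, seed=12)


def brute_force_best(read, regions, max_mismatch):
    """Independent exhaustive scan: per region the best (offset, mismatches),
    then the unique-best-gene decision, written without the package's
    vectorised machinery."""
    placements = []
    for region in regions:
        seq = region.seq
        for off in range(len(seq) - len(read) + 1):
            mm = sum(1 for a, b in zip(read, seq[off : off + len(read)]) if a != b)
            if mm <= max_mismatch:
                placements.append((mm, region.gene_at(off), off))
    if not placements:
        return ("unmapped", None, None)
    best = min(p[0] for p in placements)
    tied = [p for p in placements if p[0] == best]
    genes = {g for _, g, _ in tied}
    if len(genes) > 1:
        return ("discarded_multimap", None, None)
    return ("effective", tied[0][1], best)


@pytest.fixture(scope="session")
def brute_assign():
    return brute_force_best


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
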