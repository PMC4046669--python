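import numpy as np
import pytest

import nucdyn as nd


@pytest.fixture(scope="session")
def default_dataset():
    """One moderately sized two-condition dataset at generator defaults.

    Shared across test modules; 100 kb, 20 genes, 50x coverage.
    """
    cfg = nd.SimConfig(chrom_length=100_000, n_genes=20, seed=3, coverage=50)
    genome, genes, chromatin, reads = nd.simulate_dataset(cfg, ["meiosis", "mitosis"])
    return {"config": cfg, "genome": genome, "genes": genes,
            "chromatin": chromatin, "reads": reads}


@pytest.fixture(scope="session")
def default_tracks(default_dataset):
    out = {}
    for cond, rs in default_dataset["reads"].items():
        track, shift = nd.track_from_reads(rs, condition=cond)
        out[cond] = {"track": track, "shift": shift,
                     "calls": nd.call_peaks(track), "ndrs": nd.call_ndrs(track)}
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(arrays, **meta) -> nd.OccupancyTrack:
    """Wrap plain per-chromosome arrays as an OccupancyTrack (no smoothing)."""
    return nd.OccupancyTrack(data={c: np.asarray(v, dtype=float)
                                   for c, v in arrays.items()}, **meta)
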