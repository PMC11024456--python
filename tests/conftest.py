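import numpy as np
import pandas as pd
import pytest

from metadiet import ReplicateTable, SimConfig, default_markers, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by read-only tests."""
    return simulate_study(SimConfig(n_per_cell=2, seed=7))


@pytest.fixture
def tiny_table():
    """3 samples x 2 replicates x 3 MOTUs with hand-set counts."""
    counts = pd.DataFrame(
        [[10, 0, 0], [8, 2, 0],
         [0, 10, 0], [0, 8, 2],
         [0, 0, 10], [2, 0, 8]],
        index=["s1_R1", "s1_R2", "s2_R1", "s2_R2", "s3_R1", "s3_R2"],
        columns=["m1", "m2", "m3"],
    )
    rts = {r: r.split("_")[0] for r in counts.index}
    return ReplicateTable(counts=counts, replicate_to_sample=rts, marker_id="Sper01")


def qc_spike_config(seed: int) -> SimConfig:
    """Single-marker study used by replicate-QC recovery tests:
    20 samples x 3 replicates, one spiked outlier replicate per 10 samples."""
    return SimConfig(
        n_per_cell=5, species=("bank",), seed=seed,
        markers={"Sper01": default_markers()["Sper01"]},
        outlier_replicate_rate=1 / 30, tag_jump_rate=0.0,
        replicate_failure_rate=0.0, reads_mean=1000.0,
        junk_motus_per_marker=0,
    )


def no_artifact_config(seed: int, **kw) -> SimConfig:
    """Clean simulator: no outliers, failures, tag jumps or marker bias."""
    base = dict(marker_bias_sd=0.0, tag_jump_rate=0.0,
                outlier_replicate_rate=0.0, replicate_failure_rate=0.0)
    base.update(kw)
    return SimConfig(seed=seed, **base)
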