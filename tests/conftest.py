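import numpy as np
import pytest

from zingdiv import (
    SimulationConfig,
    TranscriptModel,
    simulate_divergence,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_transcripts=60, mean_length=500, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    """A small complete simulated study written to disk once per session."""
    from zingdiv import simulate_study

    outdir = tmp_path_factory.mktemp("study")
    manifest = simulate_study(small_config, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def divergence_sim():
    """Pure-divergence dataset (no polymorphism) with ground truth."""
    cfg = SimulationConfig(
        n_transcripts=300, mean_length=900, cds_fraction=0.7,
        mu=6.5e-9, T_div=2.4e5, theta_poly=0.0, seed=5,
    )
    models = simulate_reference(cfg)
    snps, truth = simulate_divergence(models, cfg)
    return models, snps, truth, cfg


def random_alignment(rng: np.random.Generator, n_seqs: int, n_cols: int,
                     gap_prob: float = 0.05) -> list[str]:
    bases = np.array(list("ACGT-"))
    p = [(1 - gap_prob) / 4] * 4 + [gap_prob]
    return ["".join(rng.choice(bases, size=n_cols, p=p)) for _ in range(n_seqs)]


def make_model(seq: str, cds: tuple[int, int] | None = None) -> TranscriptModel:
    if cds is None:
        return TranscriptModel("t", seq)
    return TranscriptModel("t", seq, cds[0], cds[1])
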