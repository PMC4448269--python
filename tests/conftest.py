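import pytest

from fibroprof import SimulationParams, run_study


def small_simulation_params(seed: int = 7) -> SimulationParams:
    """A fast, fully planted design used across unit tests."""
    return SimulationParams(
        n_proteins=120,
        n_exclusive_per_tissue=4,
        n_shared_per_pair=3,
        n_core=6,
        n_induced_per_tissue=3,
        n_tumor_markers=2,
        n_background=12,
        decoy_psms_per_sample=40,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return small_simulation_params()


@pytest.fixture(scope="session")
def small_study(small_params):
    """One in-memory end-to-end run on the small design."""
    return run_study(small_params)


@pytest.fixture(scope="session")
def default_studies():
    """Full-size (default-parameter) runs at three seeds, shared by the
    signature- and differential-recovery checks."""
    return {seed: run_study(SimulationParams(seed=seed)) for seed in (11, 12, 13)}
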