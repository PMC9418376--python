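import numpy as np
import pytest

from riboquant.config import FragmentationParams, SimulationConfig
from riboquant.reference import ReferenceSet, TrueMethylationProfile


def random_reference(length: int = 500, seed: int = 7, name: str = "mol") -> ReferenceSet:
    rng = np.random.default_rng(seed)
    return ReferenceSet({name: "".join(rng.choice(list("ACGT"), size=length))})


@pytest.fixture(scope="session")
def reference_500() -> ReferenceSet:
    return random_reference(500)


F_GRID_SITES = {100: 0.0, 180: 0.2, 260: 0.5, 340: 0.8, 420: 1.0}


@pytest.fixture(scope="session")
def f_grid_truth() -> TrueMethylationProfile:
    return TrueMethylationProfile.from_mapping({"mol": F_GRID_SITES})


@pytest.fixture(scope="session")
def f_grid_run(reference_500, f_grid_truth):
    """One deep simulated dataset shared by recovery/accounting tests."""
    from riboquant import ribometh as rm
    from riboquant import synthetic_data as sd

    cfg = SimulationConfig(
        seed=11,
        fragmentation=FragmentationParams(n_molecules=200_000, chunk_size=5000),
    )
    result = sd.simulate_fragmentation_reads(reference_500, f_grid_truth, cfg)
    mapping = rm.map_reads_exact(result.reads, reference_500)
    profiles = rm.count_read_ends(mapping.alignments, reference_500)
    return cfg, result, mapping, profiles
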