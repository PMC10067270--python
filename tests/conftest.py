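import numpy as np
import pytest

from epiland import (
    Landscape,
    PairwiseSpec,
    simulate_pairwise,
)


@pytest.fixture
def toy() -> Landscape:
    """2-locus landscape 00→1.0, 10→1.2, 01→1.1, 11→1.4 (ε₁₂ = 0.1)."""
    return Landscape.from_dict({"00": 1.0, "10": 1.2, "01": 1.1, "11": 1.4})


@pytest.fixture
def worked_n3() -> Landscape:
    """N=3, baseline 1, δ = (0.5, 0.3, 0.2), single interaction ε₁₂ = 0.12."""
    spec = PairwiseSpec(
        ("m1", "m2", "m3"), 1.0, (0.5, 0.3, 0.2), {("m1", "m2"): 0.12}
    )
    return simulate_pairwise(spec)


def random_pairwise_landscape(rng: np.random.Generator, n_loci: int) -> Landscape:
    """Complete pairwise-only landscape with random effects and interactions."""
    names = tuple(f"m{k + 1}" for k in range(n_loci))
    effects = rng.normal(0.0, 0.5, size=n_loci)
    interactions = {
        (names[i], names[j]): float(rng.normal(0.0, 0.2))
        for i in range(n_loci)
        for j in range(i + 1, n_loci)
    }
    spec = PairwiseSpec(names, float(rng.normal(1.0, 0.3)), tuple(effects), interactions)
    return simulate_pairwise(spec)
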