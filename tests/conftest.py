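import numpy as np
import pytest

from codivkit.snv_profiles import AlleleCountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230217)


def random_allele_counts(
    rng: np.random.Generator,
    n_positions: int = 40,
    n_samples: int = 6,
    depth: float = 40.0,
    variant_fraction: float = 0.3,
) -> AlleleCountMatrix:
    """Random allele-count fixture: most positions near-monomorphic, a
    fraction carrying an intermediate-frequency alternate allele in a random
    subset of samples."""
    counts = np.zeros((n_positions, n_samples, 4), dtype=np.int64)
    ref = rng.integers(0, 4, size=n_positions)
    for i in range(n_positions):
        is_variant = rng.random() < variant_fraction
        alt = (ref[i] + rng.integers(1, 4)) % 4
        carriers = rng.random(n_samples) < 0.5
        for j in range(n_samples):
            cov = rng.poisson(depth)
            if cov == 0:
                continue
            f = rng.uniform(0.05, 0.5) if (is_variant and carriers[j]) else 0.0
            k_alt = rng.binomial(cov, f)
            counts[i, j, ref[i]] = cov - k_alt
            counts[i, j, alt] += k_alt
    return AlleleCountMatrix(
        positions=np.arange(n_positions),
        samples=[f"s{j}" for j in range(n_samples)],
        counts=counts,
    )
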