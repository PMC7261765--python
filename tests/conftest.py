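import numpy as np
import pytest

import faebm
from faebm.data_model import RegionSet
from faebm.mixtures import MixtureFit


@pytest.fixture(scope="session")
def combined_set():
    return faebm.canonical_region_set("combined")


@pytest.fixture(scope="session")
def split_set():
    return faebm.canonical_region_set("split")


def make_region_set(n: int) -> RegionSet:
    return RegionSet(labels=tuple(f"R{i}" for i in range(n)))


def make_cohort(
    n_regions: int = 5,
    effect_sds: float = 3.0,
    n_patients: int = 150,
    n_controls: int = 130,
    seed: int = 0,
    **kwargs,
):
    """Synthetic cohort with a seed-determined random true ordering."""
    rs = make_region_set(n_regions)
    params = faebm.default_fa_params(rs, effect_sds=effect_sds)
    rng = np.random.default_rng(seed)
    config = faebm.SimulationConfig(
        region_set=rs,
        true_ordering=rng.permutation(n_regions),
        n_patients=n_patients,
        n_controls=n_controls,
        params=params,
        seed=seed,
        **kwargs,
    )
    return faebm.generate_cohort(config)


def flat_fits(n: int) -> list[MixtureFit]:
    """Mixtures whose two components coincide: every ordering and stage
    has identical likelihood (a fully symmetric model)."""
    return [
        MixtureFit(mu_h=0.5, sigma_h=0.05, mu_d=0.5, sigma_d=0.05, theta=0.5)
        for _ in range(n)
    ]


def separated_fits(n: int, gap_sds: float = 4.0) -> list[MixtureFit]:
    """Well-separated per-region mixtures with known parameters."""
    return [
        MixtureFit(
            mu_h=0.55, sigma_h=0.02, mu_d=0.55 - gap_sds * 0.02, sigma_d=0.02,
            theta=0.5,
        )
        for _ in range(n)
    ]


def normalized_kendall_distance(a, b) -> float:
    """Fraction of discordant pairs between two permutations (0 = equal,
    1 = reversed)."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    rank_a = np.empty(n, dtype=int)
    rank_a[a] = np.arange(n)
    rank_b = np.empty(n, dtype=int)
    rank_b[b] = np.arange(n)
    disc = sum(
        (rank_a[i] - rank_a[j]) * (rank_b[i] - rank_b[j]) < 0
        for i in range(n)
        for j in range(i + 1, n)
    )
    return disc / (n * (n - 1) / 2)
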