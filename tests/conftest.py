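import numpy as np
import pytest

import orichrom as oc


@pytest.fixture(scope="session")
def noise_free_data():
    """60 noise-free planted origins: (tracks, acs_list, truths)."""
    arch = oc.ArchParams(
        noise_sd=0.0, na_fraction=0.0, dup_fraction=0.0, jitter_growth=0.0
    )
    return oc.generate_occupancy(60, arch, seed=101)


@pytest.fixture(scope="session")
def noise_free_matrix(noise_free_data):
    tracks, acs_list, _ = noise_free_data
    return oc.build_aligned_matrix(tracks, acs_list)


def gaussian_profile(positions, centers, amp=1.0, sd=50.0, trough=None):
    """Sum of Gaussian bumps, optionally minus a central cosine trough."""
    positions = np.asarray(positions, dtype=float)
    out = np.zeros(len(positions))
    for c in centers:
        out += amp * np.exp(-0.5 * ((positions - c) / sd) ** 2)
    if trough is not None:
        depth, radius = trough
        x = np.clip(positions / radius, -1, 1)
        out -= depth * np.cos(np.pi * x / 2) ** 2
    return out


@pytest.fixture(scope="session")
def bump_profile_builder():
    return gaussian_profile
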