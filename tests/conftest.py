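import pytest

import musclenet as mn


@pytest.fixture(scope="session")
def fixtures():
    return mn.fixture_library()


@pytest.fixture(scope="session")
def small_body():
    """Seeded 30x40 synthetic body shared by read-only tests."""
    return mn.generate_body(mn.BodySpec(seed=7))


@pytest.fixture(scope="session")
def small_impacts(small_body):
    h, emb, _ = small_body
    return mn.impact_all(h, emb, "steady_state_4d")


def random_incidence(rng, n_bones, n_muscles, p=0.4):
    """Random valid 0/1 incidence with no isolated bones or muscles."""
    while True:
        inc = (rng.random((n_bones, n_muscles)) < p).astype(int)
        if inc.sum(axis=0).min() >= 1 and inc.sum(axis=1).min() >= 1:
            return inc
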