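import numpy as np
import pytest

from sfacv import features, sfa, toysim


@pytest.fixture(scope="session")
def flip_dihedrals() -> features.DihedralSeries:
    """Seeded rare-flip dihedral fixture: 1 slow flip + 9 fast angles."""
    return toysim.two_state_dihedral(n=100000, seed=7)


@pytest.fixture(scope="session")
def flip_features(flip_dihedrals) -> features.FeatureSeries:
    return features.sincos_expand(flip_dihedrals)


@pytest.fixture(scope="session")
def flip_model(flip_features) -> sfa.SFAModel:
    """Order-1, 2-component model fitted on the flip fixture."""
    return sfa.fit(flip_features, order=1, n_components=2)


@pytest.fixture(scope="session")
def random_features() -> features.FeatureSeries:
    """Smooth correlated random series with two segments."""
    rng = np.random.default_rng(42)
    T, J = 4000, 6
    raw = rng.normal(size=(T, J))
    smooth = np.cumsum(raw, axis=0) / np.sqrt(np.arange(1, T + 1))[:, None]
    mix = rng.normal(size=(J, J))
    return features.FeatureSeries(
        values=smooth @ mix, names=[f"f{j}" for j in range(J)],
        segment_starts=np.array([0, 2500]))
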