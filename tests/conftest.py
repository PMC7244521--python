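import numpy as np
import pytest

from costark import ChargeEnvironment, COProbe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def probe():
    """Probe along x: C at origin, O at 1.14 Å."""
    return COProbe(np.zeros(3), np.array([1.14, 0.0, 0.0]))


def random_environment(rng, n_atoms, r_min=2.0, r_max=20.0):
    """Random charge scene clear of the origin-centred probe region."""
    directions = rng.normal(size=(n_atoms, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rng.uniform(r_min, r_max, size=n_atoms)
    positions = directions * radii[:, None]
    charges = rng.normal(0.0, 0.4, size=n_atoms)
    return ChargeEnvironment(positions, charges)


def naive_potential(env, point, eps_eff=1.0):
    """Independent oracle: explicit double loop over residues and atoms."""
    total = 0.0
    for res in np.unique(env.residue_indices):
        for j in np.flatnonzero(env.residue_indices == res):
            r = np.sqrt(sum((point[k] - env.positions[j, k]) ** 2
                            for k in range(3)))
            total += env.charges[j] / r
    return total / eps_eff
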