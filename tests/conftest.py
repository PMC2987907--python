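import numpy as np
import pytest

from foldtherm.io import Structure
from foldtherm.remd import ToyPotential, geometric_ladder, run_toy_remd
from foldtherm.synth import TwoStateParams


def ideal_helix(n_residues: int = 28, start: int = 1) -> Structure:
    """An ideal α-helical Cα trace: 2.3 Å radius, 1.5 Å rise, 100°/residue."""
    k = np.arange(n_residues)
    theta = np.deg2rad(100.0) * k
    coords = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k]
    )
    return Structure(residue_numbers=np.arange(start, start + n_residues),
                     coords=coords, label="ideal_helix")


@pytest.fixture(scope="session")
def reference():
    return ideal_helix()


@pytest.fixture(scope="session")
def truth():
    """Default two-state ground truth (CD-derived thermodynamics)."""
    return TwoStateParams()


@pytest.fixture(scope="session")
def toy_remd_run():
    """A converged double-well replica-exchange run (h = 2 kcal/mol).

    Session-scoped: shared by the engine tests and the barrier-recovery
    acceptance check.
    """
    potential = ToyPotential(barrier=2.0)
    ladder = geometric_ladder(300.0, 600.0, 8)
    result = run_toy_remd(
        potential, ladder, n_steps=300_000, exchange_interval=100,
        dt=0.01, friction=1.0, seed=2, sample_interval=10,
    )
    return potential, result
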