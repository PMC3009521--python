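import numpy as np
import pytest

from penkit import (EnergyMatrix, ResidueID, SyntheticSpec, build_pen,
                    generate_synthetic_matrix, generate_toy_ensemble)


def make_matrix(total, lj=None, coulomb=None):
    """EnergyMatrix over generic residues from (n, n) arrays/lists."""
    total = None if total is None else np.asarray(total, dtype=float)
    n = len(total) if total is not None else len(lj)
    residues = [ResidueID("A", i + 1, None, "ALA") for i in range(n)]
    return EnergyMatrix(residues=residues, total=total, lj=lj, coulomb=coulomb)


@pytest.fixture
def bimodal_pen():
    """PEN over the default synthetic landscape (LJ mode -5, elec mode -27)."""
    return build_pen(generate_synthetic_matrix(SyntheticSpec(seed=7)))


@pytest.fixture
def toy_ensemble():
    return generate_toy_ensemble(n_residues=8, n_frames=3, jitter_sd=0.01,
                                 seed=42)
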