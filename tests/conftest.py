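import numpy as np
import pytest

from nanodent.crystal_builder import (
    UnitCell,
    add_vacuum_and_template,
    make_toy_crystal,
)


@pytest.fixture(scope="session")
def lj_fcc_bulk():
    """Bulk-periodic LJ fcc crystal at its 0 K lattice constant (256 atoms)."""
    slab, ff = make_toy_crystal("lj_fcc", (4, 4, 4), seed=0)
    return slab, ff


@pytest.fixture()
def lj_fcc_slab(lj_fcc_bulk):
    """Fresh indentation slab (vacuum + frozen template) per test."""
    bulk, ff = lj_fcc_bulk
    return add_vacuum_and_template(bulk.copy(), 4.0, 2), ff


@pytest.fixture(scope="session")
def simple_cubic_cell():
    return UnitCell(
        lattice_vectors=np.eye(3) * 0.5,
        species=["X"],
        frac_coords=np.zeros((1, 3)),
        charges=np.zeros(1),
        masses=np.ones(1) * 10.0,
    )
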