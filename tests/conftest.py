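import numpy as np
import pytest

from deerdock import spin_labeling as sl
from deerdock.structures import Structure
from deerdock.synthetic_data import ToySpec, make_toy_protomer


RECOVERY_SITES = (("A", 3), ("A", 12), ("A", 25), ("A", 38), ("A", 55))


def single_atom_structure(position, element="C", name="CA", res_id=1, chain="A"):
    return Structure(
        chain_ids=np.array([chain]),
        res_ids=np.array([res_id]),
        res_names=np.array(["ALA"]),
        atom_names=np.array([name]),
        elements=np.array([element]),
        coords=np.asarray(position, dtype=float).reshape(1, 3),
    )


@pytest.fixture(scope="session")
def toy_protomer():
    return make_toy_protomer(ToySpec(seed=1, label_sites=RECOVERY_SITES))


@pytest.fixture(scope="session")
def toy_ensembles(toy_protomer):
    return {
        site: sl.attach_label(toy_protomer, site, seed=31 * site[1])
        for site in RECOVERY_SITES
    }


@pytest.fixture(scope="session")
def r_grid():
    from deerdock.deer_forward import default_r_grid

    return default_r_grid(1.0, 8.0, 0.02)
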