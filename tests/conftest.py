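import numpy as np
import pytest

import voxbind as vb
from voxbind.pocket import center_on_ligand, extract_pocket
from voxbind.voxelize import GridSpec


def pdb_line(record, serial, name, res_name, chain, res_id, x, y, z,
             element=""):
    """Format one fixed-column PDB coordinate line."""
    aname = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {aname:<4} {res_name:<3} {chain}{res_id:>4}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


@pytest.fixture(scope="session")
def small_spec():
    """Compact grid for fast network tests (21 voxels per side)."""
    return GridSpec(box_size=21.0)


@pytest.fixture(scope="session")
def synthetic_record():
    """One deterministic synthetic complex (seed 7)."""
    _, rec = vb.generate_complex(vb.SyntheticParams(seed=7))
    return rec


@pytest.fixture(scope="session")
def synthetic_pocket(synthetic_record):
    return center_on_ligand(extract_pocket(synthetic_record.pair, 10.0))


@pytest.fixture(scope="session")
def small_dataset():
    """Twelve labelled synthetic complexes with centred pockets."""
    recs = vb.generate_dataset(12, seed=3)
    pockets = [center_on_ligand(extract_pocket(r.pair, 10.0)) for r in recs]
    return recs, pockets
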