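import numpy as np
import pandas as pd
import pytest

import funcsites as fs
from funcsites.structure import per_position_wcn


def make_pdb(records):
    """Minimal PDB text from (serial, atom, resname, chain, resid, x, y, z)."""
    lines = [
        f"ATOM  {ser:>5} {atom:^4}{res:>4} {ch}{rid:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {atom[0]}"
        for ser, atom, res, ch, rid, x, y, z in records
    ]
    return "\n".join(lines) + "\nEND\n"


@pytest.fixture
def three_residue_pdb():
    return make_pdb(
        [
            (1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            (2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
            (3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0),
        ]
    )


@pytest.fixture(scope="session")
def strong_fixture():
    """Strong-separation synthetic dataset: 220 positions, 4180 variants."""
    spec = fs.FixtureSpec(n_residues=220, seed=11)
    return fs.make_fixture(spec)


@pytest.fixture(scope="session")
def strong_tables(strong_fixture):
    fx = strong_fixture
    wcn = per_position_wcn(fx["structure"])
    table = fs.assemble_features(fx["ddg"], fx["dde"], wcn)
    labelling = fs.label_mave(fx["mave"], seed=7)
    return {"wcn": wcn, "table": table, "labelling": labelling}


@pytest.fixture(scope="session")
def trained(strong_fixture, strong_tables):
    model = fs.VariantClassifierModel.from_tables(
        strong_tables["table"], strong_tables["labelling"].data, seed=5
    )
    results = model.fit()
    return {"model": model, "results": results}


@pytest.fixture
def balanced_features():
    """4 well-separated Gaussian clusters in the 8-feature space, n=1200."""
    rng = np.random.default_rng(42)
    centers = {
        "WT_like": [0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.0, 5.0],
        "total_loss": [4.0, -5.0, 4.0, -5.0, 4.0, -5.0, 0.0, 9.0],
        "SBI": [0.5, -5.0, 0.5, -5.0, 0.5, -5.0, 0.0, 7.0],
        "low_abundance_high_activity": [4.0, -0.5, 4.0, -0.5, 4.0, -0.5, 0.0, 6.0],
    }
    rows, labels = [], []
    for cls, mu in centers.items():
        rows.append(rng.normal(mu, 0.25, size=(300, 8)))
        labels += [cls] * 300
    X = pd.DataFrame(np.vstack(rows), columns=fs.FEATURE_NAMES)
    order = rng.permutation(len(X))
    return X.iloc[order].reset_index(drop=True), [labels[i] for i in order]
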