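import numpy as np
import pytest

from fqdesign import chem, fields, pls, synth


@pytest.fixture(scope="session")
def quinolone_refit():
    """Full fixture-set refit: prepare, align, fields, component scan, fit.

    Computed once per session; shared by unit and acceptance tests.
    """
    mols = synth.load_fixture("quinolones.smi")
    prepared = [chem.prepare_molecule(m, seed=2020) for m in mols]
    template = {m.id: m for m in prepared}["Trovafloxacin"]
    aset = chem.align_set(prepared, template)
    grid = fields.build_grid(aset, spacing=2.0, margin=4.0)
    desc = fields.compute_descriptor_matrix(aset, grid, filter_sd=0.05)
    table = synth.load_fixture("table1").set_index("id").loc[desc.molecule_ids]
    table = table.reset_index()
    train = (table["set"] == "train").to_numpy()
    X = desc.assemble(scaled=True)
    y = table["experimental"].to_numpy(dtype=float)
    cv = pls.select_components(X[train], y[train], 8)
    model = pls.fit_pls(X[train], y[train], cv.chosen_n)
    return {
        "prepared": prepared,
        "aset": aset,
        "grid": grid,
        "desc": desc,
        "table": table,
        "train": train,
        "X": X,
        "y": y,
        "cv": cv,
        "model": model,
    }


@pytest.fixture(scope="session")
def toy_noiseless():
    """Small noiseless planted-coefficient set (exact linear activities)."""
    return synth.make_toy_set(n_mol=12, n_atoms=6, noise_sd=0.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


@pytest.fixture(scope="session")
def prepared_trova():
    m = synth.load_fixture("quinolones.smi")[-1]
    assert m.id == "Trovafloxacin"
    return chem.prepare_molecule(m, seed=7)
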