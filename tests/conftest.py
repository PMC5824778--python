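import pytest

from transatlasdb import Store, fixtures


@pytest.fixture(scope="session")
def optn_tree(tmp_path_factory):
    """Generated two-sample use-case tree plus its bookkeeping ledger."""
    outdir = tmp_path_factory.mktemp("optn_tree")
    ledger = fixtures.generate_optn_scenario(1, str(outdir))
    return outdir, ledger


@pytest.fixture(scope="session")
def optn_store(tmp_path_factory, optn_tree):
    """Installed store with the two-sample scenario fully imported."""
    outdir, ledger = optn_tree
    root = tmp_path_factory.mktemp("optn_store")
    store = Store.install(str(root / "store"))
    reports = fixtures.import_study(store, str(outdir))
    assert all(r.ok for r in reports.values())
    return store, ledger


@pytest.fixture(scope="session")
def study_tree(tmp_path_factory):
    """Four-sample, two-organism study rotating all quantifier dialects."""
    outdir = tmp_path_factory.mktemp("study_tree")
    ledger = fixtures.generate_study(fixtures.StudyConfig(seed=3), str(outdir))
    return outdir, ledger


@pytest.fixture(scope="session")
def study_store(tmp_path_factory, study_tree):
    outdir, ledger = study_tree
    root = tmp_path_factory.mktemp("study_store")
    store = Store.install(str(root / "store"))
    reports = fixtures.import_study(store, str(outdir))
    assert all(r.ok for r in reports.values())
    return store, ledger
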