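import pytest

from mirkit import fixtures as fx


@pytest.fixture(scope="session")
def default_spec():
    return fx.FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def snapshot_fixture(tmp_path_factory, default_spec):
    out = tmp_path_factory.mktemp("snap_default")
    return fx.generate_snapshot(default_spec, out)


@pytest.fixture(scope="session")
def snapshot(snapshot_fixture):
    return snapshot_fixture.load()


@pytest.fixture(scope="session")
def study_spec():
    """Spec sized for the end-to-end integration study: enough conserved
    target genes to plant 40 true targets among 100 significant mRNAs."""
    return fx.FixtureSpec(
        seed=11,
        n_genes=500,
        background_rate=0.002,
        n_conserved_pairs=60,
        n_sig_genes=100,
        target_enrichment=0.4,
    )


@pytest.fixture(scope="session")
def study_env(tmp_path_factory, study_spec):
    base = tmp_path_factory.mktemp("study")
    snapfix = fx.generate_snapshot(study_spec, base / "snap")
    expfix = fx.generate_experiment(study_spec, base / "snap", base / "exp")
    return {"spec": study_spec, "snapshot": snapfix, "experiment": expfix, "base": base}
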