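import pytest

from vsfuse import BenchmarkSpec, MoleculeRecord, compute_properties, make_active_series, make_decoy_pool


def record(smiles: str, rec_id: str = "X", with_props: bool = False) -> MoleculeRecord:
    from rdkit import Chem

    rec = MoleculeRecord(id=rec_id, structure=Chem.CanonSmiles(smiles))
    return compute_properties(rec) if with_props else rec


@pytest.fixture(scope="session")
def small_benchmark():
    """A scaled-down planted benchmark: 10 actives, 60 eligible decoys."""
    spec = BenchmarkSpec(n_actives=10, decoy_ratio=6, seed=11)
    actives, activities = make_active_series(spec)
    decoys = make_decoy_pool(spec, actives)
    return actives, decoys, activities, spec


@pytest.fixture(scope="session")
def default_benchmark_sets():
    """The canonical-shape benchmark (28 actives + 1170 decoys, N=1198)."""
    from vsfuse import default_benchmark

    actives, decoys, activities = default_benchmark(seed=5)
    return actives, decoys, activities
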