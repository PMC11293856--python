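import numpy as np
import pytest

import admkit


@pytest.fixture(scope="session")
def standard_world():
    """The standard synthetic fixture: 80 samples, 50 taxa, 20 planted positive pairs."""
    spec = admkit.SyntheticSpec(seed=11)
    meta = admkit.generate_sample_sites(spec)
    env = admkit.generate_env(spec, meta)
    table, truth = admkit.generate_abundances(spec, env, meta)
    filtered = admkit.filter_by_occurrence(table, 10)
    clr = admkit.clr_transform(admkit.impute_zeros(filtered, 0.65))
    return {
        "spec": spec,
        "meta": meta,
        "env": env,
        "table": table,
        "truth": truth,
        "filtered": filtered,
        "clr": clr,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_clr_rows(rng, n_samples, n_taxa):
    """Random positive compositions passed through the package CLR."""
    raw = rng.lognormal(0.0, 1.0, (n_samples, n_taxa))
    table = admkit.AbundanceTable(
        raw, [f"s{i}" for i in range(n_samples)], [f"t{j}" for j in range(n_taxa)]
    )
    return admkit.clr_transform(table)
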