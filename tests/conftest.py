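import numpy as np
import pandas as pd
import pytest

import noiseqtl as nq


@pytest.fixture(scope="session")
def gmap5():
    """Default five-chromosome map (90 cM, 5 cM marker spacing)."""
    return nq.build_default_map()


@pytest.fixture(scope="session")
def geno316(gmap5):
    """316-line reciprocal RIL population on the default map."""
    return nq.simulate_ril_genotypes(gmap5, nq.DesignSpec(n_lines=316, seed=11))


@pytest.fixture(scope="session")
def grid316(gmap5, geno316):
    return nq.genotype_probabilities(gmap5, geno316, step=1.0)


@pytest.fixture(scope="session")
def design316():
    return nq.DesignSpec(n_lines=316, seed=11)


@pytest.fixture()
def tiny_obs():
    """Two lines x two experiments x two blocks, one phenotype, hand values."""
    rows = []
    values = {
        ("L1", "exp1"): [1.0, 2.0, 3.0],
        ("L1", "exp2"): [2.0, 2.0, 2.0],
        ("L2", "exp1"): [10.0, 20.0, 30.0],
        ("L2", "exp2"): [5.0, 5.0, 5.0],
    }
    for (line, exp), vals in values.items():
        for b, v in enumerate(vals):
            rows.append((line, exp, f"{exp}_b{b}", "pheno", v))
    return pd.DataFrame(rows, columns=["line", "experiment", "block", "phenotype", "value"])
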