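import itertools

import numpy as np
import pandas as pd
import pytest

from kirtyper.arms import PatternMatrix
from kirtyper.interpret import GenotypeCall, HaplotypeModel, expected_pattern
from kirtyper import io as kio


@pytest.fixture(scope="session")
def table1():
    """Packaged kit reactions + control primer pair."""
    return kio.read_primer_table()


@pytest.fixture(scope="session")
def curated_kb():
    return kio.load_curated_kb()


from kirtyper.synth import random_toy_kb as make_toy_kb  # noqa: E402


def brute_force_candidates(observed_bands: dict, pm: PatternMatrix, model: HaplotypeModel):
    """Independent oracle: direct loops over all model genotypes, comparing
    expected band dictionaries on the observed reactions."""
    out = []
    for dl23 in itertools.combinations_with_replacement(model.dl23_alleles, 2):
        dl1_options = [()]
        dl1_options += [(a,) for a in model.dl1_alleles]
        dl1_options += list(
            itertools.combinations_with_replacement(model.dl1_alleles, 2)
        )
        for dl1 in dl1_options:
            g = GenotypeCall(dl1=dl1, dl23=dl23)
            exp = expected_pattern(g, pm).bands
            if all(exp[r] == v for r, v in observed_bands.items() if r in exp):
                out.append(g)
    return sorted(out)
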