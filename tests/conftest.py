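import numpy as np
import pandas as pd
import pytest

from multibin_alpha.io import Clonotype, CohortTable, Repertoire


@pytest.fixture
def toy_clonotypes():
    return [
        Clonotype("TRBV5-1", f"CASSL{chr(65 + i)}GETQYF", "TRBJ2-5")
        for i in range(10)
    ]


@pytest.fixture
def toy_repertoire(toy_clonotypes):
    counts = {ct: i + 1 for i, ct in enumerate(toy_clonotypes)}
    return Repertoire("S1", counts)


def make_cohort(library_sizes, covariate=None, seed=0):
    """CohortTable from a library-size vector and an optional covariate."""
    ids = [f"S{i:03d}" for i in range(len(library_sizes))]
    df = pd.DataFrame(
        {"sample_id": ids, "library_size": list(library_sizes)}
    )
    if covariate is not None:
        df["group"] = list(covariate)
    return CohortTable(df)


def make_repertoire(sample_id, counts, clonotypes=None):
    """Repertoire from a plain count vector with auto-generated clonotypes."""
    counts = np.asarray(counts)
    if clonotypes is None:
        clonotypes = [
            Clonotype("TRBV7-9", f"CASS{sample_id}{i:04d}F", "TRBJ1-1")
            for i in range(len(counts))
        ]
    return Repertoire(
        sample_id, {ct: int(c) for ct, c in zip(clonotypes, counts) if c > 0}
    )
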