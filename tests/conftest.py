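import numpy as np
import pytest

import sortseq_footprint as sf


@pytest.fixture(scope="session")
def reference() -> sf.ReferenceAmplicon:
    return sf.bmo_reference()


@pytest.fixture(scope="session")
def planted_model(reference) -> sf.ExpressionModel:
    return sf.default_expression_model(reference)


@pytest.fixture(scope="session")
def mutate(reference):
    """Return the reference sequence with the given (position, base) changes."""

    def _mutate(*substitutions: tuple[int, str], sequence: str | None = None) -> str:
        seq = list(sequence if sequence is not None else reference.sequence)
        for pos, base in substitutions:
            seq[pos - 1] = base
        return "".join(seq)

    return _mutate


@pytest.fixture(scope="session")
def default_library(reference) -> sf.VariantLibrary:
    """The study-condition epPCR library: default model, 10,000 variants."""
    return sf.mutagenize_library(reference, sf.EpPCRModel(), 10_000, seed=1)


def make_count_matrix(rows: dict[int, tuple[int, int, int, int]]) -> sf.CountMatrix:
    """Build a CountMatrix from {position: (A, C, G, T)} with equal row sums."""
    import pandas as pd

    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list("ACGT"), dtype=np.int64
    )
    totals = df.sum(axis=1).unique()
    assert len(totals) == 1, "test matrix rows must share one total"
    return sf.CountMatrix(df, int(totals[0]))
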