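import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sigfitkit import (
    ExposureMatrix,
    MutationalCatalog,
    SignatureCatalog,
    synth_signature_catalog,
    synth_weight_table,
)
from sigfitkit.contexts import context_labels


@pytest.fixture(scope="session")
def labels():
    return list(context_labels())


@pytest.fixture(scope="session")
def peaked_ref():
    """Eight peaked (easy) synthetic signatures."""
    return synth_signature_catalog(8, concentration=0.05, seed=11)


@pytest.fixture(scope="session")
def onehot_ref(labels):
    """Four one-hot signatures on the first four contexts."""
    prof = pd.DataFrame(0.0, index=labels, columns=["H1", "H2", "H3", "H4"])
    for j, name in enumerate(prof.columns):
        prof.iloc[j, j] = 1.0
    return SignatureCatalog(prof)


@pytest.fixture(scope="session")
def weight_table(peaked_ref):
    return synth_weight_table(
        n_donors=40, signature_names=peaked_ref.names, seed=7
    )


def exposures_from(d: dict) -> ExposureMatrix:
    """Build an ExposureMatrix from {sample: {signature: weight}}."""
    return ExposureMatrix(pd.DataFrame(d).fillna(0.0))


def catalog_from_counts(labels, columns: dict) -> MutationalCatalog:
    df = pd.DataFrame(0, index=labels, columns=list(columns))
    for sid, ctx_counts in columns.items():
        for ctx, n in ctx_counts.items():
            df.loc[ctx, sid] = n
    return MutationalCatalog(df)
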