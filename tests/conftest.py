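import pandas as pd
import pytest

from nbscreen.engine import run_cohort
from nbscreen.synthetic import SimulationSpec, generate_bundle, load_bundle


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A 200-sample synthetic fixture bundle under the default conditions."""
    outdir = tmp_path_factory.mktemp("bundle")
    generate_bundle(SimulationSpec(seed=11, n_samples=200), outdir)
    return outdir


@pytest.fixture(scope="session")
def bundle(bundle_dir):
    """(samples, panel, kb, exclusion, freqs, companions, truth)."""
    return load_bundle(bundle_dir)


@pytest.fixture(scope="session")
def cohort_calls(bundle):
    samples, panel, kb, exclusion, freqs, companions, _truth = bundle
    return run_cohort(samples, panel, kb, exclusion, freqs, companions=companions)


def truth_key(row) -> tuple:
    if row.kind == "small":
        return (str(row.contig), int(row.pos), str(row.ref), str(row.alt))
    return (str(row.contig), int(row.start), int(row.end), str(row.cnv_type))


@pytest.fixture(scope="session")
def truth_frame(bundle) -> pd.DataFrame:
    return bundle[6]
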