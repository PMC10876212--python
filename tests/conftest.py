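import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lysoprof import QuantMatrix, SampleDescriptor, simulate_lysoip_experiment, to_ifot
from lysoprof.simulate import ProteomeSimParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_design(n_pairs: int = 4, n_nontag: int = 3, condition: str = "WT"):
    """IP/FT replicate pairs plus non-tag controls for one condition."""
    samples = []
    for r in range(1, n_pairs + 1):
        samples.append(
            SampleDescriptor(f"ip_{r}", "lyso_ip", "LMP1", condition, "whole_body", r)
        )
        samples.append(
            SampleDescriptor(
                f"ft_{r}", "flow_through", "LMP1", condition, "whole_body", r
            )
        )
    for r in range(1, n_nontag + 1):
        samples.append(
            SampleDescriptor(f"nt_{r}", "non_tag", "none", condition, "whole_body", r)
        )
    return samples


def make_matrix(values, samples, protein_ids=None, unit="iBAQ") -> QuantMatrix:
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i + 1:04d}" for i in range(values.shape[0])]
    df = pd.DataFrame(
        values,
        index=pd.Index(protein_ids, name="protein_id"),
        columns=[s.sample_id for s in samples],
    )
    return QuantMatrix(df, samples, unit=unit)


def random_ibaq_matrix(rng, n_proteins=20, n_pairs=3, n_nontag=2, zero_frac=0.2):
    """Random nonnegative iBAQ matrix with semantic zeros sprinkled in."""
    samples = make_design(n_pairs, n_nontag)
    vals = rng.lognormal(0, 1, (n_proteins, len(samples)))
    mask = rng.random(vals.shape) < zero_frac
    vals[mask] = 0.0
    # keep every column detectable
    vals[0, :] = np.maximum(vals[0, :], 1.0)
    return make_matrix(vals, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240119)


@pytest.fixture(scope="session")
def default_experiment():
    """The benchmark synthetic Lyso-IP experiment (fixed seed), as iFOT."""
    params = ProteomeSimParams(seed=1)
    m, truth = simulate_lysoip_experiment(params)
    return to_ifot(m), truth, params
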