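import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20180523)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-study synthetic dataset shared across tests."""
    from heightmr.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_snps=20, n_cases=300, n_controls=300, seed=99)
    return simulate_dataset(cfg)


def write_instrument_tsv(path, rows):
    """Helper: write an instrument TSV from (snp_id, eaf, beta, se, pval) tuples."""
    header = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tsource"
    lines = [header]
    for i, (snp, eaf, beta, se, pval) in enumerate(rows):
        lines.append(
            f"{snp}\t1\t{1000 + i}\tA\tG\t{eaf}\t{beta}\t{se}\t{pval}\tEAS"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
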