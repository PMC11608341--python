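import numpy as np
import pandas as pd
import pytest

from omixstat.kernels import Kernel
from omixstat.panels import SnpPanel


def make_snp_meta(ids, info=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "id": ids,
            "chrom": [1] * n,
            "pos": list(range(1, n + 1)),
            "allele1": ["A"] * n,
            "allele2": ["C"] * n,
            "info_score": [1.0] * n if info is None else info,
        }
    )


def make_panel(dosages, info=None, sample_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return SnpPanel(
        dosages=dosages,
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        snp_meta=make_snp_meta([f"snp{j}" for j in range(m)], info=info),
    )


def random_psd_kernel(n, rank=None, seed=0, tag="K"):
    rng = np.random.default_rng(seed)
    r = rank or n
    F = rng.standard_normal((n, r)) / np.sqrt(r)
    return Kernel(values=F @ F.T, sample_ids=[f"s{i}" for i in range(n)], tag=tag)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
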