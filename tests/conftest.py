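import numpy as np
import pandas as pd
import pytest

from mutgen.simulate import InjectionSpec, SimulationConfig, simulate_quintet
from mutgen.spectra import CONTEXTS96


@pytest.fixture(scope="session")
def de_novo_quintet():
    """A quintet with 50 injected de novo variants and no sequencing error."""
    injections = tuple(
        InjectionSpec(kind="de_novo", carriers=(f"offspring_{i % 3 + 1}",))
        for i in range(50)
    )
    cfg = SimulationConfig(seed=101, n_sites=300, error_rate=0.0, injected=injections)
    sites, truth = simulate_quintet(cfg)
    return sites, truth


@pytest.fixture(scope="session")
def signature_pair():
    """Two identifiable synthetic 96-context signatures (columns sum to 1)."""
    rng = np.random.default_rng(7)
    s1 = rng.dirichlet(np.full(96, 0.3))
    s2 = rng.dirichlet(np.full(96, 0.3))
    # concentrate each on a different half of the contexts so the pair is
    # well separated (low cosine similarity), like distinct COSMIC signatures
    s1[48:] *= 0.05
    s2[:48] *= 0.05
    s1, s2 = s1 / s1.sum(), s2 / s2.sum()
    return pd.DataFrame({"S1": s1, "S2": s2}, index=list(CONTEXTS96))
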