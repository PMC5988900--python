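import numpy as np
import pytest

from cyclereg.datasets import (
    full_tss_catalog,
    load_catalog,
    load_site_counts,
    load_target_functions,
)
from cyclereg.io import GenomeSequence
from cyclereg.motifs import build_pwm


@pytest.fixture(scope="session")
def catalog():
    """The bundled TSS-level catalog (46 rows)."""
    return load_catalog()


@pytest.fixture(scope="session")
def full_catalog():
    """Catalog extended with synthetic excluded-category records (88 ncRNAs)."""
    return full_tss_catalog()


@pytest.fixture(scope="session")
def target_functions():
    return load_target_functions()


@pytest.fixture(scope="session")
def site_counts():
    return load_site_counts()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture()
def sharp_pwm():
    """A strongly informative 10-mer PWM."""
    return build_pwm(["TTAACCATGG"] * 20, pseudocount=0.5, motif_id="sharp")


def random_genome(rng, length, gc=0.5, name="chr"):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return GenomeSequence(name=name, sequence=seq)


def random_pwm(rng, length, motif_id="rand", sharpness=5.0):
    freqs = rng.dirichlet([1.0 / sharpness] * 4, size=length)
    freqs = np.maximum(freqs, 1e-6)
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    from cyclereg.motifs import PWM

    return PWM(motif_id=motif_id, freqs=freqs)


def pwm_freq_dicts(pwm):
    """PWM frequencies as the plain dict form the oracles consume."""
    return [
        {b: float(pwm.freqs[n, i]) for i, b in enumerate("ACGT")}
        for n in range(pwm.length)
    ]
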