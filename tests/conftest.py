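import numpy as np
import pytest

from elytherm import simulate as sim
from elytherm.spectra import Spectrum


@pytest.fixture(scope="session")
def cohort():
    """Small in-memory cohort shared across tests (8 species x 2 specimens)."""
    return sim.gen_cohort(8, seed=20_240_101)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """On-disk cohort in the pipeline's input layout, with a paired dataset."""
    d = tmp_path_factory.mktemp("cohort")
    sim.gen_cohort(6, seed=99, out_dir=d)
    sim.gen_paired_body_dataset(11, seed=99).to_csv(d / "paired_body.csv", index=False)
    return d


def flat_spectrum(value, kind="E", lo=350.0, hi=1750.0, label="flat"):
    return Spectrum(np.array([lo, hi]), np.array([value, value], float), kind=kind, label=label)


@pytest.fixture
def flat():
    return flat_spectrum


def smooth_random_spectrum(rng, kind="E", lo=400.0, hi=1700.0, base=30.0, amp=25.0):
    """Random smooth percent spectrum on an integer 1-nm grid: a few broad
    Gaussian bumps over a baseline, clipped to [0, 95]."""
    wl = np.arange(lo, hi + 0.5)
    vals = np.full(wl.size, base + rng.uniform(-10, 10))
    for _ in range(rng.integers(2, 5)):
        c = rng.uniform(lo, hi)
        w = rng.uniform(80, 400)
        vals = vals + rng.uniform(-amp, amp) * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return Spectrum(wl, np.clip(vals, 0.0, 95.0), kind=kind)


@pytest.fixture
def random_spectrum():
    return smooth_random_spectrum
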