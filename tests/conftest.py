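import numpy as np
import pytest

from discordans._engine import Lattice
from discordans._params import CaCyclingParams, IonicParams


@pytest.fixture(scope="session")
def ion():
    return IonicParams()


@pytest.fixture(scope="session")
def ca():
    return CaCyclingParams()


@pytest.fixture(scope="session")
def ca_quiet():
    """Ca parameters with the stochastic term switched off."""
    return CaCyclingParams(noise_source="none")


def pace_lattice(lat, cl, n_beats, stim=40.0, collect_v=False):
    """Minimal pacing loop returning per-beat Ca peaks (free µM)."""
    peaks = []
    for _ in range(n_beats):
        rec = lat.run_beat(cl, stim_amp=stim, collect_v=collect_v)
        peaks.append(rec["ca_peak"])
    return np.array(peaks)


@pytest.fixture(scope="session")
def steady600(ion, ca):
    """Single-sarcomere steady state after slow pacing (CL = 600 ms),
    the standard initial condition for rate-step experiments."""
    lat = Lattice(ion, ca, m=1, seed=0)
    pace_lattice(lat, 600.0, 90)
    return lat.snapshot()


@pytest.fixture(scope="session")
def ratestep_runs(ion, ca, steady600):
    """Twenty seeded single-sarcomere rate-step (600->300 ms) runs with
    SERCA noise; shared by the alternans-development and phase-randomisation
    checks.  Returns the per-seed peak-Ca series (n_seeds, n_beats)."""
    out = []
    for seed in range(20):
        lat = Lattice(ion, ca, m=1, seed=seed)
        lat.restore(steady600)
        peaks = pace_lattice(lat, 300.0, 210)
        out.append(peaks[:, 0, 0])
    return np.asarray(out)
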