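import numpy as np
import pytest
from hypothesis import settings

import ecgid

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def template():
    """One fixed subject template."""
    return ecgid.make_cohort(3, seed=11)[0]


@pytest.fixture(scope="session")
def clean_record(template):
    """30 s noise-free recording at 500 Hz with ground-truth R annotations."""
    return ecgid.synthesize_record(
        template, ecgid.silent_profile(), duration=30.0, fs=500.0, seed=21
    )


@pytest.fixture(scope="session")
def driving_record(template):
    """Same subject under driving-grade noise."""
    return ecgid.synthesize_record(
        template, ecgid.noise_profile_for("driving"), duration=30.0, fs=500.0, seed=21
    )


@pytest.fixture(scope="session")
def clean_cycles(clean_record):
    """Segmented beats of the clean record (ground-truth peaks)."""
    peaks = ecgid.RPeakSet(indices=clean_record.annotations, fs=clean_record.fs)
    return ecgid.segment_cycles(clean_record, peaks)


@pytest.fixture(scope="session")
def annotated_cycles(clean_cycles):
    """Clean beats with full P..T annotations."""
    out = []
    for c in clean_cycles:
        out.append(
            ecgid.Cycle(
                samples=c.samples, fs=c.fs, r_index=c.r_index,
                subject_id=c.subject_id, peaks=ecgid.annotate_peaks(c),
            )
        )
    return out


def random_peak_stats(rng: np.random.Generator) -> ecgid.PeakStats:
    """A random valid five-vertex description on a 350-sample grid."""
    locs = np.sort(rng.choice(np.arange(10, 340), size=5, replace=False))
    volts = np.array(
        [
            rng.uniform(0.05, 0.3),
            rng.uniform(-0.3, -0.05),
            rng.uniform(0.8, 2.0),
            rng.uniform(-0.5, -0.05),
            rng.uniform(0.1, 0.5),
        ]
    )
    return ecgid.PeakStats(voltages=volts, locations=locs.astype(float))
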