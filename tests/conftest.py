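import numpy as np
import pytest

import vcgtwist as v


@pytest.fixture(scope="session")
def default_loop():
    return v.LoopSpec()


@pytest.fixture(scope="session")
def clean_record(default_loop):
    """Noiseless, jitter-free 10 s record at 60 bpm with its ground truth."""
    spec = v.SyntheticEcgSpec(seed=7)
    return v.project_and_assemble(spec, default_loop)


@pytest.fixture(scope="session")
def noisy_record(default_loop):
    """Realistic record: 10 µV noise, 5% RR jitter, 100 µV baseline wander."""
    spec = v.SyntheticEcgSpec(
        seed=7, noise_sigma_uv=10.0, rr_jitter_fraction=0.05, baseline_wander_uv=100.0
    )
    return v.project_and_assemble(spec, default_loop)


@pytest.fixture(scope="session")
def measured_clean(clean_record):
    """Full pipeline products for the clean record."""
    rec, truth = clean_record
    rec = v.filter_record(rec)
    ann = v.detect_qrs(rec)
    mb = v.build_median_beat(rec, ann)
    d = v.delineate(mb)
    return rec, truth, ann, mb, d


def run_pipeline(rec):
    rec = v.filter_record(rec)
    ann = v.detect_qrs(rec)
    mb = v.build_median_beat(rec, ann)
    d = v.delineate(mb)
    return ann, mb, d
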