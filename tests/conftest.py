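"""Shared fixtures: small synthetic recordings kept cheap for CI."""

import numpy as np
import pytest

from tcresleep import (SynthConfig, FocalFeature, default_montage,
                       generate_hypnogram, generate_recording_pair)

SMALL_SITES = ("C3", "Cz", "C4", "P4", "O1", "O2")


@pytest.fixture(scope="session")
def small_config():
    """Three minutes, six sites, fixed stage mix — fast everywhere."""
    return SynthConfig(
        duration=180.0,
        sites=SMALL_SITES,
        stage_sequence=("W", "W", "N2", "N2", "N3", "N3"),
        focal_features=(FocalFeature("P4", "beta", gain=1.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    hyp = generate_hypnogram(small_config)
    rec_t, rec_e = generate_recording_pair(small_config, hyp)
    return rec_t, rec_e, hyp


@pytest.fixture(scope="session")
def small_montage():
    return default_montage(SMALL_SITES)
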