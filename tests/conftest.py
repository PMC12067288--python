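import numpy as np
import pytest

from larvahomeo.synthetic import (
    CrawlSimConfig,
    PeristalsisSimConfig,
    ProfileSimConfig,
    QuantalSimConfig,
    gen_crawl_session,
    gen_line_profiles,
    gen_peristaltic_traces,
    gen_quantal_episodes,
)

STANDARD_SITES = [(12.0, 12.0), (12.0, 36.0), (36.0, 12.0), (36.0, 36.0)]


@pytest.fixture
def quantal_cfg():
    """Standard episodic protocol: 4 well-separated sites, SNR 5."""
    return QuantalSimConfig(
        site_positions=STANDARD_SITES,
        site_pr=[0.1, 0.3, 0.5, 0.9],
        n_trials=100,
        noise_sd=10.0,
        event_amplitude=50.0,
        seed=11,
    )


@pytest.fixture
def quantal_run(quantal_cfg):
    return gen_quantal_episodes(quantal_cfg)


@pytest.fixture
def crawl_session():
    cfg = CrawlSimConfig(
        phase_schedule=[("crawl", 30), ("reorient", 3), ("crawl", 30), ("stop", 5), ("crawl", 30)],
        seed=11,
    )
    return gen_crawl_session(cfg)


@pytest.fixture
def peristalsis_run():
    cfg = PeristalsisSimConfig(record_length=300.0, seed=11)
    return gen_peristaltic_traces(cfg)


@pytest.fixture
def noisy_profiles():
    cfg = ProfileSimConfig(n_profiles=50, noise_sd=50.0, seed=11)  # noise 5% of amplitude
    return gen_line_profiles(cfg)
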