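"""Shared fixtures: the default synthetic bundle and one full protocol run.

The four-pass protocol on the default bundle takes ~1 minute, so it runs
once per session and every test that needs discovery output shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

import pacefinder as pf


@pytest.fixture(scope="session")
def default_bundle() -> pf.simdata.SimBundle:
    return pf.sim_bundle(pf.SimConfig())


@pytest.fixture(scope="session")
def protocol_report(default_bundle):
    return pf.run_pace_protocol(
        default_bundle.promoters, default_bundle.statuses, default_bundle.tree
    )


@pytest.fixture(scope="session")
def final_scan(default_bundle, protocol_report):
    """Hits and presence calls of the final PWM over every promoter."""
    return pf.scan(
        protocol_report.final_pwm, default_bundle.promoters, fdr=0.1
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("derandomized", derandomize=True)
_hyp_settings.load_profile("derandomized")
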