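"""Shared fixtures: small synthetic trace sets with known ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from smfretkit.scenarios import canonical_t99
from smfretkit.synth import KineticScenario, render_trace, sample_state_path


def make_traces(scenario: KineticScenario, k01: float, k10: float, n: int, seed: int):
    """n rendered traces of a two-state process with the given rates."""
    out = []
    for ss in np.random.SeedSequence(seed).spawn(n):
        rng = np.random.default_rng(ss)
        path = sample_state_path(k01, k10, scenario.duration, rng)
        out.append(render_trace(path, scenario, rng))
    for i, tr in enumerate(out):
        tr.molecule_id = i
    return out


@pytest.fixture(scope="session")
def canonical():
    return canonical_t99()


@pytest.fixture(scope="session")
def nobleach_canonical():
    """Canonical scenario without bleaching (full 800-frame dynamics)."""
    return replace(canonical_t99(), bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)


@pytest.fixture(scope="session")
def noiseless_canonical():
    """Deterministic emission: no E width, no shot/read noise, no bleaching."""
    return replace(
        canonical_t99(),
        fret_sds=(0.0, 0.0),
        read_noise_sd=0.0,
        shot_noise=False,
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.0,
    )
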