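"""Shared fixtures: settled spirals are expensive, so they are prepared
once per session and reused across rigidity/drift/pinning tests."""

import pytest


@pytest.fixture(scope="session")
def prep_fast():
    """Settled spiral at the fast operating point (alpha=0.3, d=0.2)."""
    from borderzone import force_estimation as fe
    return fe.prepare_spiral(alpha=0.3, d_cells=0.2, n=100)


@pytest.fixture(scope="session")
def prep_weak():
    """Settled spiral in the weak-coupling regime (alpha=0.35, d=0.1)."""
    from borderzone import force_estimation as fe
    return fe.prepare_spiral(alpha=0.35, d_cells=0.1, n=100)
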