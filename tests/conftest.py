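"""Shared fixtures: deterministic synthetic references and designs."""

import pytest

from oligotiler import DesignParams, design, fixtures


@pytest.fixture(scope="session")
def balanced_520():
    """Canonical 520 bp GC-balanced synthetic reference (seed 1)."""
    return fixtures.random_sequence(
        fixtures.FixtureSpec(length=520, seed=1, gc_target=50.0, name="bal520")
    )


@pytest.fixture(scope="session")
def default_design(balanced_520):
    """A complete design of the canonical reference under default params."""
    return design(balanced_520, DesignParams())
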