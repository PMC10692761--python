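"""Shared fixtures: synthetic chains and a session-scoped database build."""

from __future__ import annotations

import pytest

from strucphy import fixtures as fx
from strucphy.pipeline import build_database


@pytest.fixture(scope="session")
def two_helix():
    return fx.two_helix_chain(seed=1)


@pytest.fixture(scope="session")
def coil60():
    return fx.coil_chain(n=60, seed=7)


@pytest.fixture(scope="session")
def histone_like():
    return fx.histone_like_chain(seed=3)


@pytest.fixture(scope="session")
def family_chains():
    return fx.family_set(base_seed=11)


@pytest.fixture(scope="session")
def family_dirs(tmp_path_factory):
    """The family fixture set written to disk once per session."""
    d = tmp_path_factory.mktemp("famset")
    fx.family_set(out_dir=d, base_seed=11)
    return d


@pytest.fixture(scope="session")
def family_db(family_dirs, tmp_path_factory):
    """A full database build over the family fixture set (session-cached)."""
    out = tmp_path_factory.mktemp("db") / "famdb"
    return build_database(family_dirs, out)


@pytest.fixture(scope="session")
def family_db_rebuild(family_dirs, tmp_path_factory):
    """A second, independently timed build of the same fixture set.

    Returns ``(db, elapsed_seconds)``; shared so the suite runs exactly
    two full builds (determinism and timing checks both use this one).
    """
    import time

    out = tmp_path_factory.mktemp("db2") / "famdb"
    t0 = time.perf_counter()
    db = build_database(family_dirs, out)
    return db, time.perf_counter() - t0
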