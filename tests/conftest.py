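from __future__ import annotations

import numpy as np
import pytest

from gnossn import emit_scenario, report_compare, run_all


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def minimal_scenario(tmp_path_factory) -> tuple:
    out = tmp_path_factory.mktemp("minimal")
    path, ledger = emit_scenario("minimal", out, seed=11)
    return path, ledger


@pytest.fixture(scope="session")
def hierarchy_scenario(tmp_path_factory) -> tuple:
    out = tmp_path_factory.mktemp("hierarchy")
    path, ledger = emit_scenario("hierarchy", out, seed=5)
    return path, ledger


@pytest.fixture(scope="session")
def paperlike_run(tmp_path_factory) -> dict:
    """One full paper-like run shared by the end-to-end checks (it is the
    expensive fixture: 200 genomes, full pipeline)."""
    base = tmp_path_factory.mktemp("paperlike")
    scenario_dir, ledger = emit_scenario("paper-like", base / "data", seed=3)
    report = run_all(scenario_dir, base / "out")
    comparison = report_compare(base / "out", scenario_dir / "ledger.json")
    return {
        "scenario_dir": scenario_dir,
        "out_dir": base / "out",
        "ledger": ledger,
        "report": report,
        "comparison": comparison,
    }
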