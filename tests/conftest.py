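import numpy as np
import pytest

from cupgrammar.classifier import StrategyLabel
from cupgrammar.synthetic import AgentConfig, simulate_trial

MIXED_WEIGHTS = {
    StrategyLabel.PAIRING: 0.15,
    StrategyLabel.POT: 0.15,
    StrategyLabel.SUBASSEMBLY: 0.10,
    StrategyLabel.UNIT_UNIT: 0.05,
    StrategyLabel.PILE: 0.03,
    StrategyLabel.PILE_SUB: 0.01,
    StrategyLabel.PUT: 0.10,
    StrategyLabel.DISASSEMBLE: 0.20,
    StrategyLabel.OTHER: 0.21,
}


@pytest.fixture
def mixed_config() -> AgentConfig:
    """A noise-free all-category agent used across the suite."""
    return AgentConfig(MIXED_WEIGHTS, size_judgment_error=0.0, action_budget=80)


def random_trial(seed: int, n_cups: int = 9, error: float = 0.0, budget: int = 80):
    """One simulated trial on its own seeded stream."""
    cfg = AgentConfig(MIXED_WEIGHTS, size_judgment_error=error, action_budget=budget)
    return simulate_trial(
        cfg, n_cups, rng=np.random.default_rng(seed), trial_id=f"t{seed}"
    )
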