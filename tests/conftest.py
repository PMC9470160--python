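"""Shared fixtures: small synthetic sessions and agents."""

import numpy as np
import pytest

from volinfer.observer import ModelParams, simulate_agent
from volinfer.task import C_MINUS, C_PLUS, Session, TaskConfig, Trial, generate_session


@pytest.fixture(scope="session")
def default_cfg() -> TaskConfig:
    return TaskConfig(seed=7)


@pytest.fixture(scope="session")
def default_session(default_cfg) -> Session:
    return generate_session(default_cfg)


@pytest.fixture(scope="session")
def short_session() -> Session:
    return generate_session(TaskConfig(n_blocks=2, seed=3))


@pytest.fixture(scope="session")
def agent_params() -> ModelParams:
    # a competent, mildly noisy observer in the plausible fitting region
    return ModelParams(
        hazard=0.12, sigma_inf=1.0, conf_threshold=1.5, sigma_meta=0.8, conf_gain=1.0
    )


@pytest.fixture(scope="session")
def agent_run(default_session, agent_params):
    trace, resp = simulate_agent(default_session, agent_params, np.random.default_rng(0))
    return trace, resp


def make_toy_session(
    hidden_states,
    deviations=None,
    conditions=None,
    seq_len=2,
    blocks=None,
    kappa=0.5,
) -> Session:
    """Hand-built session for oracle tests: explicit states, one episode
    per state run, all trials in one block unless ``blocks`` given."""
    hidden_states = list(hidden_states)
    n = len(hidden_states)
    blocks = list(blocks) if blocks is not None else [0] * n
    conditions = list(conditions) if conditions is not None else [C_MINUS] * n
    cfg = TaskConfig(
        n_blocks=len(set(blocks)),
        trials_per_block=n // len(set(blocks)),
        episode_min=1,
        episode_max=n,
        seq_lengths=(seq_len,),
        kappa=kappa,
        seed=0,
    )
    trials = []
    ep = 0
    pos = 0
    for t, s in enumerate(hidden_states):
        if t > 0 and (hidden_states[t - 1] != s or blocks[t - 1] != blocks[t]):
            ep += 1
            pos = 0
        dev = (
            np.asarray(deviations[t], dtype=float)
            if deviations is not None
            else np.zeros(seq_len)
        )
        trials.append(
            Trial(
                index=t,
                block=blocks[t],
                condition=conditions[t],
                hidden_state=int(s),
                seq_len=len(dev),
                episode_id=ep,
                pos_in_episode=pos,
                deviations=dev,
                gen_category=int(s),
            )
        )
        pos += 1
    return Session(config=cfg, trials=trials, seed=0)
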