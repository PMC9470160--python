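"""Synthetic reversal-learning task generator.

Emulates a two-condition categorical reversal task: on each trial a sequence
of 2-8 oriented bars is drawn from one of two axial von Mises categories
(means spaced pi/2 on the orientation half-circle, concentration kappa=0.5),
and a hidden binary state reverses at episode boundaries drawn from a
truncated exponential (4-24 trials), yielding a near-constant hazard rate.

Two controllability conditions are generated:

* ``C-`` (uncontrollable): the drawn category *is* the hidden state; the
  observer monitors which category the computer draws from.
* ``C+`` (controllable): the hidden state is a key->category mapping; the
  category actually drawn on a trial is the previous action passed through
  that mapping, so sequences are realized *closed-loop* against an action
  stream (see :func:`volinfer.observer.simulate_agent`).

Orientations are axial (period pi) and handled internally on the doubled
circle ``2*theta`` (period 2*pi), where the two category means are
diametrically opposite and the von Mises algebra is standard.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

C_MINUS = "C-"
C_PLUS = "C+"

#: Category mean orientations on [0, pi): category +1 at pi/4, category -1
#: offset by the configured mean gap (pi/2 by default).
MU_PLUS = np.pi / 4


class ConfigurationError(ValueError):
    """Invalid task configuration."""


class SequencingError(RuntimeError):
    """Closed-loop C+ trial realized without a previous action."""


@dataclass(frozen=True)
class TaskConfig:
    """Generative design of one experimental session.

    Defaults reproduce the published design: 8 blocks of 72 trials (576
    total), hidden-state episodes of 4-24 trials from a truncated
    exponential, sequences of 2/4/6/8 stimuli drawn from von Mises
    categories with concentration 0.5 and means spaced pi/2.
    """

    n_blocks: int = 8
    trials_per_block: int = 72
    episode_min: int = 4
    episode_max: int = 24
    #: Scale (in trials) of the truncated exponential over episode lengths.
    #: Not printed in the original design; default gives mean episode
    #: length ~= 8.9 trials, consistent with a near-constant hazard of
    #: roughly 0.11 per trial.
    episode_scale: float = 5.0
    seq_lengths: tuple[int, ...] = (2, 4, 6, 8)
    kappa: float = 0.5
    mu_gap: float = np.pi / 2
    #: "alternate" starts C-/C+/... or C+/C-/... depending on seed parity,
    #: mirroring block-level counterbalancing across participants.
    condition_order: str = "alternate"
    #: "block": the hidden rule/category mapping is fixed within a block
    #: (Experiments 1/2A). "trial": carried as metadata for the trial-wise
    #: rule variant (2B); the generative statistics are identical.
    rule_regime: str = "block"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.episode_min < 1:
            raise ConfigurationError("episode_min must be >= 1")
        if self.episode_min > self.episode_max:
            raise ConfigurationError("episode_min must be <= episode_max")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")
        if self.episode_scale <= 0:
            raise ConfigurationError("episode_scale must be > 0")
        if not self.seq_lengths or any(l < 1 for l in self.seq_lengths):
            raise ConfigurationError("seq_lengths must be positive counts")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("need at least one block and trial")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def mu(self) -> dict[int, float]:
        """Category mean orientations, category -> radians in [0, pi)."""
        return {+1: MU_PLUS, -1: (MU_PLUS + self.mu_gap) % np.pi}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seq_lengths"] = list(self.seq_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "seq_lengths" in d:
            d["seq_lengths"] = tuple(d["seq_lengths"])
        return cls(**d)


@dataclass
class Trial:
    """One trial: a stimulus sequence drawn from a (possibly lazily
    realized) category under a hidden state."""

    index: int
    block: int
    condition: str
    hidden_state: int
    seq_len: int
    episode_id: int
    pos_in_episode: int
    #: von Mises deviations of each stimulus from its category mean, on the
    #: doubled circle (radians in (-pi, pi]).  These are category-agnostic:
    #: the realized orientation is (mu_category + deviation/2) mod pi.
    deviations: np.ndarray
    #: Category the sequence was (or will be) drawn from; None for C+
    #: trials not yet realized against an action stream.
    gen_category: int | None = None
    orientations: np.ndarray | None = None


def episode_length_pmf(cfg: TaskConfig) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the truncated exponential over episode lengths."""
    support = np.arange(cfg.episode_min, cfg.episode_max + 1)
    w = np.exp(-(support - cfg.episode_min) / cfg.episode_scale)
    return support, w / w.sum()


def draw_episode_lengths(
    n_trials: int, cfg: TaskConfig, rng: np.random.Generator
) -> list[int]:
    """Draw episode lengths until they cover ``n_trials``.

    Lengths are i.i.d. from the truncated exponential on
    [episode_min, episode_max]; the final episode is clipped so that the
    total is exactly ``n_trials``.  A clipped remainder shorter than
    ``episode_min`` is absorbed into the preceding episode when possible
    (keeping it within bounds), otherwise the partition is redrawn, so
    every returned length lies in [episode_min, episode_max].
    """
    if n_trials < cfg.episode_min:
        raise ConfigurationError(
            f"n_trials={n_trials} shorter than episode_min={cfg.episode_min}"
        )
    support, pmf = episode_length_pmf(cfg)
    for _ in range(1000):
        lengths: list[int] = []
        total = 0
        while total < n_trials:
            l = int(rng.choice(support, p=pmf))
            lengths.append(l)
            total += l
        excess = total - n_trials
        last = lengths[-1] - excess
        if last >= cfg.episode_min:
            lengths[-1] = last
            return lengths
        # fold the short remainder into the previous episode if it fits
        if len(lengths) >= 2 and cfg.episode_min <= lengths[-2] + last <= cfg.episode_max:
            lengths[-2] += last
            lengths.pop()
            return lengths
        # rare: redraw the partition
    raise RuntimeError("episode partition failed to satisfy bounds")


def draw_sequence(
    category: int, seq_len: int, cfg: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw stimulus orientations for one trial from the given category.

    Sampling is on the doubled circle: 2*theta ~ vonMises(2*mu_category,
    kappa), mapped back to [0, pi).
    """
    if seq_len not in cfg.seq_lengths:
        raise ConfigurationError(
            f"seq_len={seq_len} not in allowed set {cfg.seq_lengths}"
        )
    if category not in (-1, 1):
        raise ConfigurationError("category must be +1 or -1")
    dev = rng.vonmises(0.0, cfg.kappa, size=seq_len)
    return realize_orientations(category, dev, cfg)


def realize_orientations(
    category: int, deviations: np.ndarray, cfg: TaskConfig
) -> np.ndarray:
    """Map doubled-circle deviations from a category mean to orientations."""
    mu = cfg.mu[category]
    return (mu + np.asarray(deviations) / 2.0) % np.pi


def realize_trial_category(
    hidden_state: int, condition: str, prev_action: int | None = None
) -> int:
    """Category a trial's sequence is drawn from.

    In C- the drawn category is the hidden state itself.  In C+ the hidden
    state is the action->category mapping: action ``a`` produces category
    ``a * hidden_state`` (hidden_state=+1 is the identity mapping), so the
    previous action is required.
    """
    if condition == C_MINUS:
        return int(hidden_state)
    if condition == C_PLUS:
        if prev_action is None:
            raise SequencingError("C+ trial requires a previous action")
        return int(prev_action * hidden_state)
    raise ConfigurationError(f"unknown condition {condition!r}")


@dataclass
class Session:
    """A generated session: ordered trials plus cached flat arrays."""

    config: TaskConfig
    trials: list[Trial]
    seed: int

    # ---- flat array views used by the vectorized observer core ----
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def _cache(self) -> dict[str, np.ndarray]:
        if not hasattr(self, "_arr"):
            cfg = self.config
            n = self.n_trials
            arr = {
                "block": np.array([t.block for t in self.trials], dtype=np.int64),
                "condition": np.array(
                    [0 if t.condition == C_MINUS else 1 for t in self.trials],
                    dtype=np.int64,
                ),
                "s": np.array([t.hidden_state for t in self.trials], dtype=np.int64),
                "seq_len": np.array([t.seq_len for t in self.trials], dtype=np.int64),
                "episode_id": np.array([t.episode_id for t in self.trials], dtype=np.int64),
                "pos_in_episode": np.array(
                    [t.pos_in_episode for t in self.trials], dtype=np.int64
                ),
            }
            arr["block_start"] = np.zeros(n, dtype=np.bool_)
            if n:
                arr["block_start"][0] = True
                arr["block_start"][1:] = arr["block"][1:] != arr["block"][:-1]
            # Noiseless per-trial evidence about the hidden state, in the
            # shared (recoded) inference frame: s * 2*kappa * sum cos(dev).
            # For C- this is the plain category log-likelihood ratio sum;
            # for C+ it equals the action-recoded LLR sum regardless of the
            # action actually taken (see module docstring).
            cosdev = np.array([float(np.cos(t.deviations).sum()) for t in self.trials])
            arr["base_llr"] = arr["s"] * 2.0 * cfg.kappa * cosdev
            self._arr = arr
        return self._arr

    def __getattr__(self, name):
        cache_keys = {
            "block", "condition", "s", "seq_len", "episode_id",
            "pos_in_episode", "block_start", "base_llr",
        }
        if name in cache_keys:
            return self._cache()[name]
        raise AttributeError(name)

    def condition_of_block(self, b: int) -> str:
        return self.trials[b * self.config.trials_per_block].condition

    def validate(self) -> None:
        cfg = self.config
        if self.n_trials != cfg.n_trials:
            raise ConfigurationError("trial count != n_blocks * trials_per_block")
        # per-block episode length bounds (episodes never span blocks)
        df = self.to_frame()
        lengths = df.groupby(["block", "episode_id"]).size()
        if lengths.min() < cfg.episode_min or lengths.max() > cfg.episode_max:
            raise ConfigurationError("episode length outside configured bounds")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "trial": t.index,
                    "block": t.block,
                    "condition": t.condition,
                    "hidden_state": t.hidden_state,
                    "seq_len": t.seq_len,
                    "episode_id": t.episode_id,
                    "pos_in_episode": t.pos_in_episode,
                    "gen_category": t.gen_category,
                    "deviations": ";".join(f"{d:.10g}" for d in t.deviations),
                    "orientations": (
                        ";".join(f"{o:.10g}" for o in t.orientations)
                        if t.orientations is not None
                        else ""
                    ),
                }
            )
        return pd.DataFrame(rows)


def generate_session(
    cfg: TaskConfig,
    rng: np.random.Generator | None = None,
    action_stream: np.ndarray | None = None,
) -> Session:
    """Generate a full session deterministically from the config seed.

    Blocks alternate conditions (parity set by the seed).  Hidden-state
    episodes are drawn independently within each block.  C- trials are
    realized immediately (category = hidden state); C+ trials are realized
    lazily unless ``action_stream`` (one action per trial; entries for C-
    trials ignored) is supplied.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    first = C_MINUS if cfg.seed % 2 == 1 else C_PLUS
    other = C_PLUS if first == C_MINUS else C_MINUS

    trials: list[Trial] = []
    episode_counter = 0
    for b in range(cfg.n_blocks):
        condition = first if b % 2 == 0 else other
        lengths = draw_episode_lengths(cfg.trials_per_block, cfg, rng)
        state = int(rng.choice([-1, 1]))
        seq_lens = rng.choice(np.array(cfg.seq_lengths), size=cfg.trials_per_block)
        t_in_block = 0
        for l in lengths:
            for pos in range(l):
                idx = b * cfg.trials_per_block + t_in_block
                n_stim = int(seq_lens[t_in_block])
                dev = rng.vonmises(0.0, cfg.kappa, size=n_stim)
                trial = Trial(
                    index=idx,
                    block=b,
                    condition=condition,
                    hidden_state=state,
                    seq_len=n_stim,
                    episode_id=episode_counter,
                    pos_in_episode=pos,
                    deviations=dev,
                )
                if condition == C_MINUS:
                    trial.gen_category = state
                    trial.orientations = realize_orientations(state, dev, cfg)
                elif action_stream is not None:
                    prev = int(action_stream[idx])
                    cat = realize_trial_category(state, condition, prev)
                    trial.gen_category = cat
                    trial.orientations = realize_orientations(cat, dev, cfg)
                trials.append(trial)
                t_in_block += 1
            state = -state
            episode_counter += 1
    session = Session(config=cfg, trials=trials, seed=cfg.seed)
    session.validate()
    return session


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_session(session: Session, csv_path: str | Path) -> None:
    """Tidy CSV, one row per trial; config and seed in a sidecar JSON."""
    csv_path = Path(csv_path)
    session.to_frame().to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"config": session.config.to_dict(), "seed": session.seed},
            indent=2,
            sort_keys=True,
        )
    )


def read_session(csv_path: str | Path) -> Session:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, keep_default_na=False)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    cfg = TaskConfig.from_dict(meta["config"])
    trials = []
    for _, row in df.iterrows():
        dev = np.array([float(x) for x in str(row["deviations"]).split(";") if x])
        ori = (
            np.array([float(x) for x in str(row["orientations"]).split(";") if x])
            if str(row["orientations"])
            else None
        )
        gen = row["gen_category"]
        trials.append(
            Trial(
                index=int(row["trial"]),
                block=int(row["block"]),
                condition=str(row["condition"]),
                hidden_state=int(row["hidden_state"]),
                seq_len=int(row["seq_len"]),
                episode_id=int(row["episode_id"]),
                pos_in_episode=int(row["pos_in_episode"]),
                deviations=dev,
                gen_category=int(float(gen)) if str(gen) not in ("", "nan", "None") else None,
                orientations=ori if ori is not None and len(ori) else None,
            )
        )
    return Session(config=cfg, trials=trials, seed=int(meta["seed"]))
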