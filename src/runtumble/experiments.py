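"""Replicated experiment runners.

Each runner sweeps strategies (and, where relevant, learning durations)
over seeded replicates and returns a tidy :class:`pandas.DataFrame`, one
row per replicate-condition. Replicate ``r`` always uses seed
``base_seed + r``, so any row can be regenerated in isolation.

The experiment battery:

* ``performance_experiment`` — chemotaxis performance (final distance from
  the source after a post-learning EFE test phase) against learning
  duration.
* ``accuracy_experiment`` — KL model accuracy against a true-model oracle;
  sampling-bias histograms and per-conditional distribution change at the
  longest duration, optionally with reversed preferences.
* ``pruning_experiment`` — Bayesian model reduction: learn, re-prior,
  re-learn, then scan each of the 8 transition-prior counts for pruning.
* ``bad_bootstrap_experiment`` — long learning runs followed by a
  chemotaxis test, to count agents trapped in maladaptive models.
* ``efe_trace_experiment`` — per-step EFE decomposition for an agent that
  starts from a constructed maladaptive model and escapes it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .agent import Strategy, init_model, make_maladaptive_model
from .environment import START_DISTANCE
from .evaluation import (
    TrueModel,
    active_passive_errors,
    distribution_change_kl,
    estimate_true_model,
    model_accuracy_kl,
    run_phase,
    run_test_phase,
    transition_histogram,
)
from .model_reduction import prune_scan

__all__ = [
    "ExperimentConfig",
    "performance_experiment",
    "accuracy_experiment",
    "active_passive_experiment",
    "pruning_experiment",
    "bad_bootstrap_experiment",
    "efe_trace_experiment",
]

ALL_STRATEGIES = (
    Strategy.EFE,
    Strategy.INSTRUMENTAL,
    Strategy.EPISTEMIC,
    Strategy.RANDOM,
)


@dataclass
class ExperimentConfig:
    """Resolved configuration for every experiment runner.

    Defaults match the study conditions throughout: 300 replicates,
    1,000-step episodes and test phases from 400 units out, learning rate
    0.001, instrumental weight 0.1, log preferences (0, -60), and
    per-column prior concentration 0.5.
    """

    strategies: tuple[Strategy, ...] = ALL_STRATEGIES
    durations: tuple[int, ...] = (0, 50, 100, 200, 300, 500, 750, 1000, 2000, 4000)
    replicates: int = 300
    test_steps: int = 1000
    episode_length: int = 1000
    base_seed: int = 0
    start_distance: float = START_DISTANCE
    concentration: float = 0.5
    delta: float = 0.1
    xi: float = 0.001
    rho_log: tuple[float, float] = (0.0, -60.0)
    reversed_preferences: bool = False
    bootstrap_learn_steps: int = 4000
    prune_learn_steps: int = 500
    prune_post_steps: int = 500
    accuracy_learn_steps: int = 1000
    active_passive_learn_steps: int = 300
    active_passive_measure_steps: int = 1000
    trace_steps: int = 5000
    true_model_samples: int = 1_000_000
    true_model_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(d < 0 for d in self.durations):
            raise ValueError("durations must be non-negative")
        self.strategies = tuple(Strategy(s) for s in self.strategies)

    @property
    def effective_rho_log(self) -> tuple[float, float]:
        return tuple(reversed(self.rho_log)) if self.reversed_preferences else tuple(self.rho_log)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategies"] = [s.value for s in self.strategies]
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("strategies", "durations", "rho_log"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _new_agent(config: ExperimentConfig, rng: np.random.Generator):
    return init_model(
        rng,
        concentration=config.concentration,
        rho_log=config.effective_rho_log,
        delta=config.delta,
        xi=config.xi,
    )


def _run_learning(model, beliefs, strategy, steps, rng, config: ExperimentConfig):
    """Learning phase: consecutive episodes of ``episode_length`` steps.

    Each episode starts from a fresh random placement at the standard
    distance; beliefs (including Dirichlet counts) carry across episodes.
    Returns the summed transition tally and the final world state.
    """
    counts = np.zeros((model.n_controls, model.n_states, model.n_states))
    state = None
    remaining = steps
    while remaining > 0:
        chunk = min(config.episode_length, remaining)
        phase = run_phase(model, beliefs, strategy, chunk, rng,
                          start_distance=config.start_distance)
        counts += phase.transition_counts
        state = phase.state
        remaining -= chunk
    return counts, state


def performance_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Final distance after an EFE test phase, per strategy and duration."""
    rows = []
    for strategy in config.strategies:
        for duration in config.durations:
            for r in range(config.replicates):
                seed = config.base_seed + r
                rng = np.random.default_rng(seed)
                model, beliefs = _new_agent(config, rng)
                if duration > 0:
                    _run_learning(model, beliefs, strategy, duration, rng, config)
                result = run_test_phase(beliefs, model, config.test_steps, rng,
                                        start_distance=config.start_distance)
                rows.append({
                    "strategy": strategy.value,
                    "duration": duration,
                    "replicate": r,
                    "seed": seed,
                    "final_distance": result.final_distance,
                    "displacement": result.displacement_toward_source,
                    "success": result.success,
                })
    return pd.DataFrame(rows)


def accuracy_experiment(
    config: ExperimentConfig,
    true_model: TrueModel | None = None,
    durations: tuple[int, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """KL model accuracy, sampling histograms and distribution change.

    Returns three frames: ``kl`` (per strategy x duration x replicate),
    and ``histogram`` / ``dist_change`` measured on the runs at the longest
    duration. Histogram cells are labelled ``<action>:<prev>-><next>``.
    """
    if true_model is None:
        true_model = estimate_true_model(config.true_model_samples, config.true_model_seed,
                                         start_distance=config.start_distance)
    durations = tuple(durations) if durations is not None else (config.accuracy_learn_steps,)
    state_names = ("pos", "neg")
    action_names = ("run", "tumble")
    kl_rows, hist_rows, change_rows = [], [], []
    for strategy in config.strategies:
        for duration in durations:
            for r in range(config.replicates):
                seed = config.base_seed + r
                rng = np.random.default_rng(seed)
                model, beliefs = _new_agent(config, rng)
                initial_counts = beliefs.phi_alpha.copy()
                tallies, _ = _run_learning(model, beliefs, strategy, duration, rng, config)
                kl_rows.append({
                    "strategy": strategy.value,
                    "duration": duration,
                    "replicate": r,
                    "seed": seed,
                    "kl_true_vs_learned": model_accuracy_kl(beliefs, true_model),
                })
                if duration == max(durations):
                    hist = transition_histogram(tallies)
                    row = {"strategy": strategy.value, "replicate": r, "seed": seed}
                    for u, a_name in enumerate(action_names):
                        for i, nxt in enumerate(state_names):
                            for j, prev in enumerate(state_names):
                                row[f"{a_name}:{prev}->{nxt}"] = hist[u][i, j]
                    hist_rows.append(row)
                    change = distribution_change_kl(initial_counts, beliefs.phi_alpha)
                    crow = {"strategy": strategy.value, "replicate": r, "seed": seed}
                    for u, a_name in enumerate(action_names):
                        for j, prev in enumerate(state_names):
                            crow[f"{a_name}|{prev}"] = change[u, j]
                    change_rows.append(crow)
    return {
        "kl": pd.DataFrame(kl_rows),
        "histogram": pd.DataFrame(hist_rows),
        "dist_change": pd.DataFrame(change_rows),
    }


def active_passive_experiment(
    config: ExperimentConfig, true_model: TrueModel | None = None
) -> pd.DataFrame:
    """Cumulative active vs passive counterfactual prediction error.

    Each replicate learns for ``active_passive_learn_steps`` under its
    strategy, then keeps acting (and learning) for
    ``active_passive_measure_steps`` while both error series accumulate.
    Records the final cumulative errors.
    """
    if true_model is None:
        true_model = estimate_true_model(config.true_model_samples, config.true_model_seed,
                                         start_distance=config.start_distance)
    rows = []
    for strategy in config.strategies:
        for r in range(config.replicates):
            seed = config.base_seed + r
            rng = np.random.default_rng(seed)
            model, beliefs = _new_agent(config, rng)
            _, state = _run_learning(model, beliefs, strategy,
                                     config.active_passive_learn_steps, rng, config)
            active, passive = active_passive_errors(
                model, beliefs, strategy, true_model,
                config.active_passive_measure_steps, rng, state=state)
            rows.append({
                "strategy": strategy.value,
                "replicate": r,
                "seed": seed,
                "active_error": active[-1],
                "passive_error": passive[-1],
            })
    return pd.DataFrame(rows)


def pruning_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Bayesian model reduction after a learn / re-prior / re-learn protocol.

    Learn ``prune_learn_steps`` under each strategy, promote the posterior
    counts to priors, then act and learn for ``prune_post_steps`` more under
    the same strategy from a fresh placement, and scan each of the 8
    transition-prior counts for pruning.
    """
    state_names = ("pos", "neg")
    action_names = ("run", "tumble")
    rows = []
    for strategy in config.strategies:
        for r in range(config.replicates):
            seed = config.base_seed + r
            rng = np.random.default_rng(seed)
            model, beliefs = _new_agent(config, rng)
            _run_learning(model, beliefs, strategy, config.prune_learn_steps, rng, config)
            prior = beliefs.phi_alpha.copy()
            _run_learning(model, beliefs, strategy, config.prune_post_steps, rng, config)
            results = prune_scan(prior, beliefs.phi_alpha)
            row = {"strategy": strategy.value, "replicate": r, "seed": seed,
                   "total_pruned": sum(res.pruned for res in results)}
            for res in results:
                label = (f"{action_names[res.control]}|{state_names[res.prev_state]}"
                         f"->{state_names[res.next_state]}")
                row[f"pruned[{label}]"] = res.pruned
                row[f"delta_F[{label}]"] = res.delta_F
            rows.append(row)
    return pd.DataFrame(rows)


def bad_bootstrap_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Long-run learning followed by a chemotaxis test, per strategy.

    Failure (``success == False``) means the learned model could not move
    the agent more than 50 units toward the source in the test phase —
    the signature of a bad bootstrap.
    """
    rows = []
    for strategy in config.strategies:
        for r in range(config.replicates):
            seed = config.base_seed + r
            rng = np.random.default_rng(seed)
            model, beliefs = _new_agent(config, rng)
            _run_learning(model, beliefs, strategy, config.bootstrap_learn_steps, rng, config)
            result = run_test_phase(beliefs, model, config.test_steps, rng,
                                    start_distance=config.start_distance)
            rows.append({
                "strategy": strategy.value,
                "replicate": r,
                "seed": seed,
                "learn_steps": config.bootstrap_learn_steps,
                "final_distance": result.final_distance,
                "displacement": result.displacement_toward_source,
                "success": result.success,
            })
    return pd.DataFrame(rows)


def efe_trace_experiment(config: ExperimentConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-step EFE decomposition for an initially maladaptive EFE agent.

    The agent starts from the constructed bad-bootstrap model and acts by
    expected free energy with learning on; each row records the negative
    EFE and its epistemic / (delta-weighted) instrumental parts for both
    controls.
    """
    seed = config.base_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model, beliefs = make_maladaptive_model(
        rho_log=config.effective_rho_log, delta=config.delta, xi=config.xi)
    phase = run_phase(model, beliefs, Strategy.EFE, config.trace_steps, rng,
                      log=True, start_distance=config.start_distance)
    rows = []
    for t, rec in enumerate(phase.logs):
        rows.append({
            "t": t,
            "neg_efe_run": rec.neg_efe[0],
            "neg_efe_tumble": rec.neg_efe[1],
            "epistemic_run": rec.epistemic[0],
            "epistemic_tumble": rec.epistemic[1],
            "instrumental_run": rec.instrumental[0],
            "instrumental_tumble": rec.instrumental[1],
            "action": "run" if rec.action == 0 else "tumble",
            "observation": "pos" if rec.observation == 0 else "neg",
        })
    return pd.DataFrame(rows)
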