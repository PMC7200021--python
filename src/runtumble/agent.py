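"""Discrete active-inference agent with Dirichlet transition learning.

The agent is a one-step-lookahead POMDP agent. Its generative model comprises

* a fixed, unambiguous likelihood matrix ``lambda_`` mapping hidden gradient
  states to gradient observations (identity, up to a log floor),
* an action-conditioned transition tensor over hidden states whose columns
  carry independent Dirichlet priors with counts ``alpha``,
* a log prior preference vector ``rho_log`` over observations (positive
  gradients preferred by default), and
* two scalars: the learning rate ``xi`` and the instrumental weight ``delta``.

Perception, learning and action selection are all mean-field variational
updates. State inference combines the log likelihood of the current
observation with the expected log transition probabilities (a digamma
expression under the Dirichlet posterior). Parameter learning adds a scaled
outer product of consecutive state beliefs to the executed action's counts.
Action selection softmaxes the negative expected free energy, which splits
into a parameter-novelty (epistemic) term computed from inverse Dirichlet
counts and an instrumental term scoring predicted observations against the
prior preferences. Four strategies are supported: the full expected-free-
energy score, its instrumental part alone, its epistemic part alone, and a
uniform (random) prior over actions.

All belief updates are written for a general number of states, observations
and controls; the chemotaxis simulations use 2 of each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import digamma

from .environment import Action, Observation

__all__ = [
    "GenerativeModel",
    "Beliefs",
    "Strategy",
    "StepLog",
    "init_model",
    "make_maladaptive_model",
    "expected_log_transitions",
    "infer_state",
    "predict",
    "novelty_matrix",
    "negative_efe",
    "infer_control",
    "sample_action",
    "update_parameters",
    "agent_step",
    "dirichlet_mean",
]

#: floor applied to likelihood entries before taking logs
EPS_FLOOR = 1e-16
#: floor applied to expected log transition probabilities in state inference;
#: kept above EPS_FLOOR so the unambiguous likelihood always dominates the
#: transition message, however extreme the Dirichlet counts
TRANS_LOG_FLOOR = float(np.log(1e-14))

#: defaults used in every chemotaxis simulation
DEFAULT_XI = 0.001
DEFAULT_DELTA = 0.1
DEFAULT_RHO_LOG = (0.0, -60.0)
DEFAULT_CONCENTRATION = 0.5


class Strategy(str, Enum):
    """Action-selection strategy: which score is softmaxed into Q(u)."""

    EFE = "efe"
    INSTRUMENTAL = "instrumental"
    EPISTEMIC = "epistemic"
    RANDOM = "random"


@dataclass
class GenerativeModel:
    """Fixed parameters and priors of the agent's generative model.

    ``alpha`` is indexed ``[u][i, j]`` = prior count for the transition to
    next state ``i`` from previous state ``j`` under control ``u`` (columns
    are previous states). ``rho_log`` holds log prior preferences ln P(o).
    """

    lambda_: np.ndarray
    alpha: np.ndarray
    rho_log: np.ndarray
    delta: float = DEFAULT_DELTA
    xi: float = DEFAULT_XI
    n_states: int = 2
    n_obs: int = 2
    n_controls: int = 2
    log_lambda: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lambda_ = np.maximum(np.asarray(self.lambda_, dtype=float), EPS_FLOOR)
        self.lambda_ /= self.lambda_.sum(axis=0, keepdims=True)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.rho_log = np.asarray(self.rho_log, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("alpha counts must be strictly positive")
        self.log_lambda = np.log(self.lambda_)


@dataclass
class Beliefs:
    """Sufficient statistics of the mean-field approximate posterior."""

    phi_s: np.ndarray
    phi_u: np.ndarray
    phi_alpha: np.ndarray
    prev_phi_s: np.ndarray | None = None
    prev_action: Action | None = None

    def copy(self) -> "Beliefs":
        return Beliefs(
            phi_s=self.phi_s.copy(),
            phi_u=self.phi_u.copy(),
            phi_alpha=self.phi_alpha.copy(),
            prev_phi_s=None if self.prev_phi_s is None else self.prev_phi_s.copy(),
            prev_action=self.prev_action,
        )


@dataclass
class StepLog:
    """Per-step expected-free-energy trace, one entry per control.

    ``instrumental`` is already weighted by ``delta`` so that
    ``neg_efe == epistemic + instrumental`` holds exactly.
    """

    neg_efe: np.ndarray
    epistemic: np.ndarray
    instrumental: np.ndarray
    action: Action
    observation: Observation


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def init_model(
    seed: int | np.random.Generator,
    concentration: float = DEFAULT_CONCENTRATION,
    n_states: int = 2,
    n_obs: int = 2,
    n_controls: int = 2,
    rho_log: tuple[float, ...] | np.ndarray = DEFAULT_RHO_LOG,
    delta: float = DEFAULT_DELTA,
    xi: float = DEFAULT_XI,
) -> tuple[GenerativeModel, Beliefs]:
    """Create a randomly initialized model and matching initial beliefs.

    The likelihood is the identity (the gradient observation reports the
    hidden gradient state unambiguously). Each column of the transition
    prior is ``concentration`` times a draw from a flat Dirichlet, so the
    agent starts with random beliefs about how actions cause transitions
    while every column carries the same total prior count.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    alpha = np.empty((n_controls, n_states, n_states))
    for u in range(n_controls):
        for j in range(n_states):
            alpha[u][:, j] = concentration * rng.dirichlet(np.ones(n_states))
    model = GenerativeModel(
        lambda_=np.eye(n_obs, n_states),
        alpha=alpha,
        rho_log=np.asarray(rho_log, dtype=float),
        delta=delta,
        xi=xi,
        n_states=n_states,
        n_obs=n_obs,
        n_controls=n_controls,
    )
    beliefs = Beliefs(
        phi_s=np.full(n_states, 1.0 / n_states),
        phi_u=np.full(n_controls, 1.0 / n_controls),
        phi_alpha=alpha.copy(),
    )
    return model, beliefs


def make_maladaptive_model(
    seed: int = 0,
    rho_log: tuple[float, ...] | np.ndarray = DEFAULT_RHO_LOG,
    delta: float = DEFAULT_DELTA,
    xi: float = DEFAULT_XI,
) -> tuple[GenerativeModel, Beliefs]:
    """Construct a model caught in a bad bootstrap.

    The positive-gradient columns encode the erroneous belief that tumbling
    is *more* likely than running to keep the agent in a positive gradient
    (Dirichlet means 0.8 vs 0.2), so instrumental value initially favours
    tumbling. Both positive-gradient columns share the same total count and
    mirrored entries, hence identical novelty columns: epistemic value is
    initially equal for the two actions. The negative-gradient columns are
    symmetric across actions.
    """
    alpha = np.empty((2, 2, 2))
    alpha[Action.RUN][:, Observation.POS] = (0.1, 0.4)
    alpha[Action.TUMBLE][:, Observation.POS] = (0.4, 0.1)
    alpha[Action.RUN][:, Observation.NEG] = (0.25, 0.25)
    alpha[Action.TUMBLE][:, Observation.NEG] = (0.25, 0.25)
    model = GenerativeModel(
        lambda_=np.eye(2),
        alpha=alpha,
        rho_log=np.asarray(rho_log, dtype=float),
        delta=delta,
        xi=xi,
    )
    beliefs = Beliefs(
        phi_s=np.full(2, 0.5),
        phi_u=np.full(2, 0.5),
        phi_alpha=alpha.copy(),
    )
    return model, beliefs


def expected_log_transitions(phi_alpha_u: np.ndarray) -> np.ndarray:
    """Posterior-expected log transition matrix for one control.

    Entry ``[i, j]`` is ``digamma(count[i, j]) - digamma(sum_i count[i, j])``,
    the expectation of ``ln theta_ij`` under the column's Dirichlet.
    """
    if np.any(phi_alpha_u <= 0):
        raise ValueError("Dirichlet counts must be strictly positive")
    return digamma(phi_alpha_u) - digamma(phi_alpha_u.sum(axis=0, keepdims=True))


def dirichlet_mean(phi_alpha_u: np.ndarray) -> np.ndarray:
    """Column-wise Dirichlet mean: each column normalized by its sum."""
    return phi_alpha_u / phi_alpha_u.sum(axis=0, keepdims=True)


def infer_state(obs: Observation, beliefs: Beliefs, model: GenerativeModel) -> np.ndarray:
    """Bayesian-filter state update ('perception'); stores and returns phi_s.

    Softmax of the log likelihood of the observation plus the expected log
    transition message from the previous belief under the executed action.
    At t = 0 (no previous action) the transition message is a uniform
    log prior, which drops out of the softmax. The message is floored at
    ``TRANS_LOG_FLOOR`` so that an unambiguous likelihood can never be
    overruled by an extreme transition prior.
    """
    log_lik = model.log_lambda[int(obs), :]
    if beliefs.prev_action is None:
        message = np.full(model.n_states, -np.log(model.n_states))
    else:
        message = (
            np.maximum(
                expected_log_transitions(beliefs.phi_alpha[beliefs.prev_action]),
                TRANS_LOG_FLOOR,
            )
            @ beliefs.prev_phi_s
        )
    beliefs.phi_s = _softmax(log_lik + message)
    return beliefs.phi_s


def predict(
    beliefs: Beliefs, u: Action, model: GenerativeModel
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted next-state and next-observation distributions under ``u``."""
    pred_s = dirichlet_mean(beliefs.phi_alpha[u]) @ beliefs.phi_s
    pred_o = model.lambda_ @ pred_s
    return pred_s, pred_o


def novelty_matrix(phi_alpha_u: np.ndarray) -> np.ndarray:
    """Parameter-novelty matrix W for one control.

    Entry ``[i, j] = 1/count[i, j] - 1/sum_i count[i, j]``: the expected
    information gain about the column-``j`` Dirichlet from observing a
    transition into state ``i``. Non-negative, and vanishing as counts grow.
    """
    if np.any(phi_alpha_u <= 0):
        raise ValueError("Dirichlet counts must be strictly positive")
    return 1.0 / phi_alpha_u - 1.0 / phi_alpha_u.sum(axis=0, keepdims=True)


def _efe_terms(beliefs: Beliefs, u: Action, model: GenerativeModel) -> tuple[float, float]:
    """(epistemic, raw instrumental) value of control ``u``."""
    pred_s, pred_o = predict(beliefs, u, model)
    epistemic = float(pred_s @ novelty_matrix(beliefs.phi_alpha[u]) @ beliefs.phi_s)
    instrumental = float(pred_o @ model.rho_log)
    return epistemic, instrumental


def negative_efe(
    beliefs: Beliefs, u: Action, model: GenerativeModel, strategy: Strategy = Strategy.EFE
) -> float:
    """Negative expected free energy of control ``u`` (one-step lookahead).

    The score the given strategy softmaxes. The EFE strategy combines the
    two parts, tempering the instrumental term by ``delta`` to keep it in
    the same range as the epistemic term; the single-term strategies use
    their raw (unweighted) part, and the random strategy scores every
    control zero.
    """
    if strategy == Strategy.RANDOM:
        return 0.0
    epistemic, instrumental = _efe_terms(beliefs, u, model)
    if strategy == Strategy.EPISTEMIC:
        return epistemic
    if strategy == Strategy.INSTRUMENTAL:
        return instrumental
    return epistemic + model.delta * instrumental


def infer_control(
    beliefs: Beliefs, model: GenerativeModel, strategy: Strategy
) -> np.ndarray:
    """Posterior over controls: softmax of per-control strategy scores."""
    if strategy == Strategy.RANDOM:
        beliefs.phi_u = np.full(model.n_controls, 1.0 / model.n_controls)
        return beliefs.phi_u
    scores = np.array(
        [negative_efe(beliefs, Action(u), model, strategy) for u in range(model.n_controls)]
    )
    beliefs.phi_u = _softmax(scores)
    return beliefs.phi_u


def sample_action(phi_u: np.ndarray, rng: np.random.Generator) -> Action:
    """Draw an action from the categorical posterior over controls."""
    if abs(float(np.sum(phi_u)) - 1.0) > 1e-9 or np.any(phi_u < 0):
        raise ValueError("phi_u must be a probability simplex")
    r = rng.random()
    return Action(int(np.searchsorted(np.cumsum(phi_u), r)))


def update_parameters(beliefs: Beliefs, action: Action, model: GenerativeModel) -> Beliefs:
    """Dirichlet count ('Hebbian') update for the executed action.

    Adds ``xi * outer(phi_s, prev_phi_s)`` to the executed action's counts
    only; the total count therefore grows by exactly ``xi`` per step.
    """
    beliefs.phi_alpha[action] += model.xi * np.outer(beliefs.phi_s, beliefs.prev_phi_s)
    return beliefs


def agent_step(
    obs: Observation,
    beliefs: Beliefs,
    model: GenerativeModel,
    strategy: Strategy,
    rng: np.random.Generator,
    learn: bool = True,
    log: bool = False,
) -> tuple[Action, Beliefs, StepLog | None]:
    """One full perception-action cycle.

    Runs, in order: state inference, control inference, the Dirichlet
    parameter update for the transition that produced the current
    observation (skipped when ``learn`` is False or at t = 0), and action
    sampling. With ``log=True`` the returned :class:`StepLog` records the
    full EFE decomposition per control regardless of strategy.
    """
    infer_state(obs, beliefs, model)
    infer_control(beliefs, model, strategy)
    record = None
    if log:
        terms = np.array([_efe_terms(beliefs, Action(u), model) for u in range(model.n_controls)])
        weighted_instr = model.delta * terms[:, 1]
        record = StepLog(
            neg_efe=terms[:, 0] + weighted_instr,
            epistemic=terms[:, 0].copy(),
            instrumental=weighted_instr,
            action=Action.RUN,  # filled in below
            observation=obs,
        )
    if learn and beliefs.prev_action is not None:
        update_parameters(beliefs, beliefs.prev_action, model)
    action = sample_action(beliefs.phi_u, rng)
    beliefs.prev_phi_s = beliefs.phi_s
    beliefs.prev_action = action
    if record is not None:
        record.action = action
    return action, beliefs, record
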