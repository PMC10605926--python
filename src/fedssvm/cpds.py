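"""Consensus primal-dual splitting solver for the federated sparse SVM.

Each of the m agents holds a hinge block F_j(K_j x_j) with
K_j = Gamma_j A_j (A_j the local margin operator, Gamma_j positive sample
weights) and a local regulariser G_j(x_j) = 0.5*psi_j*||theta_j||^2 +
rho_j*||theta_j||_1. The network-wide problem

    min_x  sum_j G_j(x_j) + F_j(K_j x_j)   s.t.  x_1 = ... = x_m

is solved by a Chambolle-Pock / Condat-Vu primal-dual iteration with two
dual blocks: a local hinge dual u_j per agent, and a consensus dual that
enters only through q = (I - omega)-weighted disagreement, omega being the
Metropolis matrix. Writing L = I - omega (null space = consensus set on a
connected graph), one synchronous round is

    u_j <- clip(u_j + sigma * K_j x~_j - sigma * gamma_j, -1, 0)
    q   <- q + sigma * beta * (L x~)            # neighbour exchange of x~
    x_j <- prox_{tau G_j}(x_j - tau * (K_j' u_j + q_j))
    x~  <- 2 x_new - x_old

which converges whenever tau * sigma * (max_j ||K_j||^2 + beta*||L||) <= 1.
Only primal vectors x~ cross the network; both duals stay local. Fixed
points satisfy L x = 0 (exact consensus) together with global optimality
sum_j (dG_j + K_j' u_j) = 0, so the averaged model solves the centralized
objective, unlike plain mixing-in-the-primal schemes whose fixed points are
biased for heterogeneous data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .datasets import AgentPartition, Dataset
from .network import CommGraph
from .scheduler import CommLog, record_round
from .svm import (Classifier, Hyperparams, build_margin_operator, objective,
                  predict_accuracy, prox_hinge_conjugate, prox_regularizer)

__all__ = ["AgentProblem", "SolverConfig", "SolverState", "agent_problems",
           "initialize", "step", "solve", "consensus_residual",
           "operator_norm", "write_trace"]

TRACE_COLUMNS = ("round", "objective", "consensus_residual",
                 "cumulative_messages", "cumulative_bytes", "test_accuracy")


@dataclass
class AgentProblem:
    """One agent's share: local data, margin operator, weights, penalties."""

    data: Dataset
    hp: Hyperparams
    gamma: Optional[np.ndarray] = None
    A: np.ndarray = field(init=False)
    K: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.data.n_samples < 1:
            raise ValueError("agent needs at least one sample")
        self.A = build_margin_operator(self.data)
        if self.gamma is None:
            self.gamma = np.ones(self.data.n_samples)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (self.data.n_samples,) or np.any(self.gamma <= 0):
            raise ValueError("gamma must be positive, one entry per sample")
        self.K = self.gamma[:, None] * self.A

    def local_objective(self, x: np.ndarray) -> float:
        """gamma-weighted hinge sum plus this agent's penalties at x=(theta, theta0)."""
        hinge = np.maximum(0.0, self.gamma - self.K @ x).sum()
        theta = x[:-1]
        return float(hinge + 0.5 * self.hp.psi * theta @ theta
                     + self.hp.rho * np.abs(theta).sum())


def agent_problems(parts: AgentPartition, hp: Hyperparams) -> list[AgentProblem]:
    """Per-agent problems with psi_j = psi/m, rho_j = rho/m so the federated
    objective at consensus equals the centralized one."""
    m = parts.m
    hp_j = Hyperparams(hp.psi / m, hp.rho / m)
    return [AgentProblem(p, hp_j) for p in parts.parts]


def operator_norm(mat: np.ndarray, iters: int = 100, tol: float = 1e-10,
                  seed: int = 0) -> float:
    """Spectral norm by power iteration on mat' mat."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(mat.shape[1])
    v /= np.linalg.norm(v)
    gram = mat.T @ mat
    lam = 0.0
    for _ in range(iters):
        w = gram @ v
        lam_new = float(np.linalg.norm(w))
        if lam_new == 0.0:
            return 0.0
        v = w / lam_new
        if abs(lam_new - lam) <= tol * max(1.0, lam_new):
            lam = lam_new
            break
        lam = lam_new
    return float(np.sqrt(lam))


@dataclass
class SolverConfig:
    tau: float
    sigma: float
    beta: float = 1.0
    max_rounds: int = 1000
    tol_consensus: float = 0.0
    tol_objective: float = 0.0
    record_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.sigma <= 0 or self.beta < 0:
            raise ValueError("steps must be positive, beta nonnegative")
        if self.max_rounds < 0 or self.record_every < 1:
            raise ValueError("bad round counts")


def default_config(problems: list[AgentProblem], graph: CommGraph,
                   beta: Optional[float] = None, margin: float = 0.9,
                   **kwargs) -> SolverConfig:
    """Steps sigma = 1/Lam, tau = margin/Lam with
    Lam^2 = max_j ||K_j||^2 + beta * ||I - omega||, which satisfies the
    tau*sigma*Lam^2 <= 1 contract with room to spare."""
    k_max = max(operator_norm(p.K) for p in problems)
    norm_l = _consensus_norm(graph)
    if beta is None:
        beta = k_max**2 / norm_l if norm_l > 0 else 0.0
    lam = np.sqrt(k_max**2 + beta * norm_l)
    return SolverConfig(tau=margin / lam, sigma=1.0 / lam, beta=beta, **kwargs)


def _consensus_norm(graph: CommGraph) -> float:
    l_mat = np.eye(graph.m) - graph.weights
    return float(np.max(np.abs(np.linalg.eigvalsh(l_mat)))) if graph.m > 1 else 0.0


@dataclass
class SolverState:
    problems: list[AgentProblem]
    graph: CommGraph
    config: SolverConfig
    x: np.ndarray          # (m, d+1) per-agent primal (theta_j, theta_j0)
    x_tilde: np.ndarray    # extrapolated primals (what gets transmitted)
    u: list[np.ndarray]    # per-agent hinge duals, entries in [-1, 0]
    q: np.ndarray          # (m, d+1) consensus dual contribution
    round: int = 0
    comm: CommLog = field(default_factory=CommLog)
    trace: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.graph.m

    def averaged_classifier(self) -> Classifier:
        xbar = self.x.mean(axis=0)
        return Classifier(xbar[:-1], xbar[-1])

    def global_objective(self, x: Optional[np.ndarray] = None) -> float:
        if x is None:
            x = self.x.mean(axis=0)
        return sum(p.local_objective(x) for p in self.problems)


def consensus_residual(state: SolverState) -> float:
    """max_j ||x_j - xbar||_2."""
    xbar = state.x.mean(axis=0)
    return float(np.max(np.linalg.norm(state.x - xbar, axis=1)))


def initialize(problems: list[AgentProblem], graph: CommGraph,
               config: SolverConfig) -> SolverState:
    """Zero-initialised state; validates shapes and the step-size contract."""
    if len(problems) != graph.m:
        raise ValueError(f"{len(problems)} agent problems but graph.m={graph.m}")
    if graph.weights is None:
        raise ValueError("graph weights unset; call metropolis_weights first")
    d1 = problems[0].A.shape[1]
    if any(p.A.shape[1] != d1 for p in problems):
        raise ValueError("agents disagree on feature dimension")

    k_max = max(operator_norm(p.K) for p in problems)
    bound = config.tau * config.sigma * (k_max**2
                                         + config.beta * _consensus_norm(graph))
    if bound > 1.0 + 1e-9:
        raise ValueError(
            "step-size contract violated: tau*sigma*(max_j ||K_j||^2 + "
            f"beta*||I-omega||) = {bound:.6g} > 1")

    m = graph.m
    return SolverState(
        problems=problems, graph=graph, config=config,
        x=np.zeros((m, d1)), x_tilde=np.zeros((m, d1)),
        u=[np.zeros(p.data.n_samples) for p in problems],
        q=np.zeros((m, d1)),
    )


def step(state: SolverState) -> SolverState:
    """One synchronous round, all agents in parallel (updates in place).

    Agent j reads x~_h only for neighbours h (omega_jh > 0); zero Metropolis
    weights contribute exactly nothing to the mixed term.
    """
    cfg, w = state.config, state.graph.weights
    if state.round >= cfg.max_rounds:
        raise RuntimeError("max_rounds already reached")

    # neighbour exchange: disagreement (I - omega) x~ drives the consensus dual
    disagreement = state.x_tilde - w @ state.x_tilde
    state.q += cfg.sigma * cfg.beta * disagreement

    x_new = np.empty_like(state.x)
    for j, prob in enumerate(state.problems):
        state.u[j] = prox_hinge_conjugate(
            state.u[j] + cfg.sigma * (prob.K @ state.x_tilde[j]),
            cfg.sigma * prob.gamma)
        pull = prob.K.T @ state.u[j] + state.q[j]
        x_new[j] = prox_regularizer(state.x[j] - cfg.tau * pull, cfg.tau,
                                    prob.hp)
        if not np.isfinite(x_new[j]).all():
            raise FloatingPointError(
                f"non-finite iterate at agent {j + 1}, round {state.round + 1}")

    state.x_tilde = 2.0 * x_new - state.x
    state.x = x_new
    state.round += 1

    # one round = every agent sends its primal to each neighbour: 2|E| messages
    n_msgs = 2 * len(state.graph.edges)
    state.comm = record_round(state.comm, n_msgs, state.x.shape[1])

    if state.round % cfg.record_every == 0 or state.round == cfg.max_rounds:
        state.trace.append((state.round, state.global_objective(),
                            consensus_residual(state), state.comm.messages,
                            state.comm.bytes))
    return state


def write_trace(trace: list, path) -> None:
    """Trace rows as CSV; the test_accuracy column is blank where a row
    carries no evaluation."""
    import pandas as pd

    rows = [t + (np.nan,) * (6 - len(t)) for t in trace]
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def solve(problems: list[AgentProblem], graph: CommGraph,
          config: SolverConfig, test_data: Optional[Dataset] = None
          ) -> tuple[Classifier, SolverState]:
    """Run rounds until max_rounds or until both the consensus residual and
    the relative objective drift over the last 10 recorded points fall below
    their tolerances. Returns the network-average classifier."""
    state = initialize(problems, graph, config)
    state.trace.append((0, state.global_objective(), consensus_residual(state),
                        0, 0))
    while state.round < config.max_rounds:
        step(state)
        if (config.tol_consensus > 0 and state.round % config.record_every == 0
                and len(state.trace) >= 10):
            objs = [t[1] for t in state.trace[-10:]]
            ref = max(abs(objs[-1]), 1e-12)
            drift = (max(objs) - min(objs)) / ref
            if (consensus_residual(state) <= config.tol_consensus
                    and drift <= config.tol_objective):
                break
    clf = state.averaged_classifier()
    if test_data is not None:
        _, acc = predict_accuracy(clf, test_data)
        state.trace.append((state.round, state.global_objective(),
                            consensus_residual(state), state.comm.messages,
                            state.comm.bytes, acc))
    return clf, state
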