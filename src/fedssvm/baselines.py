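"""Reference solvers: exact centralized QP oracle and a FedAvg-style comparator.

The QP oracle rewrites the sparse-SVM objective with split weights
theta = theta+ - theta- and slack variables zeta:

    min  0.5*psi*||theta+ - theta-||^2 + sum zeta + rho*sum(theta+ + theta-)
    s.t. l_i (phi_i'(theta+ - theta-) + theta0) + zeta_i >= 1,
         theta+, theta-, zeta >= 0

and hands the (convex, quadratic) program to scipy's trust-constr with exact
gradient and Hessian. A slow proximal-subgradient routine doubles as an
independent cross-check and as the local optimiser inside the FedAvg loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, minimize

from .datasets import AgentPartition, Dataset
from .scheduler import CommLog, record_round
from .svm import Classifier, Hyperparams, objective

__all__ = ["OracleSolution", "solve_centralized_qp", "prox_subgradient",
           "LearningRateSchedule", "fedavg_svm"]


@dataclass
class OracleSolution:
    classifier: Classifier
    objective_value: float
    solver_status: str


def solve_centralized_qp(data: Dataset, hp: Hyperparams,
                         gtol: float = 1e-12, maxiter: int = 5000
                         ) -> OracleSolution:
    """Exact centralized sparse-SVM optimum via the split-variable QP."""
    if data.n_samples < 1:
        raise ValueError("empty dataset")
    n, d = data.n_samples, data.n_features
    phi, lab = data.features, data.labels.astype(float)
    nv = 2 * d + 1 + n  # [theta+, theta-, theta0, zeta]

    def unpack(z):
        return z[:d], z[d:2 * d], z[2 * d], z[2 * d + 1:]

    def fun(z):
        tp, tm, _, zeta = unpack(z)
        th = tp - tm
        return (0.5 * hp.psi * th @ th + zeta.sum()
                + hp.rho * (tp.sum() + tm.sum()))

    def jac(z):
        tp, tm, _, _ = unpack(z)
        th = tp - tm
        g = np.empty(nv)
        g[:d] = hp.psi * th + hp.rho
        g[d:2 * d] = -hp.psi * th + hp.rho
        g[2 * d] = 0.0
        g[2 * d + 1:] = 1.0
        return g

    blk = hp.psi * np.block([[np.eye(d), -np.eye(d)],
                             [-np.eye(d), np.eye(d)]])
    hess_mat = sp.block_diag([sp.csr_matrix(blk),
                              sp.csr_matrix((n + 1, n + 1))]).tocsr()

    lphi = lab[:, None] * phi
    a_lin = sp.hstack([sp.csr_matrix(lphi), sp.csr_matrix(-lphi),
                       sp.csr_matrix(lab[:, None]), sp.eye(n)]).tocsr()
    lb = np.full(nv, 0.0)
    lb[2 * d] = -np.inf
    res = minimize(
        fun, np.zeros(nv), jac=jac, hess=lambda z: hess_mat,
        method="trust-constr",
        constraints=[LinearConstraint(a_lin, lb=1.0, ub=np.inf)],
        bounds=list(zip(lb, np.full(nv, np.inf))),
        options={"gtol": gtol, "xtol": 1e-14, "barrier_tol": 1e-12,
                 "maxiter": maxiter},
    )
    if res.status not in (1, 2):  # gtol / xtol termination
        raise RuntimeError(f"QP oracle did not converge: {res.message}")
    tp, tm, t0, _ = unpack(res.x)
    clf = Classifier(tp - tm, t0)
    return OracleSolution(clf, float(res.fun), "optimal")


def prox_subgradient(data: Dataset, hp: Hyperparams, iters: int,
                     x0: Optional[np.ndarray] = None,
                     lam: Optional[float] = None, eta0: float = 0.1,
                     t_offset: int = 0) -> np.ndarray:
    """Deterministic full-batch proximal subgradient on the sparse-SVM
    objective normalised by n. Step eta_t = min(eta0, 1/(lam*t)); lam
    defaults to the normalised strong-convexity constant psi/n.

    Returns the stacked iterate x = (theta, theta0). Independent of the
    primal-dual and QP code paths: used as a second oracle in tests.
    """
    n, d = data.n_samples, data.n_features
    phi, lab = data.features, data.labels.astype(float)
    x = np.zeros(d + 1) if x0 is None else np.array(x0, dtype=float)
    if lam is None or lam <= 0:
        lam = max(hp.psi / n, 1e-12)
    psi_n, rho_n = hp.psi / n, hp.rho / n
    for t in range(1 + t_offset, iters + 1 + t_offset):
        eta = min(eta0, 1.0 / (lam * t))
        margins = lab * (phi @ x[:-1] + x[-1])
        active = margins < 1.0
        g_theta = -(lab[active, None] * phi[active]).sum(axis=0) / n
        g_bias = -lab[active].sum() / n
        x[:-1] -= eta * (g_theta + psi_n * x[:-1])
        x[-1] -= eta * g_bias
        x[:-1] = np.sign(x[:-1]) * np.maximum(np.abs(x[:-1]) - eta * rho_n, 0.0)
    return x


@dataclass(frozen=True)
class LearningRateSchedule:
    """eta_t = min(eta0, 1/(lam*t)) over the cumulative step counter t."""

    kind: str = "inverse_t"
    lam: Optional[float] = None
    eta0: float = 0.1

    def __post_init__(self) -> None:
        if self.kind != "inverse_t":
            raise ValueError(f"unknown schedule kind {self.kind!r}")


def fedavg_svm(parts: AgentPartition, hp: Hyperparams, rounds: int,
               local_epochs: int = 1,
               schedule: Optional[LearningRateSchedule] = None,
               seed: int = 0, test_data: Optional[Dataset] = None,
               record_every: int = 10
               ) -> tuple[Classifier, list, CommLog]:
    """FedAvg comparator: per round every agent runs ``local_epochs``
    deterministic full-batch proximal-subgradient passes on its local share
    of the global objective, then the server averages weighted by n_j.

    rounds=0 returns the zero classifier. Each round costs 2*m messages
    (upload + download of one model vector per client). The trace rows are
    (round, global objective, pre-average disagreement, cumulative messages,
    cumulative bytes[, test accuracy]).
    """
    if rounds < 0 or local_epochs < 1:
        raise ValueError("rounds must be >= 0 and local_epochs >= 1")
    if any(p.n_samples < 1 for p in parts.parts):
        raise ValueError("degenerate partition: empty agent")
    schedule = schedule or LearningRateSchedule()
    m = parts.m
    n = parts.n_total
    d = parts.parts[0].n_features
    weights = np.array([p.n_samples for p in parts.parts], float) / n
    def global_obj(x: np.ndarray) -> float:
        total = sum(
            np.maximum(0.0, 1.0 - p.labels * (p.features @ x[:-1] + x[-1])).sum()
            for p in parts.parts)
        return float(total + 0.5 * hp.psi * x[:-1] @ x[:-1]
                     + hp.rho * np.abs(x[:-1]).sum())

    x_global = np.zeros(d + 1)
    comm = CommLog()
    trace = []
    t_counter = 0
    for r in range(1, rounds + 1):
        locals_x = np.empty((m, d + 1))
        for j, part in enumerate(parts.parts):
            # penalties scaled by n_j/n so every agent sees the global
            # per-sample rates psi/n, rho/n after local normalisation
            hp_local = Hyperparams(hp.psi * part.n_samples / n,
                                   hp.rho * part.n_samples / n)
            locals_x[j] = prox_subgradient(
                part, hp_local, iters=local_epochs, x0=x_global,
                lam=schedule.lam, eta0=schedule.eta0, t_offset=t_counter)
        t_counter += local_epochs
        disagreement = float(np.max(np.linalg.norm(
            locals_x - weights @ locals_x, axis=1)))
        x_global = weights @ locals_x
        comm = record_round(comm, 2 * m, d + 1)
        if r % record_every == 0 or r == rounds:
            row = [r, global_obj(x_global), disagreement,
                   comm.messages, comm.bytes]
            if test_data is not None:
                from .svm import predict_accuracy
                row.append(predict_accuracy(
                    Classifier(x_global[:-1], x_global[-1]), test_data)[1])
            trace.append(tuple(row))
    return Classifier(x_global[:-1], x_global[-1]), trace, comm
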