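"""Mk-model engine: CTMC transition probabilities, pruning likelihood,
ML rate estimation, and marginal ancestral state reconstruction.

The Mk model is a continuous-time Markov chain on k discrete character
states.  Rate structures:

* ``ER``  — equal rates, one free parameter q; Q_ij = q (i != j).
* ``SYM`` — symmetric rates, k(k-1)/2 free parameters.
* ``ARD`` — all rates different, k(k-1) free parameters.

The likelihood of a tip-state configuration is computed by the pruning
algorithm (a post-order dynamic program over conditional partial
likelihoods), and marginal ancestral posteriors by a second, pre-order
pass that combines each node's downward partials with an "upward" message
carrying the information from the rest of the tree.  Per-node rescaling
keeps everything finite on large trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .phylo import Node, PhyloTree

BINARY_STATES = ("monomorphic", "dimorphic")
TERNARY_STATES = ("monomorphic", "male_enlarged", "female_enlarged")

#: branch lengths below this are floored inside the engine only (the stored
#: tree is never modified); avoids singular P(t) on zero-length terminals
LENGTH_FLOOR = 1e-8

RATE_STRUCTURES = ("ER", "SYM", "ARD")


def _n_free_rates(k: int, structure: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]


@dataclass(frozen=True)
class MkModel:
    """A k-state Mk model: state labels, rate structure, free rates, root prior.

    ``root_prior`` is ``"uniform"`` (default; also the ER stationary
    distribution), ``"stationary"``, or an explicit probability vector.
    """

    states: tuple[str, ...]
    rate_structure: str = "ER"
    rates: tuple[float, ...] = (1.0,)
    root_prior: Union[str, tuple[float, ...]] = "uniform"

    def __post_init__(self):
        if self.rate_structure not in RATE_STRUCTURES:
            raise ValueError(f"unknown rate structure {self.rate_structure!r}")
        k = len(self.states)
        if k < 2:
            raise ValueError("need at least 2 states")
        want = _n_free_rates(k, self.rate_structure)
        if len(self.rates) != want:
            raise ValueError(
                f"{self.rate_structure} with k={k} needs {want} rates, "
                f"got {len(self.rates)}")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")

    @property
    def k(self) -> int:
        return len(self.states)

    def Q(self) -> np.ndarray:
        """Generator matrix: nonnegative off-diagonals, rows sum to zero."""
        k = self.k
        Q = np.zeros((k, k))
        if self.rate_structure == "ER":
            Q[:] = self.rates[0]
        elif self.rate_structure == "SYM":
            it = iter(self.rates)
            for i in range(k):
                for j in range(i + 1, k):
                    Q[i, j] = Q[j, i] = next(it)
        else:  # ARD
            it = iter(self.rates)
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = next(it)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalized (uniform for ER/SYM)."""
        if self.rate_structure in ("ER", "SYM"):
            return np.full(self.k, 1.0 / self.k)
        Q = self.Q()
        vals, vecs = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(vals)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def prior_vector(self) -> np.ndarray:
        if isinstance(self.root_prior, str):
            if self.root_prior == "uniform":
                return np.full(self.k, 1.0 / self.k)
            if self.root_prior == "stationary":
                return self.stationary_distribution()
            raise ValueError(f"unknown root prior {self.root_prior!r}")
        pi = np.asarray(self.root_prior, dtype=float)
        if pi.shape != (self.k,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("fixed root prior must be a length-k probability vector")
        return pi

    def state_index(self, label: str) -> int:
        return self.states.index(label)


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt), a row-stochastic k x k matrix.

    Uses the ER closed forms for k = 2 and k = 3 (exact, cheap); otherwise
    the scipy matrix exponential.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    k = model.k
    if model.rate_structure == "ER":
        q = model.rates[0]
        # ER closed form: off-diagonal entries (1 - e^{-kqt})/k,
        # diagonal 1 - (k-1)(1 - e^{-kqt})/k
        e = np.exp(-k * q * t)
        p_diff = (1.0 - e) / k
        P = np.full((k, k), p_diff)
        np.fill_diagonal(P, 1.0 - (k - 1) * p_diff)
        return P
    return expm(model.Q() * t)


@dataclass
class ASRResult:
    """Marginal reconstruction output.

    ``node_probs`` maps internal-node id -> posterior probability vector
    (ordered as ``model.states``); ``map_states`` the argmax label per node;
    ``tied_nodes`` lists nodes whose top two posteriors are within 1e-9.
    """

    model: MkModel
    log_likelihood: float
    node_probs: dict[int, np.ndarray]
    map_states: dict[int, str]
    tied_nodes: list[int] = field(default_factory=list)
    method: str = "marginal"


# -- internal machinery -------------------------------------------------------

def _edge_length(node: Node) -> float:
    t = node.length if node.length is not None else 0.0
    return max(t, LENGTH_FLOOR)


def _tip_partial(model: MkModel, state: str) -> np.ndarray:
    v = np.zeros(model.k)
    try:
        v[model.state_index(state)] = 1.0
    except ValueError:
        raise ValueError(
            f"tip state {state!r} not among model states {model.states}") from None
    return v


def _downward_pass(tree: PhyloTree, tips: Mapping[str, str], model: MkModel):
    """Post-order partials with per-node rescaling.

    Returns (partials, log_scale, P_edges): ``partials[id]`` is the rescaled
    conditional likelihood vector at each node, ``log_scale`` the summed log
    scalers, and ``P_edges[id]`` the transition matrix on the branch above
    each non-root node.
    """
    missing = [l for l in tree.leaf_labels() if l not in tips]
    if missing:
        raise ValueError(f"leaves without a tip state: {sorted(missing)}; "
                         "prune them before computing the likelihood")
    partials: dict[int, np.ndarray] = {}
    P_edges: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node is not tree.root:
            P_edges[node.id] = transition_matrix(model, _edge_length(node))
        if node.is_leaf:
            partials[node.id] = _tip_partial(model, tips[node.label])
            continue
        part = np.ones(model.k)
        for child in node.children:
            part = part * (P_edges[child.id] @ partials[child.id])
        s = part.max()
        if s > 0:
            part = part / s
            log_scale += np.log(s)
        partials[node.id] = part
    return partials, log_scale, P_edges


def log_likelihood(tree: PhyloTree, tips: Mapping[str, str],
                   model: MkModel) -> float:
    """Pruning-algorithm log-likelihood of the tip states.

    Returns ``-inf`` for configurations of probability zero (e.g. a
    zero-rate model with discordant tips).
    """
    partials, log_scale, _ = _downward_pass(tree, tips, model)
    root_lik = float(model.prior_vector() @ partials[tree.root.id])
    if root_lik <= 0.0:
        return -np.inf
    return np.log(root_lik) + log_scale


def log_likelihood_brute_force(tree: PhyloTree, tips: Mapping[str, str],
                               model: MkModel) -> float:
    """Exhaustive enumeration over all internal-node state assignments.

    Independent oracle for the pruning algorithm; cost k^(#internal nodes),
    intended for trees of a handful of leaves only.
    """
    import itertools

    internal = tree.internal_nodes()
    pi = model.prior_vector()
    P = {n.id: transition_matrix(model, _edge_length(n))
         for n in tree.postorder() if n is not tree.root}
    k = model.k
    total = 0.0
    state_of: dict[int, int] = {
        leaf.id: model.state_index(tips[leaf.label]) for leaf in tree.leaves()}
    for assign in itertools.product(range(k), repeat=len(internal)):
        for node, s in zip(internal, assign):
            state_of[node.id] = s
        term = pi[state_of[tree.root.id]]
        for node in tree.postorder():
            if node is tree.root:
                continue
            term *= P[node.id][state_of[node.parent.id], state_of[node.id]]
        total += term
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))


def marginal_posteriors_brute_force(tree: PhyloTree, tips: Mapping[str, str],
                                    model: MkModel) -> dict[int, np.ndarray]:
    """Node posteriors by marginalizing the exhaustive joint (oracle)."""
    import itertools

    internal = tree.internal_nodes()
    pi = model.prior_vector()
    P = {n.id: transition_matrix(model, _edge_length(n))
         for n in tree.postorder() if n is not tree.root}
    k = model.k
    acc = {n.id: np.zeros(k) for n in internal}
    state_of: dict[int, int] = {
        leaf.id: model.state_index(tips[leaf.label]) for leaf in tree.leaves()}
    for assign in itertools.product(range(k), repeat=len(internal)):
        for node, s in zip(internal, assign):
            state_of[node.id] = s
        term = pi[state_of[tree.root.id]]
        for node in tree.postorder():
            if node is tree.root:
                continue
            term *= P[node.id][state_of[node.parent.id], state_of[node.id]]
        for node, s in zip(internal, assign):
            acc[node.id][s] += term
    return {nid: v / v.sum() for nid, v in acc.items()}


def marginal_asr(tree: PhyloTree, tips: Mapping[str, str], model: MkModel,
                 *, method: str = "marginal") -> ASRResult:
    """Two-pass ancestral state reconstruction.

    ``method="marginal"`` (default) computes exact marginal posteriors:
    the pre-order pass propagates, for each node, the likelihood of all
    data *outside* its subtree (the upward message), so that

        P(state_v = i | data)  ∝  up_v[i] * down_v[i].

    ``method="conditional"`` is a fast approximate variant in which the
    pre-order pass reuses the parent's finished posterior instead of the
    exclusive message; it mirrors the conditional-scaled two-pass values
    some ancestral-character-estimation routines report and is provided
    for comparison only.
    """
    if method not in ("marginal", "conditional"):
        raise ValueError(f"unknown method {method!r}")
    partials, log_scale, P_edges = _downward_pass(tree, tips, model)
    pi = model.prior_vector()
    root_lik = float(pi @ partials[tree.root.id])
    ll = -np.inf if root_lik <= 0 else np.log(root_lik) + log_scale

    # child messages M_c(j) = sum_i P_c[j, i] down_c(i)
    messages = {nid: P_edges[nid] @ partials[nid] for nid in P_edges}

    up: dict[int, np.ndarray] = {tree.root.id: pi.copy()}
    node_probs: dict[int, np.ndarray] = {}
    map_states: dict[int, str] = {}
    tied: list[int] = []
    for node in tree.preorder():
        if node is not tree.root:
            parent = node.parent
            if method == "marginal":
                g = up[parent.id].copy()
                for sib in parent.children:
                    if sib is not node:
                        g = g * messages[sib.id]
            else:  # conditional: reuse the parent's full posterior
                g = up[parent.id] * partials[parent.id]
            # message through the branch above v: sum over parent state j
            a = P_edges[node.id].T @ g
            s = a.max()
            up[node.id] = a / s if s > 0 else a
        if node.is_leaf:
            continue
        post = up[node.id] * partials[node.id]
        tot = post.sum()
        post = post / tot if tot > 0 else np.full(model.k, 1.0 / model.k)
        node_probs[node.id] = post
        order = np.sort(post)[::-1]
        if len(order) > 1 and order[0] - order[1] <= 1e-9:
            tied.append(node.id)
        map_states[node.id] = model.states[int(np.argmax(post))]
    return ASRResult(model=model, log_likelihood=ll, node_probs=node_probs,
                     map_states=map_states, tied_nodes=tied, method=method)


# -- rate estimation ----------------------------------------------------------

RATE_BOUNDS = (1e-8, 1e3)


@dataclass
class FitResult:
    model: MkModel
    log_likelihood: float
    converged: bool
    at_lower_bound: bool
    n_evaluations: int


def fit_rates(tree: PhyloTree, tips: Mapping[str, str],
              states: Sequence[str], *, rate_structure: str = "ER",
              root_prior: Union[str, tuple[float, ...]] = "uniform") -> FitResult:
    """Maximum-likelihood rate estimation.

    ER uses bounded scalar search on log q (bounds 1e-8..1e3 per unit branch
    length, tolerance ~1e-10 in log-likelihood); SYM/ARD use L-BFGS-B on
    log-rates.  If all tips share one state the MLE is at the q -> 0
    boundary; the lower bound is returned with ``at_lower_bound=True``.
    """
    states = tuple(states)
    observed = {tips[l] for l in tree.leaf_labels()}
    lo, hi = RATE_BOUNDS
    n_free = _n_free_rates(len(states), rate_structure)
    evals = 0

    def make(rates) -> MkModel:
        return MkModel(states=states, rate_structure=rate_structure,
                       rates=tuple(float(r) for r in np.atleast_1d(rates)),
                       root_prior=root_prior)

    if len(observed) < 2:
        model = make([lo] * n_free)
        return FitResult(model=model,
                         log_likelihood=log_likelihood(tree, tips, model),
                         converged=True, at_lower_bound=True, n_evaluations=1)

    if rate_structure == "ER":
        def neg_ll(log_q: float) -> float:
            nonlocal evals
            evals += 1
            return -log_likelihood(tree, tips, make(np.exp(log_q)))

        res = minimize_scalar(neg_ll, bounds=(np.log(lo), np.log(hi)),
                              method="bounded",
                              options={"xatol": 1e-10, "maxiter": 500})
        q_hat = float(np.exp(res.x))
        model = make(q_hat)
        return FitResult(model=model, log_likelihood=-float(res.fun),
                         converged=bool(res.success),
                         at_lower_bound=q_hat <= lo * 1.01,
                         n_evaluations=evals)

    # multivariate: quasi-Newton on log-rates
    x0 = np.zeros(n_free)

    def neg_ll_vec(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        ll = log_likelihood(tree, tips, make(np.exp(x)))
        return 1e12 if not np.isfinite(ll) else -ll

    res = minimize(neg_ll_vec, x0, method="L-BFGS-B",
                   bounds=[(np.log(lo), np.log(hi))] * n_free,
                   options={"maxiter": 500, "ftol": 1e-12})
    rates = np.exp(res.x)
    model = make(rates)
    return FitResult(model=model, log_likelihood=-float(res.fun),
                     converged=bool(res.success),
                     at_lower_bound=bool(np.any(rates <= lo * 1.01)),
                     n_evaluations=evals)
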