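"""Two-state Mk ancestral-state reconstruction of mating system.

Thallism is coded as a binary character (homothallic = 0, heterothallic
= 1, unknown = ``?``) evolving along a fixed rooted tree under a
continuous-time Markov chain with rates ``q01`` (0→1) and ``q10`` (1→0).
For two states the transition matrix has the closed form

    P(t) = Π + (I − Π) · exp(−(q01+q10) t),     Π = rows of (π0, π1),

with stationary frequencies π0 = q10/(q01+q10), π1 = q01/(q01+q10).
Likelihoods use Felsenstein pruning; unknown tips contribute the partial
likelihood (1, 1).  Marginal node posteriors come from the standard
up–down (inside–outside) pass, and rate uncertainty is integrated by a
small Metropolis–Hastings sampler over (q01, q10) with node posteriors
averaged over the retained samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

UNKNOWN = "?"


@dataclass
class Mk2Params:
    """Rates and root prior of the two-state Markov model."""

    q01: float = 1.0
    q10: float = 1.0
    root_prior: tuple[float, float] | None = None  # None -> stationary

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        if self.root_prior is not None:
            if abs(sum(self.root_prior) - 1.0) > 1e-9:
                raise ValueError("root prior must sum to 1")

    def stationary(self) -> np.ndarray:
        q = self.q01 + self.q10
        if q == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / q, self.q01 / q])

    def prior(self) -> np.ndarray:
        if self.root_prior is not None:
            return np.asarray(self.root_prior, dtype=float)
        return self.stationary()

    def transition_matrix(self, t: float) -> np.ndarray:
        """Exact 2-state matrix exponential P(t) = expm(Q t)."""
        if t < 0:
            raise ValueError("negative branch length")
        q = self.q01 + self.q10
        if q == 0 or t == 0:
            e = 1.0 if q == 0 else float(np.exp(-q * t))
        else:
            e = float(np.exp(-q * t))
        pi = self.stationary()
        p = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                p[i, j] = pi[j] + ((1.0 if i == j else 0.0) - pi[j]) * e
        return p


@dataclass
class PhyloTree:
    """A rooted tree flattened to arrays in post-order.

    ``children[i]`` lists child indices of node ``i``; ``blen[i]`` is the
    branch above node ``i`` (0 at the root).  ``postorder`` ends at the
    root.  Leaf labels must be unique.
    """

    children: list[list[int]]
    blen: np.ndarray
    postorder: list[int]
    labels: dict[int, str]  # leaf node index -> taxon label
    node_names: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children: list[list[int]] = [[] for _ in nodes]
        blen = np.zeros(len(nodes))
        labels: dict[int, str] = {}
        for n in nodes:
            i = index[id(n)]
            blen[i] = n.edge.length if n.edge.length is not None else 0.0
            for ch in n.child_nodes():
                children[i].append(index[id(ch)])
            if n.is_leaf():
                if n.taxon is None or n.taxon.label is None:
                    raise ValueError("leaf without a taxon label")
                labels[i] = n.taxon.label
        if len(set(labels.values())) != len(labels):
            raise ValueError("leaf labels must be unique")
        post = [index[id(n)] for n in tree.postorder_node_iter()]
        names = [""] * len(nodes)
        for rank, i in enumerate(post):
            names[i] = f"node{rank}"
        return cls(children, blen, post, labels, names)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls.from_dendropy(tree)


def _tip_partials(tree: PhyloTree, tips: dict[str, str]) -> np.ndarray:
    """Leaf partial-likelihood rows; '?' tips are (1, 1)."""
    missing = set(l for l in tree.labels.values()) - set(tips)
    if missing:
        raise ValueError(f"tip states missing for: {sorted(missing)}")
    partials = np.ones((tree.n_nodes, 2))
    for i, label in tree.labels.items():
        s = str(tips[label])
        if s == UNKNOWN:
            continue
        if s not in ("0", "1"):
            raise ValueError(f"tip state for {label!r} must be 0, 1 or ?, got {s!r}")
        partials[i] = 0.0
        partials[i, int(s)] = 1.0
    return partials


def _pruning(tree: PhyloTree, tips: dict[str, str], params: Mk2Params):
    """Post-order partials and per-branch transition matrices."""
    if np.any(~np.isfinite(tree.blen)) or np.any(tree.blen < 0):
        raise ValueError("branch lengths must be finite and non-negative")
    partials = _tip_partials(tree, tips)
    pmats = np.empty((tree.n_nodes, 2, 2))
    for i in range(tree.n_nodes):
        pmats[i] = params.transition_matrix(float(tree.blen[i]))
    for i in tree.postorder:
        if tree.children[i]:
            v = np.ones(2)
            for c in tree.children[i]:
                v = v * (pmats[c] @ partials[c])
            partials[i] = v
    return partials, pmats


def mk2_loglik(tree: PhyloTree, tips: dict[str, str], params: Mk2Params) -> float:
    """Felsenstein-pruning log-likelihood of the tip states."""
    partials, _ = _pruning(tree, tips, params)
    like = float(params.prior() @ partials[tree.root])
    if like <= 0:
        return -np.inf
    return float(np.log(like))


def marginal_posteriors(
    tree: PhyloTree, tips: dict[str, str], params: Mk2Params
) -> dict[int, np.ndarray]:
    """Marginal posterior P(state | data) at every node (up–down pass)."""
    partials, pmats = _pruning(tree, tips, params)
    outside = np.zeros((tree.n_nodes, 2))
    outside[tree.root] = params.prior()
    for i in reversed(tree.postorder):  # pre-order
        for c in tree.children[i]:
            sib = np.ones(2)
            for other in tree.children[i]:
                if other != c:
                    sib = sib * (pmats[other] @ partials[other])
            outside[c] = (outside[i] * sib) @ pmats[c]
    post: dict[int, np.ndarray] = {}
    for i in range(tree.n_nodes):
        v = outside[i] * partials[i]
        total = v.sum()
        if total <= 0:
            raise ValueError("zero likelihood; check tip states and rates")
        post[i] = v / total
    return post


def simulate_mk2(
    tree: PhyloTree, params: Mk2Params, seed: int | np.random.Generator = 0
) -> tuple[dict[str, str], dict[int, int]]:
    """Simulate tip states (and true node states) under the model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parent = [-1] * tree.n_nodes
    for i in range(tree.n_nodes):
        for c in tree.children[i]:
            parent[c] = i
    states: dict[int, int] = {tree.root: int(rng.random() < params.prior()[1])}
    for i in reversed(tree.postorder):  # pre-order: parents before children
        if i == tree.root:
            continue
        p = params.transition_matrix(float(tree.blen[i]))[states[parent[i]]]
        states[i] = int(rng.random() < p[1])
    tips = {tree.labels[i]: str(states[i]) for i in tree.leaves}
    return tips, states


@dataclass
class McmcResult:
    samples: np.ndarray          # (n, 2) retained (q01, q10) draws
    acceptance_rate: float
    mean_posteriors: dict[int, np.ndarray]
    node_names: list[str]


def mcmc_rates(
    tree: PhyloTree,
    tips: dict[str, str],
    n_samples: int = 1000,
    seed: int = 0,
    burn_in: int = 200,
    proposal_sd: float = 0.35,
    prior_mean: float = 1.0,
    equal_rates: bool = False,
    posterior_thin: int = 5,
    root_prior: tuple[float, float] | None = None,
) -> McmcResult:
    """Metropolis–Hastings over (q01, q10) with exponential priors.

    Proposals are log-normal (symmetric on the log scale, with the
    Jacobian term included in the acceptance ratio).  Node posteriors are
    averaged over every ``posterior_thin``-th retained sample.  A given
    seed reproduces the chain exactly.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)

    def logpost(q01: float, q10: float) -> float:
        ll = mk2_loglik(tree, tips, Mk2Params(q01, q10, root_prior))
        lp = -(q01 + q10) / prior_mean  # exponential prior, mean prior_mean
        return ll + lp

    q = np.array([prior_mean, prior_mean])
    lp = logpost(*q)
    samples = np.empty((n_samples, 2))
    accepted = 0
    total = burn_in + n_samples
    post_sum: dict[int, np.ndarray] = {}
    n_post = 0
    window_rejects = 0
    for it in range(total):
        prop = q * np.exp(rng.normal(0.0, proposal_sd, size=2))
        if equal_rates:
            prop[1] = prop[0]
        lp_prop = logpost(*prop)
        # log-normal proposal: Jacobian ratio prod(prop)/prod(q)
        log_accept = lp_prop - lp + np.log(prop).sum() - np.log(q).sum()
        if np.log(rng.random()) < log_accept:
            q, lp = prop, lp_prop
            accepted += 1
            window_rejects = 0
        else:
            window_rejects += 1
            if window_rejects == 200:
                logger.warning("no acceptance over 200 iterations; tune proposal_sd")
        if it >= burn_in:
            k = it - burn_in
            samples[k] = q
            if k % posterior_thin == 0:
                post = marginal_posteriors(tree, tips, Mk2Params(q[0], q[1], root_prior))
                for node, v in post.items():
                    post_sum[node] = post_sum.get(node, 0.0) + v
                n_post += 1
    mean_post = {node: v / n_post for node, v in post_sum.items()}
    return McmcResult(samples, accepted / total, mean_post, tree.node_names)


def posteriors_tsv(tree: PhyloTree, posteriors: dict[int, np.ndarray]) -> str:
    """Node posterior table; node labels are post-order indices."""
    lines = ["node\ttaxon\tp_homothallic\tp_heterothallic"]
    for rank, i in enumerate(tree.postorder):
        taxon = tree.labels.get(i, "")
        p = posteriors[i]
        lines.append(f"node{rank}\t{taxon}\t{p[0]:.6f}\t{p[1]:.6f}")
    return "\n".join(lines) + "\n"
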