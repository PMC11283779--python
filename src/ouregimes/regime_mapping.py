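"""Locomotor-regime painting, equal-rates Mk fitting, and stochastic character maps.

The locomotor categories (ground, arboreal, glider, flyer) are collapsed
into painting schemes; an equal-rates Mk model is fitted to the painted tip
states by maximum likelihood (Felsenstein pruning); and full character
histories (simmaps) are drawn from the posterior of histories given the
tips by backward-forward node-state sampling followed by endpoint-
conditioned CTMC path sampling on each branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo import Phylogeny, write_simmap_newick, parse_simmap_newick

__all__ = [
    "CATEGORIES",
    "SCHEMES",
    "RegimeScheme",
    "RegimeMap",
    "MkFit",
    "paint_scheme",
    "fit_mk_er",
    "sample_simmap",
]

#: canonical locomotor categories, in the conventional ground -> flyer order
CATEGORIES = ("ground", "arboreal", "glider", "flyer")


@dataclass(frozen=True)
class RegimeScheme:
    """A total mapping from the four locomotor categories to regime labels."""

    name: str
    mapping: dict

    def __post_init__(self):
        missing = set(CATEGORIES) - set(self.mapping)
        if missing:
            raise ValueError(f"scheme {self.name!r} misses categories {sorted(missing)}")

    @property
    def regimes(self) -> tuple:
        seen = []
        for c in CATEGORIES:
            r = self.mapping[c]
            if r not in seen:
                seen.append(r)
        return tuple(seen)


#: the four painting schemes: identity, and the three two-group mergers
SCHEMES = {
    "loc4": RegimeScheme("loc4", {c: c for c in CATEGORIES}),
    "loc3a": RegimeScheme("loc3a", {"ground": "ground", "arboreal": "arboreal",
                                    "glider": "glider+flyer", "flyer": "glider+flyer"}),
    "loc3b": RegimeScheme("loc3b", {"ground": "ground", "arboreal": "arboreal+glider",
                                    "glider": "arboreal+glider", "flyer": "flyer"}),
    "loc3c": RegimeScheme("loc3c", {"ground": "ground+arboreal", "arboreal": "ground+arboreal",
                                    "glider": "glider", "flyer": "flyer"}),
}


def paint_scheme(categories: dict, scheme) -> dict:
    """Relabel species locomotor categories under a painting scheme.

    ``scheme`` may be a :class:`RegimeScheme` or one of the names in
    :data:`SCHEMES`.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    out = {}
    for sp, cat in categories.items():
        if cat not in scheme.mapping:
            raise KeyError(f"species {sp!r} has unknown category {cat!r}")
        out[sp] = scheme.mapping[cat]
    return out


# ---------------------------------------------------------------- regime maps

@dataclass
class RegimeMap:
    """A piecewise-constant regime history along every branch of a tree.

    ``segments[i]`` lists (regime, duration) pairs for the branch above node
    ``i``, ordered rootward to tipward; the root's entry is a single
    zero-duration segment carrying the root state.
    """

    tree: Phylogeny
    segments: list
    _path_cache: dict = field(default=None, repr=False, compare=False)

    def validate(self, tol: float = 1e-8):
        t = self.tree
        for i in range(t.n_nodes):
            segs = self.segments[i]
            if not segs:
                raise ValueError(f"node {i} has no segments")
            if t.parent[i] < 0:
                continue
            total = sum(d for _, d in segs)
            if abs(total - t.lengths[i]) > tol * max(1.0, t.lengths[i]):
                raise ValueError(
                    f"segments on branch {i} sum to {total}, branch length {t.lengths[i]}")
            if any(d < 0 for _, d in segs):
                raise ValueError(f"negative segment duration on branch {i}")
            if any(a == b for (a, _), (b, _) in zip(segs, segs[1:])):
                raise ValueError(f"adjacent equal-state segments on branch {i}")
            parent_end = self.node_state(t.parent[i])
            if segs[0][0] != parent_end:
                raise ValueError(
                    f"branch {i} starts in {segs[0][0]!r} but parent ends in {parent_end!r}")

    def node_state(self, node: int) -> str:
        """Regime at a node = state at the end of the branch above it."""
        return self.segments[node][-1][0]

    @property
    def root_state(self) -> str:
        return self.segments[self.tree.root][-1][0]

    @property
    def tip_states(self) -> dict:
        return {self.tree.labels[i]: self.node_state(i) for i in self.tree.tips}

    @property
    def states(self) -> tuple:
        seen = set()
        for segs in self.segments:
            seen.update(s for s, _ in segs)
        return tuple(sorted(seen))

    def n_transitions(self) -> int:
        return sum(len(self.segments[i]) - 1
                   for i in range(self.tree.n_nodes) if self.tree.parent[i] >= 0)

    def tip_path_segments(self, tip: int):
        """(regime, t0, t1) pieces along the root-to-tip path, t measured from the root.

        Memoized; maps are treated as immutable once constructed.
        """
        if self._path_cache is None:
            self._path_cache = {}
        if tip in self._path_cache:
            return self._path_cache[tip]
        nodes = self.tree.path_to_root(tip)[::-1]  # root first
        out, t = [], 0.0
        for nd in nodes:
            if self.tree.parent[nd] < 0:
                continue
            for state, dur in self.segments[nd]:
                out.append((state, t, t + dur))
                t += dur
        self._path_cache[tip] = out
        return out

    def to_simmap_newick(self) -> str:
        segs = [list(s) for s in self.segments]
        # the root's bookkeeping segment is not written
        segs[self.tree.root] = []
        return write_simmap_newick(self.tree, segs)

    @classmethod
    def from_simmap_newick(cls, text: str) -> "RegimeMap":
        tree, segs = parse_simmap_newick(text)
        root = tree.root
        if not segs[root]:
            # root state = starting state of any child branch
            child = tree.children[root][0]
            segs[root] = [(segs[child][0][0], 0.0)]
        rm = cls(tree, segs)
        rm.validate()
        return rm

    @classmethod
    def constant(cls, tree: Phylogeny, state: str) -> "RegimeMap":
        segs = [[(state, float(tree.lengths[i]))] for i in range(tree.n_nodes)]
        segs[tree.root] = [(state, 0.0)]
        return cls(tree, segs)


# ------------------------------------------------------------------ Mk model

@dataclass
class MkFit:
    """Equal-rates Mk fit: one transition rate q shared by all state pairs."""

    states: tuple
    q: float
    log_likelihood: float
    root_prior: np.ndarray = field(default=None)
    boundary: bool = False

    @property
    def k(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        k = self.k
        Q = np.full((k, k), self.q)
        np.fill_diagonal(Q, -(k - 1) * self.q)
        return Q

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) in closed form for the equal-rates model."""
        k = self.k
        decay = np.exp(-k * self.q * t)
        off = (1.0 - decay) / k
        P = np.full((k, k), off)
        np.fill_diagonal(P, off + decay)
        return P


def _tip_state_array(tree: Phylogeny, tip_states: dict, states: tuple) -> np.ndarray:
    idx = {s: i for i, s in enumerate(states)}
    n = tree.n_nodes
    L = np.ones((n, len(states)))
    for t in tree.tips:
        lab = tree.labels[t]
        if lab not in tip_states:
            raise KeyError(f"tip {lab!r} has no state")
        L[t] = 0.0
        L[t, idx[tip_states[lab]]] = 1.0
    return L


def _mk_partials(tree: Phylogeny, tip_states: dict, states: tuple, q: float):
    """Pruning: conditional likelihoods of each subtree given the node state.

    Returns (partials, log scaling) with per-node rescaling for stability.
    """
    mk = MkFit(states, q, 0.0)
    L = _tip_state_array(tree, tip_states, states)
    logscale = 0.0
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        acc = np.ones(len(states))
        for c in kids:
            P = mk.transition_matrix(tree.lengths[c])
            acc = acc * (P @ L[c])
        m = acc.max()
        if m <= 0:
            return L, -np.inf
        L[node] = acc / m
        logscale += np.log(m)
    return L, logscale


def mk_loglik(tree: Phylogeny, tip_states: dict, states: tuple, q: float,
              root_prior: np.ndarray | None = None) -> float:
    """Equal-rates Mk log-likelihood by the pruning algorithm."""
    if root_prior is None:
        root_prior = np.full(len(states), 1.0 / len(states))
    L, logscale = _mk_partials(tree, tip_states, states, q)
    lik = float(root_prior @ L[tree.root])
    if lik <= 0 or not np.isfinite(logscale):
        return -np.inf
    return np.log(lik) + logscale


def fit_mk_er(tree: Phylogeny, tip_states: dict, states: tuple | None = None,
              q_max: float = 100.0) -> MkFit:
    """Maximum-likelihood equal-rates Mk fit with a uniform root prior."""
    if states is None:
        states = tuple(sorted(set(tip_states.values())))
    prior = np.full(len(states), 1.0 / len(states))
    observed = set(tip_states[tree.labels[t]] for t in tree.tips)
    if len(observed) < 2:
        warnings.warn("all tips share one state; q is at the 0 boundary")
        return MkFit(states, 0.0, mk_loglik(tree, tip_states, states, 0.0, prior),
                     prior, boundary=True)

    def nll(logq):
        return -mk_loglik(tree, tip_states, states, np.exp(logq), prior)

    res = minimize_scalar(nll, bounds=(np.log(1e-8), np.log(q_max)), method="bounded",
                          options={"xatol": 1e-10})
    q = float(np.exp(res.x))
    boundary = q <= 1.5e-8 or q >= q_max / 1.5
    return MkFit(states, q, -float(res.fun), prior, boundary=boundary)


# --------------------------------------------------------- simmap sampling

class PathSamplingError(RuntimeError):
    """Endpoint-conditioned path sampling exhausted its rejection budget."""


def _sample_node_states(tree: Phylogeny, tip_states: dict, mk: MkFit,
                        rng: np.random.Generator) -> np.ndarray:
    """Backward-forward draw of all node states given tips (one posterior sample)."""
    states = mk.states
    L, _ = _mk_partials(tree, tip_states, states, mk.q)
    prior = mk.root_prior if mk.root_prior is not None else np.full(mk.k, 1 / mk.k)
    chosen = np.zeros(tree.n_nodes, dtype=int)
    w = prior * L[tree.root]
    chosen[tree.root] = rng.choice(mk.k, p=w / w.sum())
    for node in tree.postorder[::-1]:  # preorder
        for c in tree.children[node]:
            P = mk.transition_matrix(tree.lengths[c])
            w = P[chosen[node]] * L[c]
            chosen[c] = rng.choice(mk.k, p=w / w.sum())
    return chosen


def _forward_path(a: int, t: float, k: int, q: float, rng) -> list:
    """Unconditioned CTMC path from state a over time t: [(state, dur), ...]."""
    rate = (k - 1) * q
    path, state, elapsed = [], a, 0.0
    while True:
        if rate == 0:
            path.append((state, t - elapsed))
            return path
        wait = rng.exponential(1.0 / rate)
        if elapsed + wait >= t:
            path.append((state, t - elapsed))
            return path
        path.append((state, wait))
        elapsed += wait
        others = [s for s in range(k) if s != state]
        state = others[rng.integers(len(others))]


def _uniformized_path(a: int, b: int, t: float, mk: MkFit, rng) -> list:
    """Endpoint-conditioned path by uniformization (exact; no rejection)."""
    k, q = mk.k, mk.q
    mu = (k - 1) * q * 1.000000001 + 1e-300
    R = np.eye(k) + mk.rate_matrix() / mu
    Pab = mk.transition_matrix(t)[a, b]
    # sample the number of virtual jumps N | endpoints
    Rpow = [np.eye(k)]
    logpois = -mu * t
    weights, nmax = [], 0
    total, term = 0.0, np.exp(logpois)
    while total < 0.999999 * 1.0 and nmax < 10000:
        w = term * Rpow[nmax][a, b] / Pab
        weights.append(w)
        total += w
        nmax += 1
        Rpow.append(Rpow[-1] @ R)
        term *= mu * t / nmax
    weights = np.array(weights)
    weights = weights / weights.sum()
    N = int(rng.choice(len(weights), p=weights))
    if N == 0:
        return [(a, t)]
    times = np.sort(rng.uniform(0, t, size=N))
    # conditioned DTMC through the virtual jumps
    seq = [a]
    for j in range(1, N):
        w = R[seq[-1]] * Rpow[N - j][:, b]
        seq.append(int(rng.choice(k, p=w / w.sum())))
    seq.append(b)
    # collapse virtual (self) jumps into segments
    segs, cur, t0 = [], a, 0.0
    for jt, s in zip(times, seq[1:]):
        if s != cur:
            segs.append((cur, jt - t0))
            cur, t0 = s, jt
    segs.append((cur, t - t0))
    return segs


def _conditioned_path(a: int, b: int, t: float, mk: MkFit, rng,
                      max_rejects: int = 10000) -> list:
    """Endpoint-conditioned CTMC path: rejection first, uniformization fallback."""
    if mk.q == 0 or t == 0:
        if a != b:
            raise PathSamplingError("q=0 cannot connect different endpoint states")
        return [(a, t)]
    for _ in range(max_rejects):
        path = _forward_path(a, t, mk.k, mk.q, rng)
        if path[-1][0] == b:
            return path
    return _uniformized_path(a, b, t, mk, rng)


def sample_simmap(tree: Phylogeny, tip_states: dict, mk: MkFit, n_maps: int,
                  seed: int, max_rejects: int = 10000) -> list:
    """Draw stochastic character maps from the posterior of histories.

    Node states are sampled by backward-forward conditional sampling; each
    branch history is then an endpoint-conditioned CTMC path.  Tip segments
    always end in the observed tip state.
    """
    rng = np.random.default_rng(seed)
    states = mk.states
    maps = []
    for _ in range(n_maps):
        node_states = _sample_node_states(tree, tip_states, mk, rng)
        segments = [None] * tree.n_nodes
        segments[tree.root] = [(states[node_states[tree.root]], 0.0)]
        for i in range(tree.n_nodes):
            if tree.parent[i] < 0:
                continue
            a = node_states[tree.parent[i]]
            b = node_states[i]
            try:
                path = _conditioned_path(a, b, float(tree.lengths[i]), mk, rng,
                                         max_rejects)
            except PathSamplingError as exc:
                raise PathSamplingError(f"branch {i}: {exc}") from exc
            segments[i] = [(states[s], d) for s, d in path]
        rm = RegimeMap(tree, segments)
        maps.append(rm)
    return maps
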