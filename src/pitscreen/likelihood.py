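"""Phylogenetic likelihood core: Felsenstein pruning, ML fitting, and
fixed-topology branch-length estimation.

Likelihoods are computed over compressed site patterns with per-node scaling.
Site likelihoods may be mixtures over components (discrete-gamma rate
categories for protein models; site classes for the branch-site model); each
component assigns every branch an eigendecomposed reversible rate matrix, so
``P(t)`` along a branch is a cheap diagonal rescaling.

Branch lengths are optimized one edge at a time: with the post-order
("inside") partial below an edge and the pre-order ("outside") partial above
it, the likelihood as a function of that single branch length reduces to
``sum_k a_k exp(lambda_k t)`` per site pattern, which Brent's method
maximizes in microseconds.  A top-down pass keeps the outside partials fresh
as edges are updated, so each pass is exact coordinate ascent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .io_formats import Alignment, Phylogeny, TreeNode
from .models import (
    AA_INDEX,
    CODON_INDEX,
    CodonModelSpec,
    ProteinModelSpec,
    build_rate_matrix,
    eig_reversible,
    empirical_protein_frequencies,
    ReversibleEig,
)

__all__ = [
    "FitResult",
    "TreeLikelihood",
    "log_likelihood",
    "fit_model",
    "estimate_branch_lengths",
    "OMEGA_BOUNDS",
    "KAPPA_BOUNDS",
    "BRANCH_BOUNDS",
]

OMEGA_BOUNDS = (1e-6, 100.0)
KAPPA_BOUNDS = (0.05, 100.0)
BRANCH_BOUNDS = (0.0, 50.0)
ALPHA_BOUNDS = (0.05, 50.0)

_TINY = 1e-300


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    log_likelihood: float
    estimates: dict
    converged: bool
    n_evaluations: int
    tree: Phylogeny | None = None


@dataclass
class Component:
    """One mixture component: weight, rate multiplier, eigensystem per class."""

    weight: float
    rate: float
    systems: dict[str, ReversibleEig]

    def system_for(self, label: str) -> ReversibleEig:
        return self.systems[label]


def _encode_states(aln: Alignment, taxa: Sequence[str]) -> np.ndarray:
    """(n_taxa, n_sites) integer states; -1 = missing/ambiguous."""
    if aln.kind == "codon":
        rows = []
        for t in taxa:
            rows.append([CODON_INDEX.get(c, -1) for c in aln.codons(t)])
    else:
        rows = []
        for t in taxa:
            rows.append([AA_INDEX.get(c, -1) for c in aln.sequences[t]])
    return np.array(rows, dtype=np.int64)


class TreeLikelihood:
    """Pruning machine bound to one alignment + tree (+ branch class labels).

    The tree's branch lengths are held in a mutable vector ``self.t`` indexed
    by edge (= non-root node, postorder); model parameters enter through
    :meth:`set_components`.
    """

    def __init__(
        self,
        aln: Alignment,
        tree: Phylogeny,
        n_states: int,
        class_of_edge: Sequence[str],
        compress: bool = True,
    ):
        self.tree = tree
        nodes = list(tree.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root_index = self.n_nodes - 1
        self.parent = np.full(self.n_nodes, -1)
        self.children: list[list[int]] = [[] for _ in nodes]
        for i, n in enumerate(nodes):
            if n.parent is not None:
                p = self.index[id(n.parent)]
                self.parent[i] = p
                self.children[p].append(i)
        self.is_tip = np.array([n.is_tip for n in nodes])
        self.t = np.array([n.length for n in nodes], dtype=float)
        self.class_of_edge = list(class_of_edge)
        self.n_states = n_states

        tip_order = [n.name for n in nodes if n.is_tip]
        missing = [t for t in tip_order if t not in aln.sequences]
        if missing:
            raise ValueError(f"tips without sequence: {missing}")
        states = _encode_states(aln, tip_order)
        if compress:
            patterns, pattern_of_site, weights = np.unique(
                states, axis=1, return_inverse=True, return_counts=True
            )
        else:
            patterns, weights = states, np.ones(states.shape[1])
            pattern_of_site = np.arange(states.shape[1])
        #: index of the pattern holding each original site
        self.pattern_of_site = np.asarray(pattern_of_site).ravel()
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        self.tip_patterns: dict[int, np.ndarray] = {}
        row = 0
        for i, n in enumerate(nodes):
            if n.is_tip:
                self.tip_patterns[i] = patterns[row]
                row += 1

        self.components: list[Component] = []
        self.n_evaluations = 0

    # -- parameterization ---------------------------------------------------

    def set_components(self, components: list[Component]) -> None:
        self.components = components

    def sync_tree(self) -> None:
        """Write the current branch-length vector back onto the tree nodes."""
        for i, n in enumerate(self.nodes):
            if n.parent is not None:
                n.length = float(self.t[i])

    # -- core pruning -------------------------------------------------------

    def _edge_P(self, comp: Component, edge: int, t: float | None = None) -> np.ndarray:
        sys = comp.system_for(self.class_of_edge[edge])
        tt = self.t[edge] if t is None else t
        return (sys.U * np.exp(sys.lam * comp.rate * tt)) @ sys.Vt

    def _child_message(self, comp: Component, edge: int, partials, scales) -> tuple[np.ndarray, np.ndarray]:
        """M[pat, i] = P(data below child | parent state i), with log-scale."""
        P = self._edge_P(comp, edge)
        if self.is_tip[edge]:
            states = self.tip_patterns[edge]
            M = np.where(states[:, None] >= 0, P.T[np.clip(states, 0, None)], 1.0)
            return M, np.zeros(self.n_patterns)
        return partials[edge] @ P.T, scales[edge]

    def _inside(self) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
        """Post-order partials for internal nodes, per component combined later.

        Returns per-component lists accessed as partials[comp_idx][node].
        """
        all_partials = []
        all_scales = []
        for comp in self.components:
            partials: dict[int, np.ndarray] = {}
            scales: dict[int, np.ndarray] = {}
            for i in range(self.n_nodes):
                if self.is_tip[i]:
                    continue
                L = np.ones((self.n_patterns, self.n_states))
                s = np.zeros(self.n_patterns)
                for c in self.children[i]:
                    M, sc = self._child_message(comp, c, partials, scales)
                    L = L * M
                    s = s + sc
                m = L.max(axis=1)
                safe = np.where(m > 0, m, 1.0)
                L /= safe[:, None]
                s = s + np.log(safe)
                partials[i] = L
                scales[i] = s
            all_partials.append(partials)
            all_scales.append(scales)
        return all_partials, all_scales

    def log_likelihood(self) -> float:
        """Total lnL = sum over patterns of weight * log mixture site likelihood."""
        self.n_evaluations += 1
        all_partials, all_scales = self._inside()
        return self._root_lnl(all_partials, all_scales)

    def _root_lnl(self, all_partials, all_scales) -> float:
        r = self.root_index
        logs = []
        for comp, partials, scales in zip(self.components, all_partials, all_scales):
            pi = comp.systems[next(iter(comp.systems))].pi
            site = partials[r] @ pi
            logs.append(np.log(np.maximum(site, _TINY)) + scales[r] + np.log(comp.weight))
        logs = np.array(logs)
        mx = logs.max(axis=0)
        site_log = mx + np.log(np.exp(logs - mx[None, :]).sum(axis=0))
        return float(self.weights @ site_log)

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-pattern mixture log-likelihoods (pattern order; see weights)."""
        all_partials, all_scales = self._inside()
        r = self.root_index
        logs = []
        for comp, partials, scales in zip(self.components, all_partials, all_scales):
            pi = comp.systems[next(iter(comp.systems))].pi
            site = partials[r] @ pi
            logs.append(np.log(np.maximum(site, _TINY)) + scales[r] + np.log(comp.weight))
        logs = np.array(logs)
        mx = logs.max(axis=0)
        return mx + np.log(np.exp(logs - mx[None, :]).sum(axis=0))

    def component_posteriors(self) -> np.ndarray:
        """(n_components, n_patterns) posterior probability of each component."""
        all_partials, all_scales = self._inside()
        r = self.root_index
        logs = []
        for comp, partials, scales in zip(self.components, all_partials, all_scales):
            pi = comp.systems[next(iter(comp.systems))].pi
            site = partials[r] @ pi
            logs.append(np.log(np.maximum(site, _TINY)) + scales[r] + np.log(comp.weight))
        logs = np.array(logs)
        mx = logs.max(axis=0)
        w = np.exp(logs - mx[None, :])
        return w / w.sum(axis=0, keepdims=True)

    # -- branch-length optimization -----------------------------------------

    def optimize_branches(self, n_passes: int = 2, tol: float = 1e-9) -> float:
        """Coordinate-ascent passes over all branch lengths; returns final lnL.

        Each pass recomputes inside partials once, then walks the tree
        top-down maintaining fresh outside partials, optimizing each branch
        by Brent on the one-dimensional profile likelihood.
        """
        lnl = -np.inf
        for _ in range(n_passes):
            all_partials, all_scales = self._inside()
            self.n_evaluations += 1
            # outside partials per component, keyed by node (edge above node)
            out: list[dict[int, tuple[np.ndarray, np.ndarray]]] = [
                {} for _ in self.components
            ]
            order = [i for i in self._preorder_indices() if i != self.root_index]
            for v in order:
                u = self.parent[v]
                for ci, comp in enumerate(self.components):
                    partials, scales = all_partials[ci], all_scales[ci]
                    if u == self.root_index:
                        pi = comp.systems[next(iter(comp.systems))].pi
                        O = np.tile(pi, (self.n_patterns, 1))
                        sO = np.zeros(self.n_patterns)
                    else:
                        Ou, sOu = out[ci][u]
                        P_u = self._edge_P(comp, u)
                        O = Ou @ P_u
                        sO = sOu
                    for sib in self.children[u]:
                        if sib == v:
                            continue
                        M, sc = self._child_message(comp, sib, partials, scales)
                        O = O * M
                        sO = sO + sc
                    m = O.max(axis=1)
                    safe = np.where(m > 0, m, 1.0)
                    O = O / safe[:, None]
                    sO = sO + np.log(safe)
                    out[ci][v] = (O, sO)
                self._optimize_edge(v, all_partials, all_scales, out)
            new_lnl = self.log_likelihood()
            if np.isfinite(lnl) and abs(new_lnl - lnl) < tol * max(1.0, abs(new_lnl)):
                lnl = new_lnl
                break
            lnl = new_lnl
        return lnl

    def _preorder_indices(self) -> list[int]:
        order = []
        stack = [self.root_index]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def _optimize_edge(self, v: int, all_partials, all_scales, out) -> None:
        """Maximize lnL over the length of the edge above node v."""
        B_list, lam_list, off_list = [], [], []
        for ci, comp in enumerate(self.components):
            sys = comp.system_for(self.class_of_edge[v])
            O, sO = out[ci][v]
            if self.is_tip[v]:
                states = self.tip_patterns[v]
                # F one-hot or all-ones for missing: (F @ Vt.T)[pat,k] = Vt[k,s]
                FV = np.where(
                    states[:, None] >= 0,
                    sys.Vt.T[np.clip(states, 0, None)],
                    sys.Vt.sum(axis=1)[None, :],
                )
                sF = np.zeros(self.n_patterns)
            else:
                F = all_partials[ci][v]
                sF = all_scales[ci][v]
                FV = F @ sys.Vt.T
            OU = O @ sys.U
            B_list.append(OU * FV * comp.weight)
            lam_list.append(sys.lam * comp.rate)
            off_list.append(sO + sF)
        offsets = np.array(off_list)
        mx = offsets.max(axis=0)
        B = np.concatenate(
            [b * np.exp(o - mx)[:, None] for b, o in zip(B_list, offsets)], axis=1
        )
        lam = np.concatenate(lam_list)
        w = self.weights

        def neg(t: float) -> float:
            site = B @ np.exp(lam * t)
            return -float(w @ np.log(np.maximum(site, _TINY)))

        t0 = self.t[v]
        res = minimize_scalar(neg, bounds=BRANCH_BOUNDS, method="bounded",
                              options={"xatol": 1e-8})
        if res.fun <= neg(t0):
            self.t[v] = float(res.x)


# ---------------------------------------------------------------------------
# Component builders
# ---------------------------------------------------------------------------


_EIG_CACHE: dict = {}


def _cached_codon_eig(kappa: float, omega: float, pi: np.ndarray) -> ReversibleEig:
    # kappa/omega repeat heavily during finite-difference steps of the
    # optimizer; caching the eigensystems avoids redundant 61x61 eigh calls
    key = (pi.tobytes(), round(kappa, 12), round(omega, 12))
    sys = _EIG_CACHE.get(key)
    if sys is None:
        spec = CodonModelSpec(kappa=kappa, omega_by_class={"BG": omega}, frequencies=pi)
        Q = build_rate_matrix(spec, "BG")
        sys = eig_reversible(Q, pi)
        if len(_EIG_CACHE) > 512:
            _EIG_CACHE.clear()
        _EIG_CACHE[key] = sys
    return sys


def _codon_components(spec: CodonModelSpec, labels: Iterable[str]) -> list[Component]:
    if spec.frequencies is None:
        raise ValueError("codon spec needs frequencies (use with_frequencies_from)")
    systems = {}
    for label in set(labels):
        cls = spec.resolve_class(label)
        if cls not in systems:
            systems[cls] = _cached_codon_eig(
                spec.kappa, spec.omega_by_class[cls], spec.frequencies
            )
        systems[label] = systems[cls]
    return [Component(weight=1.0, rate=1.0, systems=systems)]


def _protein_components(spec: ProteinModelSpec, labels: Iterable[str]) -> list[Component]:
    Q = build_rate_matrix(spec)
    sys = eig_reversible(Q, spec.frequencies)
    systems = {label: sys for label in set(labels)}
    rates, weights = spec.rates_and_weights()
    return [
        Component(weight=float(wk), rate=float(rk), systems=systems)
        for rk, wk in zip(rates, weights)
    ]


def _edge_labels(tree: Phylogeny, branch_class_map) -> list[str]:
    """Resolve one label per postorder node (root's entry unused)."""
    labels = []
    if branch_class_map is not None:
        # keyed by frozenset of descendant tip names
        branch_class_map = {frozenset(k): v for k, v in branch_class_map.items()}
    for node in tree.postorder():
        if branch_class_map is not None:
            tipset = frozenset(_tips_below(node))
            label = branch_class_map.get(tipset)
        else:
            label = node.label
        labels.append(label if label is not None else "BG")
    return labels


def _tips_below(node: TreeNode) -> list[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.append(n.name)
        stack.extend(n.children)
    return out


def make_tree_likelihood(
    aln: Alignment,
    tree: Phylogeny,
    spec,
    branch_class_map: Mapping | None = None,
) -> TreeLikelihood:
    if isinstance(spec, CodonModelSpec):
        if aln.kind != "codon":
            raise ValueError("codon model requires a codon alignment")
        spec = spec.with_frequencies_from(aln)
        n_states = 61
    elif isinstance(spec, ProteinModelSpec):
        if aln.kind != "protein":
            raise ValueError("protein model requires a protein alignment")
        n_states = 20
    else:
        raise TypeError(type(spec).__name__)
    labels = _edge_labels(tree, branch_class_map)
    tl = TreeLikelihood(aln, tree, n_states, labels)
    if isinstance(spec, CodonModelSpec):
        tl.set_components(_codon_components(spec, labels))
    else:
        tl.set_components(_protein_components(spec, labels))
    tl._spec = spec
    return tl


def log_likelihood(
    aln: Alignment,
    tree: Phylogeny,
    spec,
    branch_class_map: Mapping | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of the alignment on the tree.

    Missing states contribute partial likelihood 1 in every state.  Site
    patterns are compressed; the result is identical to the uncompressed sum.
    ``branch_class_map`` optionally maps frozensets of descendant tip names to
    branch-class labels (otherwise labels stored on the tree nodes are used;
    unlabeled branches are background).
    """
    return make_tree_likelihood(aln, tree, spec, branch_class_map).log_likelihood()


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def _free_scalars(spec, free: set[str]) -> list[tuple[str, float, tuple[float, float]]]:
    """(name, current value, bounds) for each free scalar parameter."""
    out = []
    if isinstance(spec, CodonModelSpec):
        if "kappa" in free:
            out.append(("kappa", spec.kappa, KAPPA_BOUNDS))
        for label in sorted(spec.omega_by_class):
            if "omega" in free or f"omega:{label}" in free:
                out.append((f"omega:{label}", spec.omega_by_class[label], OMEGA_BOUNDS))
    else:
        if "alpha" in free and spec.gamma_shape is not None:
            out.append(("alpha", spec.gamma_shape, ALPHA_BOUNDS))
    return out


def _apply_scalars(spec, names: Sequence[str], values: Sequence[float]):
    if isinstance(spec, CodonModelSpec):
        kappa = spec.kappa
        omegas = dict(spec.omega_by_class)
        for n, v in zip(names, values):
            if n == "kappa":
                kappa = v
            elif n.startswith("omega:"):
                omegas[n.split(":", 1)[1]] = v
        return CodonModelSpec(
            kappa=kappa,
            omega_by_class=omegas,
            frequencies=spec.frequencies,
            frequency_mode=spec.frequency_mode,
            background_class=spec.background_class,
        )
    alpha = spec.gamma_shape
    for n, v in zip(names, values):
        if n == "alpha":
            alpha = v
    return ProteinModelSpec(
        exchangeabilities=spec.exchangeabilities,
        frequencies=spec.frequencies,
        gamma_shape=alpha,
        n_rate_categories=spec.n_rate_categories,
    )


def _rebuild_components(tl: TreeLikelihood, spec) -> None:
    if isinstance(spec, CodonModelSpec):
        tl.set_components(_codon_components(spec, tl.class_of_edge))
    else:
        tl.set_components(_protein_components(spec, tl.class_of_edge))
    tl._spec = spec


def fit_model(
    aln: Alignment,
    tree: Phylogeny,
    spec,
    free: Iterable[str] = ("kappa", "omega", "branch_lengths"),
    branch_class_map: Mapping | None = None,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_rounds: int = 60,
) -> FitResult:
    """Maximize the log-likelihood over the requested free parameters.

    Free parameters: ``"kappa"``, ``"omega"`` (all classes) or
    ``"omega:<label>"``, ``"branch_lengths"``, ``"alpha"`` (protein gamma
    shape).  Scalars are optimized by bounded quasi-Newton on log-transformed
    values, alternating with exact coordinate-ascent passes over branch
    lengths; the alternation stops when the relative lnL change drops below
    *tol*.  ``n_starts`` runs (the given start plus jittered restarts seeded
    from *seed*) guard against local optima; the best fit is returned, with a
    copy of the tree carrying the fitted branch lengths.
    """
    free = set(free)
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    base_tree = tree

    for start in range(max(1, n_starts)):
        work_tree = base_tree.copy()
        cur_spec = spec
        if start > 0 and isinstance(spec, CodonModelSpec):
            jitter = lambda v, lo, hi: float(np.clip(v * rng.uniform(0.33, 3.0), lo, hi))
            omegas = {
                k: (jitter(v, *OMEGA_BOUNDS) if ("omega" in free or f"omega:{k}" in free) else v)
                for k, v in spec.omega_by_class.items()
            }
            kap = jitter(spec.kappa, *KAPPA_BOUNDS) if "kappa" in free else spec.kappa
            cur_spec = CodonModelSpec(
                kappa=kap, omega_by_class=omegas, frequencies=spec.frequencies,
                frequency_mode=spec.frequency_mode, background_class=spec.background_class,
            )
        elif start > 0:
            cur_spec = spec  # protein: restarts differ only via branch jitter
            for node in work_tree.preorder():
                if node.parent is not None:
                    node.length = float(np.clip(node.length * rng.uniform(0.5, 2.0), *BRANCH_BOUNDS))

        res = _fit_single(aln, work_tree, cur_spec, free, branch_class_map, tol, max_rounds)
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    return best


def _fit_single(aln, tree, spec, free, branch_class_map, tol, max_rounds) -> FitResult:
    if isinstance(spec, CodonModelSpec):
        spec = spec.with_frequencies_from(aln)
    tl = make_tree_likelihood(aln, tree, spec, branch_class_map)
    scalars = _free_scalars(spec, free)
    do_branches = "branch_lengths" in free

    lnl = tl.log_likelihood()
    converged = False
    for _ in range(max_rounds):
        prev = lnl
        if scalars:
            names = [s[0] for s in scalars]
            x0 = np.log([s[1] for s in scalars])
            bounds = [(np.log(lo), np.log(hi)) for _, _, (lo, hi) in scalars]

            def neg(logx):
                s = _apply_scalars(tl._spec, names, np.exp(logx))
                _rebuild_components(tl, s)
                return -tl.log_likelihood()

            opt = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 15, "ftol": 1e-12})
            new_spec = _apply_scalars(tl._spec, names, np.exp(opt.x))
            _rebuild_components(tl, new_spec)
            scalars = _free_scalars(new_spec, free)
        if do_branches:
            lnl = tl.optimize_branches(n_passes=2)
        else:
            lnl = tl.log_likelihood()
        if abs(lnl - prev) < tol * max(1.0, abs(lnl)):
            converged = True
            break

    tl.sync_tree()
    fitted = tl.tree
    estimates: dict = {}
    spec_final = tl._spec
    if isinstance(spec_final, CodonModelSpec):
        estimates["kappa"] = spec_final.kappa
        estimates["omega_by_class"] = dict(spec_final.omega_by_class)
    else:
        estimates["gamma_shape"] = spec_final.gamma_shape
    estimates["branch_lengths"] = {
        frozenset(_tips_below(n)): n.length for n in fitted.postorder() if n.parent is not None
    }
    return FitResult(
        log_likelihood=lnl,
        estimates=estimates,
        converged=converged,
        n_evaluations=tl.n_evaluations,
        tree=fitted,
    )


def estimate_branch_lengths(
    aln: Alignment,
    tree_topology: Phylogeny,
    spec: ProteinModelSpec | None = None,
    plus_f: bool = True,
    initial_length: float = 0.1,
    tol: float = 1e-7,
    max_rounds: int = 40,
) -> Phylogeny:
    """Estimate branch lengths on a fixed topology under a protein model.

    This is the constrained-tree step of the screen: the genome topology is
    enforced and only branch lengths are free.  With ``plus_f`` the model's
    equilibrium frequencies are replaced by the empirical alignment
    frequencies ("+F").  Branches of the input topology with zero/absent
    lengths start from *initial_length*.
    """
    if spec is None:
        spec = ProteinModelSpec(gamma_shape=1.0)
    if plus_f:
        spec = ProteinModelSpec(
            exchangeabilities=spec.exchangeabilities,
            frequencies=empirical_protein_frequencies(aln),
            gamma_shape=spec.gamma_shape,
            n_rate_categories=spec.n_rate_categories,
        )
    work = tree_topology.copy()
    for node in work.preorder():
        if node.parent is not None and node.length <= 0:
            node.length = initial_length
    tl = make_tree_likelihood(aln, work, spec)
    prev = -np.inf
    for _ in range(max_rounds):
        lnl = tl.optimize_branches(n_passes=1)
        if np.isfinite(prev) and abs(lnl - prev) < tol * max(1.0, abs(lnl)):
            break
        prev = lnl
    tl.sync_tree()
    return tl.tree
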