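"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/adjustment code paths: the
likelihood oracle enumerates every assignment of internal-node states
directly from the model definition (transition matrices via scipy's expm),
and the FDR oracle is the literal step-up definition.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from pitscreen.io_formats import Alignment, Phylogeny
from pitscreen.models import (
    AA_INDEX,
    CODON_INDEX,
    CodonModelSpec,
    ProteinModelSpec,
    build_rate_matrix,
)


def brute_force_log_likelihood(aln: Alignment, tree: Phylogeny, spec) -> float:
    """lnL by summation over all internal-node state assignments.

    For every site, builds the joint probability tensor over internal states
    by broadcasting edge transition probabilities, then sums it — a direct
    transcription of the marginal-likelihood definition.  Feasible for <=5
    tips and a handful of sites.
    """
    if isinstance(spec, CodonModelSpec):
        spec = spec.with_frequencies_from(aln)
        n_states = 61
        pi = spec.frequencies

        def encode(taxon):
            return [CODON_INDEX.get(c, -1) for c in aln.codons(taxon)]

        def edge_P(node):
            label = node.label
            cls = spec.resolve_class(label)
            Q = build_rate_matrix(spec, cls)
            return expm(Q * node.length)

    else:
        n_states = 20
        pi = spec.frequencies
        if spec.gamma_shape is not None and spec.n_rate_categories > 1:
            raise NotImplementedError("oracle covers single-rate protein models")

        def encode(taxon):
            return [AA_INDEX.get(c, -1) for c in aln.sequences[taxon]]

        Q = build_rate_matrix(spec)

        def edge_P(node):
            return expm(Q * node.length)

    internals = [n for n in tree.postorder() if not n.is_tip]
    idx = {id(n): k for k, n in enumerate(internals)}
    n_int = len(internals)
    tips = {n.name: n for n in tree.tips()}
    states = {t: encode(t) for t in tips}
    n_sites = len(next(iter(states.values())))
    P_of = {id(n): edge_P(n) for n in tree.postorder() if n.parent is not None}

    def axis_shape(k):
        shape = [1] * n_int
        shape[k] = n_states
        return shape

    total = 0.0
    for site in range(n_sites):
        tensor = np.ones((n_states,) * n_int)
        root_axis = idx[id(tree.root)]
        tensor = tensor * pi.reshape(axis_shape(root_axis))
        for node in tree.postorder():
            if node.parent is None:
                continue
            p_axis = idx[id(node.parent)]
            P = P_of[id(node)]
            if node.is_tip:
                s = states[node.name][site]
                if s < 0:
                    continue  # missing: sum_x P[i, x] = 1
                tensor = tensor * P[:, s].reshape(axis_shape(p_axis))
            else:
                c_axis = idx[id(node)]
                shape = [1] * n_int
                shape[p_axis] = n_states
                shape[c_axis] = n_states
                # reshape assigns P's first dimension to the lower axis
                # index; P rows must land on the parent axis
                M = P if p_axis < c_axis else P.T
                tensor = tensor * M.reshape(shape)
        total += np.log(tensor.sum())
    return float(total)


def stepup_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = p[i] * n / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def ols_by_hand(points):
    """Closed-form simple linear regression (slope, intercept)."""
    x = np.array([p[0] for p in points], float)
    y = np.array([p[1] for p in points], float)
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return slope, ybar - slope * xbar
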