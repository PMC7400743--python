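"""Per-gene branch-model selection screen.

For each orthologous gene group (OGG): drop species with excessive missing
data, require enough foreground (pit viper) and background species, prune the
genome tree to the surviving taxa with the foreground stem labeled, fit the
one-ratio (single omega) and two-ratio (separate foreground-stem omega) codon
models, and compare them by a chi-square likelihood-ratio test with one
degree of freedom.  P-values are Benjamini-Hochberg adjusted across genes;
candidates are genes with q below alpha, elevated foreground omega
(omega1 > omega0), and a foreground branch long enough to carry information
(the low-dN/dS exclusion).

An optional branch-site scan (model A style) localizes putatively selected
sites on the foreground branch with naive empirical Bayes posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io_formats import Alignment, CladeConfig, Phylogeny
from .likelihood import (
    Component,
    FitResult,
    TreeLikelihood,
    fit_model,
    make_tree_likelihood,
)
from .models import CodonModelSpec

__all__ = [
    "SelectionTestResult",
    "filter_ogg",
    "prune_user_tree",
    "branch_model_test",
    "fdr_adjust",
    "call_candidates",
    "branch_site_scan",
    "BranchSiteResult",
]


@dataclass
class SelectionTestResult:
    gene: str
    lnl0: float
    lnl1: float
    omega0: float
    omega1: float
    kappa: float
    lrt: float
    p_value: float
    foreground_t: float
    converged: bool = True
    q_value: float | None = None
    low_rate_excluded: bool = False
    candidate: bool = False


def filter_ogg(
    aln: Alignment,
    config: CladeConfig,
    max_missing: float = 0.20,
    min_fg: int = 4,
    min_bg: int = 4,
) -> Alignment | None:
    """Drop high-missingness species; reject alignments with too few taxa.

    Species with a missing-data fraction above *max_missing* are removed.
    The alignment is rejected (returns None) unless at least *min_fg*
    foreground and *min_bg* non-foreground species survive ("more than
    three" of each by default).
    """
    if aln.kind != "codon":
        raise ValueError("selection filtering expects a codon alignment")
    keep = [t for t in aln.taxa if aln.missing_fraction(t) <= max_missing]
    fg = [t for t in keep if t in config.foreground]
    bg = [t for t in keep if t not in config.foreground]
    if len(fg) < min_fg or len(bg) < min_bg:
        return None
    return aln.subset(keep)


def prune_user_tree(
    genome_tree: Phylogeny,
    keep: Iterable[str],
    foreground_clade: Iterable[str],
) -> Phylogeny:
    """Prune the genome tree to *keep* and label the foreground stem 'FG'."""
    keep = set(keep)
    fg_kept = set(foreground_clade) & keep
    if len(fg_kept) < 2:
        raise ValueError(
            f"only {len(fg_kept)} foreground taxa kept; no stem branch definable"
        )
    pruned = genome_tree.prune_to(keep)
    for node in pruned.preorder():
        node.label = None
    stem = pruned.mrca(fg_kept)
    if stem.parent is None:
        raise ValueError("foreground clade spans the whole pruned tree; no stem")
    stem.label = "FG"
    return pruned


def branch_model_test(
    aln: Alignment,
    labeled_tree: Phylogeny,
    init_kappa: float = 2.0,
    init_omega: float = 0.4,
    seed: int = 0,
    n_starts: int = 1,
) -> SelectionTestResult:
    """One-ratio vs two-ratio branch-model LRT for one gene.

    Both models free kappa, omega(s) and all branch lengths.  The two-ratio
    fit starts from the one-ratio optimum (plus a perturbed-omega1 restart),
    which makes the nested-model dominance lnL1 >= lnL0 hold by
    construction.  The LRT statistic is clamped at 0 and referred to
    chi-square with one degree of freedom.
    """
    spec0 = CodonModelSpec(
        kappa=init_kappa, omega_by_class={"BG": init_omega}
    ).with_frequencies_from(aln)
    fit0 = fit_model(
        aln, labeled_tree, spec0,
        free={"kappa", "omega", "branch_lengths"},
        n_starts=n_starts, seed=seed,
    )
    k0 = fit0.estimates["kappa"]
    w0 = fit0.estimates["omega_by_class"]["BG"]

    best1: FitResult | None = None
    for w1_init in (w0, min(2.0 * w0 + 0.5, 50.0)):
        spec1 = CodonModelSpec(
            kappa=k0,
            omega_by_class={"BG": w0, "FG": w1_init},
            frequencies=spec0.frequencies,
        )
        fit1 = fit_model(
            aln, fit0.tree, spec1,
            free={"kappa", "omega", "branch_lengths"},
            n_starts=1, seed=seed,
        )
        if best1 is None or fit1.log_likelihood > best1.log_likelihood:
            best1 = fit1

    lrt = 2.0 * (best1.log_likelihood - fit0.log_likelihood)
    if lrt < -1e-6:
        # optimizer failure in the alternative model; treat as no improvement
        lrt = 0.0
    lrt = max(lrt, 0.0)
    fg_t = _foreground_branch_length(best1.tree)
    return SelectionTestResult(
        gene=aln.name,
        lnl0=fit0.log_likelihood,
        lnl1=best1.log_likelihood,
        omega0=best1.estimates["omega_by_class"]["BG"],
        omega1=best1.estimates["omega_by_class"]["FG"],
        kappa=best1.estimates["kappa"],
        lrt=lrt,
        p_value=float(chi2.sf(lrt, df=1)),
        foreground_t=fg_t,
        converged=fit0.converged and best1.converged,
    )


def _foreground_branch_length(tree: Phylogeny) -> float:
    for node in tree.preorder():
        if node.label == "FG":
            return node.length
    return math.nan


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_candidates(
    results: Sequence[SelectionTestResult],
    alpha: float = 0.05,
    min_fg_t: float = 1e-4,
) -> set[str]:
    """Attach q-values and candidacy flags; return the candidate gene set.

    Genes with a fitted foreground branch shorter than *min_fg_t* carry no
    information about omega1 and are excluded before the BH adjustment
    (``low_rate_excluded``).  Candidates satisfy q < alpha and
    omega1 > omega0.
    """
    for r in results:
        r.low_rate_excluded = not (r.foreground_t >= min_fg_t)
        r.candidate = False
        r.q_value = None
    tested = [r for r in results if not r.low_rate_excluded]
    if not tested:
        return set()
    q = fdr_adjust([r.p_value for r in tested])
    for r, qv in zip(tested, q):
        r.q_value = float(qv)
        r.candidate = (qv < alpha) and (r.omega1 > r.omega0)
    return {r.gene for r in results if r.candidate}


# ---------------------------------------------------------------------------
# Branch-site scan (model A style, naive empirical Bayes posteriors)
# ---------------------------------------------------------------------------


@dataclass
class BranchSiteResult:
    gene: str
    lnl_null: float
    lnl_alt: float
    lrt: float
    p_value: float
    omega0: float
    omega2: float
    proportions: tuple[float, float, float, float]
    #: per-site posterior probability of the positively-selected classes (2a+2b)
    site_posteriors: np.ndarray


def _branch_site_components(
    spec_freqs, kappa, w0, w2, p_raw, labels
) -> list[Component]:
    from .likelihood import _cached_codon_eig

    a, b = p_raw
    z = np.array([a, b, 0.0])
    z = np.exp(z - z.max())
    p0, p1, p2 = z / z.sum()
    # class 2 splits between 2a (background omega0) and 2b (background 1)
    # proportionally to p0 : p1, the standard model-A construction
    denom = p0 + p1 if p0 + p1 > 0 else 1.0
    props = (p0, p1, p2 * p0 / denom, p2 * p1 / denom)
    eig_w0 = _cached_codon_eig(kappa, w0, spec_freqs)
    eig_1 = _cached_codon_eig(kappa, 1.0, spec_freqs)
    eig_w2 = _cached_codon_eig(kappa, w2, spec_freqs)
    comp_systems = [
        {"BG": eig_w0, "FG": eig_w0},
        {"BG": eig_1, "FG": eig_1},
        {"BG": eig_w0, "FG": eig_w2},
        {"BG": eig_1, "FG": eig_w2},
    ]
    comps = [
        Component(weight=max(w, 1e-12), rate=1.0, systems=s)
        for w, s in zip(props, comp_systems)
    ]
    return comps


def _fit_branch_site(
    aln: Alignment,
    tree: Phylogeny,
    fix_omega2: bool,
    init: dict,
    max_rounds: int = 30,
    tol: float = 1e-7,
):
    spec = CodonModelSpec(
        kappa=init["kappa"], omega_by_class={"BG": init.get("w0", 0.2)}
    ).with_frequencies_from(aln)
    freqs = spec.frequencies
    tl = make_tree_likelihood(aln, tree, spec)

    # free scalars: kappa, w0 in (0,1], [w2 in [1,50]], mixture logits a,b
    x = [np.log(init["kappa"]), np.log(init.get("w0", 0.2)), init.get("a", 1.0),
         init.get("b", 0.0)]
    if not fix_omega2:
        x.append(np.log(init.get("w2", 2.0)))
    bounds = [(np.log(0.05), np.log(100)), (np.log(1e-6), 0.0),
              (-12, 12), (-12, 12)]
    if not fix_omega2:
        bounds.append((0.0, np.log(50.0)))

    def set_params(vec):
        kappa = float(np.exp(vec[0]))
        w0 = float(np.exp(vec[1]))
        a, b = float(vec[2]), float(vec[3])
        w2 = 1.0 if fix_omega2 else float(np.exp(vec[4]))
        tl.set_components(_branch_site_components(freqs, kappa, w0, w2, (a, b), None))
        return kappa, w0, w2, (a, b)

    def neg(vec):
        set_params(vec)
        return -tl.log_likelihood()

    lnl = -neg(np.array(x))
    vec = np.array(x)
    for _ in range(max_rounds):
        prev = lnl
        opt = minimize(neg, vec, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 25, "ftol": 1e-12})
        vec = opt.x
        set_params(vec)
        lnl = tl.optimize_branches(n_passes=2)
        if abs(lnl - prev) < tol * max(1.0, abs(lnl)):
            break
    kappa, w0, w2, (a, b) = set_params(vec)
    z = np.array([a, b, 0.0])
    z = np.exp(z - z.max())
    p0, p1, p2 = z / z.sum()
    denom = p0 + p1 if p0 + p1 > 0 else 1.0
    props = (p0, p1, p2 * p0 / denom, p2 * p1 / denom)
    return tl, lnl, {"kappa": kappa, "w0": w0, "w2": w2, "props": props,
                     "a": a, "b": b}


def branch_site_scan(
    aln: Alignment,
    labeled_tree: Phylogeny,
    seed: int = 0,
) -> BranchSiteResult:
    """Branch-site test of positive selection on the foreground branch.

    Model-A site classes (purifying omega0 <= 1, neutral omega = 1, and
    foreground-positive omega2 >= 1 on classes 2a/2b) are fitted; the null
    fixes omega2 = 1 and the LRT uses one degree of freedom.  Per-site
    positive-class posteriors are naive empirical Bayes: mixture weights and
    parameters are plugged in at their ML estimates.
    """
    tl_null, lnl_null, est_null = _fit_branch_site(
        aln, labeled_tree, fix_omega2=True,
        init={"kappa": 2.0, "w0": 0.2},
    )
    tl_alt, lnl_alt, est_alt = _fit_branch_site(
        aln, labeled_tree, fix_omega2=False,
        init={"kappa": est_null["kappa"], "w0": est_null["w0"],
              "a": est_null["a"], "b": est_null["b"], "w2": 2.0},
    )
    if lnl_alt < lnl_null:
        lnl_alt = lnl_null  # alternative nests the null; keep dominance
    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    post = tl_alt.component_posteriors()  # (4, n_patterns)
    positive = post[2] + post[3]
    site_post = positive[tl_alt.pattern_of_site]
    return BranchSiteResult(
        gene=aln.name,
        lnl_null=lnl_null,
        lnl_alt=lnl_alt,
        lrt=lrt,
        p_value=float(chi2.sf(lrt, df=1)),
        omega0=est_alt["w0"],
        omega2=est_alt["w2"],
        proportions=est_alt["props"],
        site_posteriors=site_post,
    )
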