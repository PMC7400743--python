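"""Clade-resolved branch-length statistics of a gene tree.

For each gene tree the screen needs, relative to configurable ancestral
nodes: the average root-to-tip branch length of the foreground clade versus
the outgroup (step 1), versus the non-pit viper subfamilies (step 2), and the
foreground stem length versus the longest non-pit viper root-to-tip length
(step 3).  A quantity is left undefined (None) when the tree lacks the taxa
needed to measure it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import CladeConfig, Phylogeny, TreeNode

__all__ = [
    "CladeMetrics",
    "mrca",
    "avg_root_to_tip",
    "max_root_to_tip",
    "stem_branch_length",
    "compute_clade_metrics",
]


@dataclass
class CladeMetrics:
    """Per-gene branch-length metrics; ``None`` marks an undefined quantity."""

    gene: str
    avg_fg_vs_outgroup: float | None  # step-1 y
    avg_outgroup: float | None        # step-1 x
    avg_fg_vs_vipers: float | None    # step-2 y
    avg_nonpit_vipers: float | None   # step-2 x
    stem_fg: float | None             # step-3 y
    max_nonpit_root_to_tip: float | None  # step-3 x
    fg_monophyletic: bool


def mrca(tree: Phylogeny, taxa: Iterable[str]) -> TreeNode:
    """Deepest node whose tip descendants include all of *taxa*."""
    return tree.mrca(taxa)


def avg_root_to_tip(tree: Phylogeny, start: TreeNode, taxa: Iterable[str]) -> float:
    """Mean branch-length sum over the paths start -> tip for each named tip."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    return sum(tree.path_length(start, t) for t in taxa) / len(taxa)


def max_root_to_tip(tree: Phylogeny, start: TreeNode, taxa: Iterable[str]) -> float:
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    return max(tree.path_length(start, t) for t in taxa)


def stem_branch_length(tree: Phylogeny, clade_taxa: Iterable[str]) -> float | None:
    """Length of the branch subtending the clade's MRCA, or None.

    Returns None when the clade (restricted to tips present in the tree) is
    not monophyletic, or when its MRCA is the root (no parent branch).
    """
    clade_taxa = set(clade_taxa)
    if not clade_taxa:
        raise ValueError("empty clade")
    present = clade_taxa & set(tree.tip_names())
    if not present:
        raise KeyError("no clade member present in tree")
    node = tree.mrca(present)
    if tree.tip_set(node) != present:
        return None  # non-monophyletic
    if node.parent is None:
        return None  # root has no stem
    return node.length


def compute_clade_metrics(
    tree: Phylogeny,
    config: CladeConfig,
    viper_origin: str = "viperidae_mrca",
) -> CladeMetrics:
    """Compute all screen metrics for one gene tree.

    Step 1 measures from the MRCA of foreground + outgroup; steps 2 and 3
    measure from the MRCA of all Viperidae present in the tree
    (``viper_origin="viperidae_mrca"``, the default) or from the MRCA of
    foreground + Azemiopinae (``"crotalinae_azemiopinae_mrca"``).
    Comparison sets with no representative in the tree leave the dependent
    fields None.
    """
    tips = set(tree.tip_names())
    fg = config.foreground & tips
    if not fg:
        raise ValueError(f"{tree.name}: no foreground taxon present")
    og = config.outgroup & tips
    nonpit = config.nonpit_vipers & tips

    avg_fg_out = avg_out = None
    if og:
        start1 = tree.mrca(fg | og)
        avg_fg_out = avg_root_to_tip(tree, start1, fg)
        avg_out = avg_root_to_tip(tree, start1, og)

    avg_fg_vip = avg_nonpit = max_nonpit = None
    if nonpit:
        if viper_origin == "viperidae_mrca":
            origin_taxa = fg | nonpit
        elif viper_origin == "crotalinae_azemiopinae_mrca":
            origin_taxa = fg | (config.azemiopinae & tips)
        else:
            raise ValueError(f"unknown viper_origin {viper_origin!r}")
        start2 = tree.mrca(origin_taxa)
        avg_fg_vip = avg_root_to_tip(tree, start2, fg)
        avg_nonpit = avg_root_to_tip(tree, start2, nonpit)
        max_nonpit = max_root_to_tip(tree, start2, nonpit)

    stem = stem_branch_length(tree, fg) if len(fg) >= 1 else None
    mono = stem is not None or (len(fg) >= 1 and tree.tip_set(tree.mrca(fg)) == fg
                                and tree.mrca(fg).parent is None)

    return CladeMetrics(
        gene=tree.name or "",
        avg_fg_vs_outgroup=avg_fg_out,
        avg_outgroup=avg_out,
        avg_fg_vs_vipers=avg_fg_vip,
        avg_nonpit_vipers=avg_nonpit,
        stem_fg=stem,
        max_nonpit_root_to_tip=max_nonpit,
        fg_monophyletic=mono,
    )
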