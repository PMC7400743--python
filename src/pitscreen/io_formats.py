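"""Core sequence/tree data model and readers/writers for FASTA, Newick and TSV.

The pipeline moves three kinds of objects around: in-frame codon (or protein)
alignments keyed by taxon, rooted phylogenies with branch lengths, and a clade
configuration naming the foreground lineage (pit vipers) and the comparison
taxon sets.  Everything downstream — the branch-length screen, the codon-model
likelihood engine and the substitution scan — consumes these types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "Alignment",
    "Phylogeny",
    "TreeNode",
    "CladeConfig",
    "FormatError",
    "MISSING_CHARS",
    "STOP_CODONS",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_newick",
    "parse_newick",
    "write_newick",
    "write_records_table",
    "translate_codon_alignment",
]

#: Characters that count as missing data in both nucleotide and protein space.
MISSING_CHARS = frozenset("-N?X")

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA


class FormatError(ValueError):
    """Raised when an input file violates a format invariant."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A taxon-keyed multiple sequence alignment.

    Parameters
    ----------
    name : str
        Gene/OGG identifier.
    kind : {"codon", "protein"}
        Codon alignments are counted in nucleotide columns and must have a
        length divisible by three.
    sequences : dict
        Mapping taxon name -> upper-case character string, all equal length.
    """

    name: str
    kind: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if self.kind not in ("codon", "protein"):
            raise ValueError(f"unknown alignment kind {self.kind!r}")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"{self.name}: sequences have unequal lengths {sorted(lengths)}"
            )
        if self.kind == "codon" and self.length % 3 != 0:
            raise FormatError(
                f"{self.name}: codon alignment length {self.length} not divisible by 3"
            )
        for taxon in self.sequences:
            if not taxon:
                raise FormatError(f"{self.name}: empty taxon name")

    @property
    def length(self) -> int:
        """Number of columns (nucleotides for codon alignments)."""
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    def missing_fraction(self, taxon: str) -> float:
        """Fraction of columns that are missing ('-', 'N', '?', 'X') for *taxon*."""
        seq = self.sequences[taxon]
        if not seq:
            return 0.0
        return sum(c in MISSING_CHARS for c in seq) / len(seq)

    def subset(self, taxa: Iterable[str]) -> "Alignment":
        """Restrict the alignment to *taxa* (order preserved from the alignment)."""
        keep = set(taxa)
        return Alignment(
            name=self.name,
            kind=self.kind,
            sequences={t: s for t, s in self.sequences.items() if t in keep},
        )

    def codons(self, taxon: str) -> list[str]:
        if self.kind != "codon":
            raise ValueError("codons() requires a codon alignment")
        seq = self.sequences[taxon]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _clean_codon_sequence(seq: str, name: str) -> str:
    """Upper-case a CDS and recode ambiguous/stop codons as fully missing.

    Any codon containing a symbol outside {A,C,G,T}, and any stop codon of the
    standard genetic code, becomes ``---``.  Consensus-called CDSs routinely
    contain N-runs and artifactual internal stops; treating them as missing
    keeps the taxon in the alignment without inventing states.
    """
    seq = seq.upper()
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(c not in "ACGT" for c in codon) or codon in STOP_CODONS:
            out.append("---")
        else:
            out.append(codon)
    return "".join(out)


def read_fasta_alignment(path, kind: str = "codon", name: str | None = None) -> Alignment:
    """Read a FASTA alignment of the given *kind* ("codon" or "protein").

    Characters are upper-cased.  For codon alignments, codons containing
    non-ACGT symbols or matching a stop codon are recoded as missing (``---``).

    Raises
    ------
    FormatError
        On unequal sequence lengths, duplicate taxon names, empty input, or a
        codon alignment whose length is not divisible by 3.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate taxon {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise FormatError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    if kind == "codon":
        length = lengths.pop()
        if length % 3 != 0:
            raise FormatError(f"{path}: codon alignment length {length} not divisible by 3")
        sequences = {t: _clean_codon_sequence(s, t) for t, s in sequences.items()}
    if name is None:
        name = getattr(path, "stem", None) or str(path)
    return Alignment(name=name, kind=kind, sequences=sequences)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.sequences.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def translate_codon_alignment(aln: Alignment) -> Alignment:
    """Translate a codon alignment column-wise into a protein alignment.

    Missing/ambiguous codons (already recoded to ``---`` on read) translate to
    the missing residue ``X``.
    """
    if aln.kind != "codon":
        raise ValueError("translation requires a codon alignment")
    out: dict[str, str] = {}
    for taxon in aln.sequences:
        residues = []
        for codon in aln.codons(taxon):
            if any(c not in "ACGT" for c in codon) or codon in STOP_CODONS:
                residues.append("X")
            else:
                residues.append(str(Seq(codon).translate()))
        out[taxon] = "".join(residues)
    return Alignment(name=aln.name, kind="protein", sequences=out)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class TreeNode:
    """A node in a rooted phylogeny; ``length`` is the branch above the node."""

    __slots__ = ("name", "length", "children", "parent", "label")

    def __init__(self, name=None, length=0.0, label=None):
        self.name: str | None = name
        self.length: float = length
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode | None" = None
        #: branch-class label of the branch above this node (e.g. "FG")
        self.label: str | None = label

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with named tips, non-negative branch lengths and
    optional branch-class labels (used to mark the foreground stem).
    """

    def __init__(self, root: TreeNode, name: str | None = None):
        self.root = root
        self.name = name
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        tips = self.tip_names()
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise FormatError(f"duplicate tip labels {dupes}")
        for node in self.preorder():
            if node.length < 0:
                raise FormatError(f"negative branch length {node.length} above {node.name}")

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def find_tip(self, name: str) -> TreeNode:
        for n in self.tips():
            if n.name == name:
                return n
        raise KeyError(f"taxon {name!r} not in tree")

    # -- queries ------------------------------------------------------------

    def mrca(self, taxa: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the named tips."""
        taxa = set(taxa)
        if not taxa:
            raise ValueError("mrca of an empty taxon set")
        missing = taxa - set(self.tip_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        # count, for each node, how many of the target tips sit below it
        counts: dict[int, int] = {}
        node_by_id: dict[int, TreeNode] = {}
        for node in self.postorder():
            node_by_id[id(node)] = node
            c = sum(counts.get(id(ch), 0) for ch in node.children)
            if node.is_tip and node.name in taxa:
                c += 1
            counts[id(node)] = c
            if c == len(taxa):
                return node
        raise RuntimeError("unreachable: root must contain all tips")

    def tip_set(self, node: TreeNode) -> frozenset[str]:
        names = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                names.append(n.name)
            stack.extend(n.children)
        return frozenset(names)

    def path_length(self, ancestor: TreeNode, tip_name: str) -> float:
        """Sum of branch lengths on the path from *ancestor* down to a tip."""
        node = self.find_tip(tip_name)
        total = 0.0
        while node is not ancestor:
            total += node.length
            node = node.parent
            if node is None:
                raise ValueError(f"{tip_name!r} is not a descendant of the given node")
        return total

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n.parent is not None)

    # -- editing ------------------------------------------------------------

    def copy(self) -> "Phylogeny":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.label)
            for ch in node.children:
                new.add_child(clone(ch))
            return new

        return Phylogeny(clone(self.root), name=self.name)

    def scale(self, factor: float) -> "Phylogeny":
        """Return a copy with every branch length multiplied by *factor*."""
        out = self.copy()
        for node in out.preorder():
            node.length *= factor
        return out

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to the named tips.

        Unary internal nodes left by the pruning are collapsed with their
        branch lengths summed, so path lengths between kept tips are
        preserved exactly.  Branch labels on collapsed chains are retained if
        any collapsed branch carried one.
        """
        keep = set(keep)
        missing = keep - set(self.tip_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")

        def build(node: TreeNode) -> TreeNode | None:
            if node.is_tip:
                if node.name in keep:
                    return TreeNode(node.name, node.length, node.label)
                return None
            kept_children = [c for c in (build(ch) for ch in node.children) if c is not None]
            if not kept_children:
                return None
            if len(kept_children) == 1:
                child = kept_children[0]
                child.length += node.length
                if child.label is None:
                    child.label = node.label
                return child
            new = TreeNode(node.name, node.length, node.label)
            for ch in kept_children:
                new.add_child(ch)
            return new

        root = build(self.root)
        if root is None:
            raise ValueError("no tips kept")
        root.length = 0.0
        return Phylogeny(root, name=self.name)

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                body = node.name
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    body += node.name
            if node.parent is None:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"


def parse_newick(newick: str, name: str | None = None) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny` (via dendropy).

    Branches without lengths are read as 0 with a warning.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"could not parse Newick: {exc}") from exc

    warned = False

    def convert(dnode) -> TreeNode:
        nonlocal warned
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None and not warned:
                warnings.warn("branch without length read as 0", stacklevel=3)
                warned = True
            length = 0.0
        if length < 0:
            raise FormatError(f"negative branch length {length}")
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(name=label, length=float(length))
        for ch in dnode.child_nodes():
            node.add_child(convert(ch))
        return node

    return Phylogeny(convert(dtree.seed_node), name=name)


def read_newick(path, name: str | None = None) -> Phylogeny:
    with open(path) as fh:
        text = fh.read()
    if name is None:
        name = getattr(path, "stem", None) or str(path)
    return parse_newick(text, name=name)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# CladeConfig
# ---------------------------------------------------------------------------


@dataclass
class CladeConfig:
    """Named taxon sets driving every comparison in the screen.

    ``foreground`` is the focal clade (pit vipers, Crotalinae); ``outgroup``
    the infrared-insensitive non-viper snakes (Colubridae + Elapidae);
    ``viperinae`` and ``azemiopinae`` the infrared-insensitive viper
    subfamilies compared in the second and third filter steps.
    """

    foreground: frozenset[str]
    outgroup: frozenset[str] = frozenset()
    viperinae: frozenset[str] = frozenset()
    azemiopinae: frozenset[str] = frozenset()

    def __post_init__(self):
        self.foreground = frozenset(self.foreground)
        self.outgroup = frozenset(self.outgroup)
        self.viperinae = frozenset(self.viperinae)
        self.azemiopinae = frozenset(self.azemiopinae)
        if not self.foreground:
            raise ValueError("foreground taxon set is empty")
        sets = [self.foreground, self.outgroup, self.viperinae, self.azemiopinae]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"taxon sets overlap: {sorted(overlap)}")

    @property
    def nonpit_vipers(self) -> frozenset[str]:
        return self.viperinae | self.azemiopinae

    @property
    def all_taxa(self) -> frozenset[str]:
        return self.foreground | self.outgroup | self.viperinae | self.azemiopinae


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def _render(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.8g}"
    if value is None:
        return "NA"
    return str(value)


def write_records_table(records: Sequence[Mapping], path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous mapping records as a TSV with a header row.

    Floats are rendered with 8 significant digits; ``None`` becomes ``NA``.
    An empty record sequence yields a header-only file (requires *columns*
    or writes an empty header).
    """
    if columns is None:
        columns = list(records[0].keys()) if records else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(_render(rec[c]) for c in columns) + "\n")
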