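"""Truth-labelled synthetic datasets with the statistical structure the
screen assumes.

The generator emulates the study design: a 19-taxon snake species tree with
eight pit vipers (Crotalinae), the infrared-insensitive viper subfamilies
(Viperinae, Azemiopinae), colubrid/elapid outgroups and henophidian snakes.
Per gene, the species tree is scaled by a lognormal gene rate, a chosen
fraction of genes get their pit-viper stem branch multiplied by an
acceleration factor (the lineage-accelerated signal the screen hunts), every
branch receives independent mean-one lognormal noise, and codon alignments
are evolved forward under the branch-specific-omega codon model (accelerated
genes carry the elevated foreground omega on the stem).

Every stochastic step is driven by a single run seed; regenerating a bundle
from the same spec is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    Alignment,
    CladeConfig,
    Phylogeny,
    parse_newick,
    write_fasta_alignment,
    write_newick,
    write_records_table,
)
from .models import (
    AMINO_ACIDS,
    SENSE_CODONS,
    CodonModelSpec,
    ProteinModelSpec,
    build_rate_matrix,
    eig_reversible,
    transition_matrix,
)

__all__ = [
    "DEFAULT_SPECIES_TREE_NEWICK",
    "default_species_tree",
    "default_clade_config",
    "SimulationSpec",
    "GeneData",
    "simulate_gene_tree",
    "simulate_codon_alignment",
    "simulate_protein_alignment",
    "inject_foreground_substitutions",
    "simulate_screen_dataset",
]

# Ultrametric 19-taxon snake tree (branch lengths in expected substitutions
# per site, root-to-tip depth 0.16).  The pit-viper (Crotalinae) stem is
# 0.05; the deepest non-pit viper root-to-tip length inside Viperidae is
# 0.10, so a 3x stem acceleration (0.15) clears it while unaccelerated genes
# (0.05) sit well below — the separation the third filter step relies on.
_CROTALINAE = (
    "((Deinagkistrodon_acutus:0.025,(Crotalus_mitchellii:0.01,"
    "Crotalus_horridus:0.01):0.015):0.005,(Gloydius_brevicaudus:0.02,"
    "((Protobothrops_mucrosquamatus:0.008,Protobothrops_jerdonii:0.008):0.007,"
    "(Viridovipera_stejnegeri:0.01,Ovophis_monticola:0.01):0.005):0.005):0.01)"
)
DEFAULT_SPECIES_TREE_NEWICK = (
    "(((Xenopeltis_unicolor:0.11,(Python_bivittatus:0.06,Python_regius:0.06):0.05):0.03,"
    "(Boa_constrictor:0.08,Eryx_tataricus:0.08):0.06):0.02,"
    "(((Vipera_berus:0.06,Daboia_siamensis:0.06):0.04,"
    f"(Azemiops_feae:0.08,{_CROTALINAE}:0.05):0.02):0.04,"
    "((Pantherophis_guttatus:0.08,Thamnophis_sirtalis:0.08):0.04,"
    "Ophiophagus_hannah:0.12):0.02):0.02);"
)

CROTALINAE_TAXA = frozenset(
    {
        "Crotalus_mitchellii",
        "Crotalus_horridus",
        "Protobothrops_mucrosquamatus",
        "Protobothrops_jerdonii",
        "Deinagkistrodon_acutus",
        "Gloydius_brevicaudus",
        "Viridovipera_stejnegeri",
        "Ovophis_monticola",
    }
)
VIPERINAE_TAXA = frozenset({"Vipera_berus", "Daboia_siamensis"})
AZEMIOPINAE_TAXA = frozenset({"Azemiops_feae"})
OUTGROUP_TAXA = frozenset(
    {"Pantherophis_guttatus", "Thamnophis_sirtalis", "Ophiophagus_hannah"}
)


def default_species_tree() -> Phylogeny:
    tree = parse_newick(DEFAULT_SPECIES_TREE_NEWICK, name="genome_tree")
    label_foreground_stem(tree, CROTALINAE_TAXA)
    return tree


def default_clade_config() -> CladeConfig:
    return CladeConfig(
        foreground=CROTALINAE_TAXA,
        outgroup=OUTGROUP_TAXA,
        viperinae=VIPERINAE_TAXA,
        azemiopinae=AZEMIOPINAE_TAXA,
    )


def label_foreground_stem(tree: Phylogeny, foreground: frozenset[str]) -> None:
    """Mark the branch subtending the foreground clade with label 'FG'."""
    present = foreground & set(tree.tip_names())
    node = tree.mrca(present)
    node.label = "FG"


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    species_tree: Phylogeny = field(default_factory=default_species_tree)
    n_genes: int = 200
    gene_rate_sigma: float = 0.3          # lognormal sd of per-gene rate (median 1)
    accelerated_fraction: float = 0.05
    acceleration_factor: float = 3.0      # multiplier on the foreground stem
    branch_noise_sigma: float = 0.1       # mean-one lognormal per-branch noise
    codon_model: CodonModelSpec = field(
        default_factory=lambda: CodonModelSpec(
            kappa=2.0,
            omega_by_class={"BG": 0.2, "FG": 2.0},
            frequencies=np.full(61, 1.0 / 61),
            frequency_mode="uniform",
        )
    )
    n_codons: int = 300
    foreground: frozenset[str] = CROTALINAE_TAXA
    tipwide_acceleration: bool = False    # also accelerate branches inside the clade
    seed: int = 0

    def __post_init__(self):
        if self.acceleration_factor < 1:
            raise ValueError("acceleration_factor must be >= 1")
        if not 0 <= self.accelerated_fraction <= 1:
            raise ValueError("accelerated_fraction must be in [0,1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def n_accelerated(self) -> int:
        return int(round(self.n_genes * self.accelerated_fraction))

    def is_accelerated(self, gene_index: int) -> bool:
        # the first n_accelerated gene indices carry the signal; truth is
        # recorded in the bundle so downstream code never relies on the order
        return gene_index < self.n_accelerated


def _gene_rng(seed: int, gene_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, gene_index, stream])


def simulate_gene_tree(spec: SimulationSpec, gene_index: int) -> tuple[Phylogeny, bool]:
    """One gene tree: species tree x gene rate, optional stem acceleration,
    independent mean-one lognormal branch noise.  Deterministic per
    (seed, gene_index)."""
    rng = _gene_rng(spec.seed, gene_index, 0)
    rate = float(np.exp(rng.normal(0.0, spec.gene_rate_sigma))) if spec.gene_rate_sigma > 0 else 1.0
    tree = spec.species_tree.copy()
    tree.name = f"gene_{gene_index:04d}"
    accelerated = spec.is_accelerated(gene_index)

    fg_present = spec.foreground & set(tree.tip_names())
    stem_node = tree.mrca(fg_present)
    stem_node.label = "FG"

    mu = -0.5 * spec.branch_noise_sigma**2  # mean-one lognormal
    for node in tree.preorder():
        if node.parent is None:
            continue
        length = node.length * rate
        if accelerated:
            on_stem = node is stem_node
            inside = spec.tipwide_acceleration and _is_descendant(node, stem_node)
            if on_stem or inside:
                length *= spec.acceleration_factor
        if spec.branch_noise_sigma > 0:
            length *= float(np.exp(rng.normal(mu, spec.branch_noise_sigma)))
        node.length = length
    return tree, accelerated


def _is_descendant(node, ancestor) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def _sample_children(P: np.ndarray, parent_states: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    return (cum[parent_states] < u[:, None]).sum(axis=1)


def simulate_codon_alignment(
    tree: Phylogeny,
    model: CodonModelSpec,
    n_codons: int,
    seed: int,
    branch_class_map: dict | None = None,
) -> Alignment:
    """Evolve codons forward along the tree under the branch-class model.

    Root states are drawn from the equilibrium frequencies; each branch
    applies its class's transition matrix.  Branch classes come from
    ``branch_class_map`` (frozenset of descendant tips -> label) or from the
    labels stored on the tree.
    """
    if model.frequencies is None:
        raise ValueError("model needs explicit frequencies for simulation")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    systems = {
        cls: eig_reversible(build_rate_matrix(model, cls), model.frequencies)
        for cls in model.omega_by_class
    }
    if branch_class_map is not None:
        branch_class_map = {frozenset(k): v for k, v in branch_class_map.items()}

    pi = model.frequencies
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[id(root)] = rng.choice(61, size=n_codons, p=pi)
    sequences: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        if branch_class_map is not None:
            label = branch_class_map.get(frozenset(_tip_names_below(node)))
        else:
            label = node.label
        cls = model.resolve_class(label)
        P = systems[cls].P(node.length)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        child = _sample_children(P, states[id(node.parent)], rng)
        states[id(node)] = child
        if node.is_tip:
            sequences[node.name] = "".join(SENSE_CODONS[s] for s in child)
    return Alignment(name=tree.name or "sim", kind="codon", sequences=sequences)


def _tip_names_below(node) -> list[str]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.append(n.name)
        stack.extend(n.children)
    return out


def simulate_protein_alignment(
    tree: Phylogeny,
    spec: ProteinModelSpec,
    n_sites: int,
    seed: int,
) -> Alignment:
    """Forward simulation under the empirical protein model (+gamma rates)."""
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(spec)
    sys = eig_reversible(Q, spec.frequencies)
    rates, weights = spec.rates_and_weights()
    site_rates = rates[rng.choice(len(rates), size=n_sites, p=weights)]
    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(20, size=n_sites, p=spec.frequencies)
    sequences: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n_sites, dtype=np.int64)
        for r in np.unique(site_rates):
            mask = site_rates == r
            P = sys.P(node.length * r)
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            child[mask] = _sample_children(P, parent_states[mask], rng)
        states[id(node)] = child
        if node.is_tip:
            sequences[node.name] = "".join(AMINO_ACIDS[s] for s in child)
    return Alignment(name=tree.name or "sim", kind="protein", sequences=sequences)


def inject_foreground_substitutions(
    aln: Alignment,
    k: int,
    foreground: frozenset[str],
    seed: int,
) -> Alignment:
    """Plant k clade-specific substitutions into a protein alignment.

    At k distinct random columns every background taxon is set to the
    background consensus residue and every foreground taxon to a different
    residue, so a clean scan recovers exactly these columns (plus any hits
    the base alignment already had).
    """
    if aln.kind != "protein":
        raise ValueError("injection requires a protein alignment")
    fg = [t for t in aln.taxa if t in foreground]
    bg = [t for t in aln.taxa if t not in foreground]
    if not fg or not bg:
        raise ValueError("need both foreground and background taxa")
    n_cols = aln.length
    if k > n_cols:
        raise ValueError(f"k={k} exceeds {n_cols} columns")
    rng = np.random.default_rng(seed)
    cols = sorted(rng.choice(n_cols, size=k, replace=False))
    seqs = {t: list(s) for t, s in aln.sequences.items()}
    for col in cols:
        residues = [seqs[t][col] for t in bg if seqs[t][col] in AMINO_ACIDS]
        consensus = max(set(residues), key=residues.count) if residues else "A"
        substitute = next(a for a in AMINO_ACIDS if a != consensus)
        for t in bg:
            seqs[t][col] = consensus
        for t in fg:
            seqs[t][col] = substitute
    return Alignment(
        name=aln.name, kind="protein",
        sequences={t: "".join(s) for t, s in seqs.items()},
    )


@dataclass
class GeneData:
    name: str
    tree: Phylogeny
    alignment: Alignment
    accelerated: bool


def simulate_screen_dataset(
    spec: SimulationSpec,
    out_dir: str | Path | None = None,
    with_alignments: bool = True,
) -> list[GeneData]:
    """Per-gene trees (+codon alignments) with truth labels.

    Accelerated genes carry the foreground omega on the stem branch during
    sequence simulation; null genes evolve entirely under the background
    omega.  With *out_dir* the bundle is written out as Newick/FASTA plus a
    truth-label TSV.
    """
    bundle: list[GeneData] = []
    for g in range(spec.n_genes):
        tree, accelerated = simulate_gene_tree(spec, g)
        aln = None
        if with_alignments:
            model = spec.codon_model
            if not accelerated:
                # null genes: background omega everywhere
                model = CodonModelSpec(
                    kappa=model.kappa,
                    omega_by_class={"BG": model.omega_by_class[model.background_class]},
                    frequencies=model.frequencies,
                    frequency_mode=model.frequency_mode,
                )
            aln_seed = int(np.random.default_rng([spec.seed, g, 1]).integers(2**31))
            aln = simulate_codon_alignment(tree, model, spec.n_codons, aln_seed)
        bundle.append(GeneData(name=tree.name, tree=tree, alignment=aln, accelerated=accelerated))

    if out_dir is not None:
        out = Path(out_dir)
        (out / "trees").mkdir(parents=True, exist_ok=True)
        if with_alignments:
            (out / "alignments").mkdir(parents=True, exist_ok=True)
        for gd in bundle:
            write_newick(gd.tree, out / "trees" / f"{gd.name}.nwk")
            if gd.alignment is not None:
                write_fasta_alignment(gd.alignment, out / "alignments" / f"{gd.name}.fasta")
        write_records_table(
            [{"gene": gd.name, "accelerated": gd.accelerated} for gd in bundle],
            out / "truth.tsv",
        )
    return bundle
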