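import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pitscreen.io_formats import Alignment, CladeConfig, parse_newick
from pitscreen.models import CodonModelSpec, SENSE_CODONS


@pytest.fixture
def toy_tree():
    """((A:1,B:3):1,C:2); — root-to-tip: A=2, B=4, C=2."""
    return parse_newick("((A:1,B:3):1,C:2);", name="toy")


@pytest.fixture
def viper_toy_tree():
    """(((P1:1,P2:1):2,A1:1):1,V1:4); — pit-viper pair P1,P2 with stem 2."""
    return parse_newick("(((P1:1,P2:1):2,A1:1):1,V1:4);", name="vipertoy")


@pytest.fixture
def viper_toy_config():
    return CladeConfig(
        foreground={"P1", "P2"}, azemiopinae={"A1"}, viperinae={"V1"}
    )


@pytest.fixture
def uniform_codon_spec():
    return CodonModelSpec(
        kappa=2.0,
        omega_by_class={"BG": 0.3},
        frequencies=np.full(61, 1.0 / 61),
        frequency_mode="uniform",
    )


def random_codon_alignment(taxa, n_codons, seed, missing_rate=0.0):
    """Uniform random codon alignment (not simulated on a tree)."""
    rng = np.random.default_rng(seed)
    seqs = {}
    for t in taxa:
        codons = list(rng.choice(SENSE_CODONS, size=n_codons))
        if missing_rate:
            for i in range(n_codons):
                if rng.random() < missing_rate:
                    codons[i] = "---"
        seqs[t] = "".join(codons)
    return Alignment(name="rand", kind="codon", sequences=seqs)


# 6-taxon tree used by the simulation-estimation round trips: foreground
# pair F1,F2 whose stem (length 0.2) is the labeled branch.
SIX_TAXON_NEWICK = (
    "(((F1:0.05,F2:0.05):0.2,(V1:0.1,V2:0.1):0.05):0.05,(O1:0.2,O2:0.2):0.05);"
)


@pytest.fixture
def six_taxon_labeled_tree():
    tree = parse_newick(SIX_TAXON_NEWICK, name="sixtax")
    tree.mrca({"F1", "F2"}).label = "FG"
    return tree
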