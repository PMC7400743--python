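"""Reversible substitution models: branch-specific-omega codon model and
empirical protein model with discrete-gamma rate variation.

The codon model is the Goldman-Yang-style model used for branch tests of
selection: substitutions between codons differing at more than one position
have rate zero; single-nucleotide changes get a factor kappa if they are
transitions and a factor omega (dN/dS) if they are nonsynonymous, times the
equilibrium frequency of the target codon.  Each branch class (e.g. the
foreground stem "FG" vs the background "BG") carries its own omega.

The protein model is an empirical exchangeability matrix (WAG shipped as
packaged data) with either fixed or empirical ("+F") frequencies and an
optional discrete-gamma distribution of site rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist
from Bio.Data.CodonTable import standard_dna_table

from ._wag import WAG_EXCHANGEABILITIES_LOWER, WAG_FREQUENCIES, WAG_RESIDUES
from .io_formats import Alignment, MISSING_CHARS

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "AMINO_ACIDS",
    "CodonModelSpec",
    "ProteinModelSpec",
    "build_rate_matrix",
    "transition_matrix",
    "f3x4_frequencies",
    "empirical_protein_frequencies",
    "discrete_gamma_rates",
    "eig_reversible",
    "ReversibleEig",
]

_NUCS = "TCAG"
_NUC_INDEX = {n: i for i, n in enumerate(_NUCS)}

#: The 61 sense codons of the standard genetic code, in TCAG order (the
#: conventional codon-model state ordering).
SENSE_CODONS: list[str] = [
    a + b + c
    for a in _NUCS
    for b in _NUCS
    for c in _NUCS
    if a + b + c not in standard_dna_table.stop_codons
]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA: list[str] = [standard_dna_table.forward_table[c] for c in SENSE_CODONS]

AMINO_ACIDS = WAG_RESIDUES
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_PURINES = {"A", "G"}


def _codon_pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(single_diff, is_transition, is_nonsynonymous) boolean 61x61 tables."""
    n = len(SENSE_CODONS)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            a, b = ci[k], cj[k]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            nonsyn[i, j] = CODON_AA[i] != CODON_AA[j]
    return single, transition, nonsyn


_SINGLE_DIFF, _IS_TRANSITION, _IS_NONSYN = _codon_pair_tables()


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------


@dataclass
class CodonModelSpec:
    """Branch-class codon model: one omega per branch-class label.

    ``frequencies`` is the 61-vector of equilibrium codon frequencies; it may
    be given directly or derived from an alignment with
    :func:`f3x4_frequencies`.  ``background_class`` names the class assigned
    to unlabeled branches and to labels absent from ``omega_by_class``.
    """

    kappa: float = 2.0
    omega_by_class: dict[str, float] = field(default_factory=lambda: {"BG": 0.4})
    frequencies: np.ndarray | None = None
    frequency_mode: str = "F3x4"
    background_class: str = "BG"

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        for label, om in self.omega_by_class.items():
            if om < 0:
                raise ValueError(f"omega[{label}] must be >= 0")
        if self.frequencies is not None:
            self.frequencies = _check_frequencies(np.asarray(self.frequencies, float), 61)
        if self.background_class not in self.omega_by_class:
            raise ValueError("background_class must be a key of omega_by_class")

    def resolve_class(self, label: str | None) -> str:
        if label is not None and label in self.omega_by_class:
            return label
        return self.background_class

    def with_frequencies_from(self, aln: Alignment) -> "CodonModelSpec":
        """Return a copy with frequencies filled in per ``frequency_mode``."""
        if self.frequencies is not None:
            return self
        if self.frequency_mode == "F3x4":
            freqs = f3x4_frequencies(aln)
        elif self.frequency_mode == "F61":
            freqs = f61_frequencies(aln)
        elif self.frequency_mode == "uniform":
            freqs = np.full(61, 1.0 / 61)
        else:
            raise ValueError(f"unknown frequency_mode {self.frequency_mode!r}")
        return CodonModelSpec(
            kappa=self.kappa,
            omega_by_class=dict(self.omega_by_class),
            frequencies=freqs,
            frequency_mode=self.frequency_mode,
            background_class=self.background_class,
        )


@dataclass
class ProteinModelSpec:
    """Empirical amino-acid model (default WAG), optional +F and gamma rates."""

    exchangeabilities: np.ndarray | None = None  # 20x20 symmetric; None -> WAG
    frequencies: np.ndarray | None = None        # None -> WAG frequencies
    gamma_shape: float | None = None             # None -> single rate
    n_rate_categories: int = 4

    def __post_init__(self):
        if self.exchangeabilities is None:
            self.exchangeabilities = wag_exchangeability_matrix()
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        if self.exchangeabilities.shape != (20, 20):
            raise ValueError("exchangeabilities must be 20x20")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        if self.frequencies is None:
            self.frequencies = np.array(WAG_FREQUENCIES, float)
        self.frequencies = _check_frequencies(np.asarray(self.frequencies, float), 20)
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.n_rate_categories < 1:
            raise ValueError("need >= 1 rate category")

    def rates_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        if self.gamma_shape is None or self.n_rate_categories == 1:
            return np.array([1.0]), np.array([1.0])
        rates = discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)
        weights = np.full(self.n_rate_categories, 1.0 / self.n_rate_categories)
        return rates, weights


def wag_exchangeability_matrix() -> np.ndarray:
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = WAG_EXCHANGEABILITIES_LOWER[k]
            k += 1
    return s


def _check_frequencies(pi: np.ndarray, n: int) -> np.ndarray:
    if pi.shape != (n,):
        raise ValueError(f"frequency vector must have length {n}")
    if np.any(pi < 0) or not np.isfinite(pi).all():
        raise ValueError("frequencies must be finite and >= 0")
    total = pi.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {total}, not 1")
    return pi / total


# ---------------------------------------------------------------------------
# Frequencies from data
# ---------------------------------------------------------------------------

_FREQ_FLOOR = 1e-4  # floor on positional nucleotide frequencies (guards
                    # against zero equilibrium frequencies from sparse data)


def f3x4_frequencies(aln: Alignment) -> np.ndarray:
    """F3x4 codon frequencies: products of position-specific nucleotide
    frequencies over sense codons, renormalized."""
    if aln.kind != "codon":
        raise ValueError("F3x4 requires a codon alignment")
    counts = np.zeros((3, 4))
    for seq in aln.sequences.values():
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if any(c not in "ACGT" for c in codon):
                continue
            for pos, c in enumerate(codon):
                counts[pos, _NUC_INDEX[c]] += 1
    if counts.sum() == 0:
        return np.full(61, 1.0 / 61)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, _FREQ_FLOOR)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, _NUC_INDEX[c[0]]] * freqs[1, _NUC_INDEX[c[1]]] * freqs[2, _NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def f61_frequencies(aln: Alignment) -> np.ndarray:
    """Observed sense-codon frequencies with a small floor."""
    counts = np.zeros(61)
    for taxon in aln.sequences:
        for codon in aln.codons(taxon):
            idx = CODON_INDEX.get(codon)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        return np.full(61, 1.0 / 61)
    pi = np.maximum(counts / counts.sum(), _FREQ_FLOOR / 61)
    return pi / pi.sum()


def empirical_protein_frequencies(aln: Alignment) -> np.ndarray:
    counts = np.zeros(20)
    for seq in aln.sequences.values():
        for c in seq:
            if c in AA_INDEX:
                counts[AA_INDEX[c]] += 1
    if counts.sum() == 0:
        return np.full(20, 0.05)
    pi = np.maximum(counts / counts.sum(), 1e-4)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------


def _codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    rate = np.where(_IS_TRANSITION, kappa, 1.0) * np.where(_IS_NONSYN, omega, 1.0)
    Q = np.where(_SINGLE_DIFF, rate * pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _protein_rate_matrix(exch: np.ndarray, pi: np.ndarray) -> np.ndarray:
    Q = exch * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_rate_matrix(spec, class_label: str | None = None) -> np.ndarray:
    """Normalized instantaneous rate matrix for one branch class.

    Rows sum to zero; the matrix is scaled so that the expected number of
    substitutions per unit time at equilibrium, ``-sum_i pi_i Q_ii``, is 1 —
    branch lengths are then expected substitutions per site (per codon for
    codon models).  The matrix is time-reversible: ``pi_i Q_ij = pi_j Q_ji``.
    """
    if isinstance(spec, CodonModelSpec):
        if spec.frequencies is None:
            raise ValueError("codon spec has no frequencies; call with_frequencies_from")
        omega = spec.omega_by_class[spec.resolve_class(class_label)]
        Q = _codon_rate_matrix(spec.kappa, omega, spec.frequencies)
        pi = spec.frequencies
    elif isinstance(spec, ProteinModelSpec):
        Q = _protein_rate_matrix(spec.exchangeabilities, spec.frequencies)
        pi = spec.frequencies
    else:
        raise TypeError(f"unknown model spec {type(spec).__name__}")
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clamped to [0, 1].

    With *pi* supplied the exponential is computed by eigendecomposition in
    the pi-symmetrized basis (exact for reversible models, real spectrum);
    otherwise by scaling-and-squaring.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if pi is not None:
        P = eig_reversible(Q, pi).P(t)
    else:
        P = expm(Q * t)
    if P.min() < -1e-9:
        raise FloatingPointError(f"transition matrix entry {P.min()} < 0")
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass
class ReversibleEig:
    """Eigensystem of a reversible Q: P(t) = U @ diag(exp(lam*t)) @ Vt."""

    U: np.ndarray
    lam: np.ndarray
    Vt: np.ndarray
    pi: np.ndarray

    def P(self, t: float) -> np.ndarray:
        return (self.U * np.exp(self.lam * t)) @ self.Vt


def eig_reversible(Q: np.ndarray, pi: np.ndarray) -> ReversibleEig:
    """Eigendecompose a reversible rate matrix in the pi-symmetrized basis.

    ``B = D Q D^-1`` with ``D = diag(sqrt(pi))`` is symmetric for reversible
    Q, so the spectrum is real and the decomposition is numerically stable.
    """
    d = np.sqrt(pi)
    B = (Q * d[:, None]) / d[None, :]
    B = 0.5 * (B + B.T)  # symmetrize away rounding noise
    lam, S = np.linalg.eigh(B)
    U = S / d[:, None]
    Vt = S.T * d[None, :]
    return ReversibleEig(U=U, lam=lam, Vt=Vt, pi=pi)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, 1/alpha).

    The category means average to 1 exactly (mean-one gamma, the standard
    discrete-gamma construction for among-site rate variation).
    """
    if k == 1:
        return np.array([1.0])
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X; X <= b] for mean-one gamma = gammainc(alpha+1, alpha*b)
    partial = gammainc(alpha + 1, alpha * bounds[1:-1])
    partial = np.concatenate([[0.0], partial, [1.0]])
    means = k * np.diff(partial)
    return means / means.mean()
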