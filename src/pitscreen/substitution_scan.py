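"""Detection of foreground-specific (pit-viper-specific) amino-acid
substitutions.

A foreground-specific substitution is an alignment column where every
background snake shares one residue while every foreground (pit viper)
sequence shares a different residue — the classic signature of a fixed
lineage-specific replacement.  Columns are only scanned when the foreground
is fully observed and enough background sequences are present; the reported
proportion is counts over scanned columns, which keeps genes with different
missingness comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import Alignment, MISSING_CHARS

__all__ = ["SubstitutionSite", "SubstitutionReport", "find_foreground_specific_sites"]


@dataclass(frozen=True)
class SubstitutionSite:
    position: int  # 1-based protein column
    background_state: str
    foreground_state: str

    @property
    def notation(self) -> str:
        """'S126N'-style: background state, 1-based position, foreground state."""
        return f"{self.background_state}{self.position}{self.foreground_state}"


@dataclass
class SubstitutionReport:
    gene: str
    sites: list[SubstitutionSite]
    n_scanned: int

    @property
    def count(self) -> int:
        return len(self.sites)

    @property
    def proportion(self) -> float:
        return self.count / self.n_scanned if self.n_scanned else 0.0


def find_foreground_specific_sites(
    aln: Alignment,
    foreground: Iterable[str],
    background: Iterable[str],
    min_bg: int = 3,
) -> SubstitutionReport:
    """Scan a protein alignment for foreground-specific substitution columns.

    A column is scanned iff every foreground sequence has a non-missing
    residue and at least *min_bg* background sequences do.  It is a hit iff
    all foreground residues are identical, all observed background residues
    are identical, and the two states differ.
    """
    if aln.kind != "protein":
        raise ValueError("substitution scan expects a protein alignment")
    foreground = [t for t in foreground if t in aln.sequences]
    background = [t for t in background if t in aln.sequences]
    if not foreground or not background:
        raise ValueError("foreground and background must both be present in the alignment")
    overlap = set(foreground) & set(background)
    if overlap:
        raise ValueError(f"taxa in both sets: {sorted(overlap)}")

    fg_seqs = [aln.sequences[t] for t in foreground]
    bg_seqs = [aln.sequences[t] for t in background]
    sites: list[SubstitutionSite] = []
    n_scanned = 0
    for col in range(aln.length):
        fg_states = {s[col] for s in fg_seqs}
        if fg_states & MISSING_CHARS:
            continue
        bg_states = [s[col] for s in bg_seqs if s[col] not in MISSING_CHARS]
        if len(bg_states) < min_bg:
            continue
        n_scanned += 1
        if len(fg_states) != 1:
            continue
        bg_unique = set(bg_states)
        if len(bg_unique) != 1:
            continue
        fg_state = next(iter(fg_states))
        bg_state = next(iter(bg_unique))
        if fg_state != bg_state:
            sites.append(SubstitutionSite(col + 1, bg_state, fg_state))
    return SubstitutionReport(gene=aln.name, sites=sites, n_scanned=n_scanned)
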