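"""Full-screen orchestration: branch-length screen + selection screen, their
union and intersection, substitution reports, and supermatrix statistics.

The two sub-screens are deliberately independent: the branch-length filter
works on per-gene trees, the selection screen on per-gene codon alignments
plus a pruned genome tree.  The final candidate list is their union; genes
found by both are the doubly-supported set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence
import tomllib

from .io_formats import (
    Alignment,
    CladeConfig,
    Phylogeny,
    read_fasta_alignment,
    read_newick,
    translate_codon_alignment,
    write_records_table,
    MISSING_CHARS,
)
from .phylo_metrics import compute_clade_metrics
from .branch_screen import run_three_step_screen, rescreen_unconstrained
from .selection_tests import (
    branch_model_test,
    call_candidates,
    filter_ogg,
    prune_user_tree,
)
from .substitution_scan import find_foreground_specific_sites

__all__ = ["RunConfig", "run_full_screen", "concatenate_supermatrix", "ScreenReport"]

logger = logging.getLogger("pitscreen")


@dataclass
class RunConfig:
    """Configuration of a full screen run; round-trips through TOML."""

    alignments_dir: str
    trees_dir: str
    genome_tree: str
    output_dir: str
    foreground: list[str]
    outgroup: list[str] = field(default_factory=list)
    viperinae: list[str] = field(default_factory=list)
    azemiopinae: list[str] = field(default_factory=list)
    unconstrained_trees_dir: str | None = None
    refit_lines: bool = True
    strict: bool = True
    viper_origin: str = "viperidae_mrca"
    alpha: float = 0.05
    max_missing: float = 0.20
    min_fg: int = 4
    min_bg: int = 4
    min_fg_t: float = 1e-4
    seed: int = 0

    def clade_config(self) -> CladeConfig:
        return CladeConfig(
            foreground=frozenset(self.foreground),
            outgroup=frozenset(self.outgroup),
            viperinae=frozenset(self.viperinae),
            azemiopinae=frozenset(self.azemiopinae),
        )

    # -- TOML round trip ----------------------------------------------------

    def to_toml(self) -> str:
        lines = []
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, bool):
                rendered = "true" if value else "false"
            elif isinstance(value, (int, float)):
                rendered = repr(value)
            elif isinstance(value, str):
                rendered = f'"{value}"'
            elif isinstance(value, list):
                rendered = "[" + ", ".join(f'"{v}"' for v in value) + "]"
            else:
                raise TypeError(f"cannot render {key}={value!r}")
            lines.append(f"{key} = {rendered}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_toml())

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class ScreenReport:
    branch_candidates: set[str]
    selection_candidates: set[str]
    final_candidates: set[str]
    doubly_supported: set[str]
    screen_records: list
    selection_results: list
    substitution_reports: dict
    dispositions: dict[str, str]


def _load_dir(path: Path, loader, suffixes) -> dict[str, object]:
    out = {}
    for p in sorted(path.iterdir()):
        if p.suffix in suffixes:
            out[p.stem] = loader(p)
    return out


def run_full_screen(config: RunConfig) -> ScreenReport:
    """Run both sub-screens and combine their candidate lists.

    Emits per-step scatter tables, the selection results table, the
    candidate lists and per-candidate substitution reports under
    ``config.output_dir``; partial per-gene failures are logged and the run
    continues.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    from . import __version__ as _v
    logger.info("pitscreen %s full screen; seed=%d", _v, config.seed)
    logger.info("config: %s", asdict(config))

    clades = config.clade_config()
    genome_tree = read_newick(Path(config.genome_tree), name="genome_tree")
    trees: dict[str, Phylogeny] = _load_dir(
        Path(config.trees_dir), lambda p: read_newick(p, name=p.stem), {".nwk", ".tre", ".newick"}
    )
    alignments: dict[str, Alignment] = _load_dir(
        Path(config.alignments_dir),
        lambda p: read_fasta_alignment(p, kind="codon", name=p.stem),
        {".fasta", ".fa", ".fna"},
    )
    genes = sorted(set(trees) | set(alignments))
    dispositions: dict[str, str] = {}

    # ---- branch-length screen --------------------------------------------
    metrics = []
    for gene in sorted(trees):
        try:
            metrics.append(
                compute_clade_metrics(trees[gene], clades, viper_origin=config.viper_origin)
            )
        except Exception as exc:
            logger.warning("%s: branch metrics failed (%s)", gene, exc)
            dispositions[gene] = f"branch-screen error: {exc}"
    write_records_table(
        [
            {
                "gene": m.gene,
                "avg_fg_vs_outgroup": m.avg_fg_vs_outgroup,
                "avg_outgroup": m.avg_outgroup,
                "avg_fg_vs_vipers": m.avg_fg_vs_vipers,
                "avg_nonpit_vipers": m.avg_nonpit_vipers,
                "stem_fg": m.stem_fg,
                "max_nonpit_root_to_tip": m.max_nonpit_root_to_tip,
                "fg_monophyletic": m.fg_monophyletic,
            }
            for m in metrics
        ],
        out_dir / "clade_metrics.tsv",
        columns=[
            "gene", "avg_fg_vs_outgroup", "avg_outgroup", "avg_fg_vs_vipers",
            "avg_nonpit_vipers", "stem_fg", "max_nonpit_root_to_tip",
            "fg_monophyletic",
        ],
    )
    records = run_three_step_screen(
        metrics, strict=config.strict, refit_lines=config.refit_lines
    )
    branch_candidates = {r.gene for r in records if r.final_pass}
    if config.unconstrained_trees_dir:
        unconstrained = _load_dir(
            Path(config.unconstrained_trees_dir),
            lambda p: read_newick(p, name=p.stem),
            {".nwk", ".tre", ".newick"},
        )
        branch_candidates = rescreen_unconstrained(
            branch_candidates, unconstrained, clades,
            strict=config.strict, refit_lines=config.refit_lines,
            viper_origin=config.viper_origin,
        )
    for step in (1, 2, 3):
        write_records_table(
            [
                {
                    "gene": r.gene,
                    "x": getattr(r, f"step{step}").x,
                    "y": getattr(r, f"step{step}").y,
                    "pass": getattr(r, f"step{step}").passed,
                }
                for r in records
            ],
            out_dir / f"branch_screen_step{step}.tsv",
        )

    # ---- selection screen -------------------------------------------------
    selection_results = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        filtered = filter_ogg(
            aln, clades, max_missing=config.max_missing,
            min_fg=config.min_fg, min_bg=config.min_bg,
        )
        if filtered is None:
            dispositions[gene] = "selection: rejected by taxon/missingness filter"
            continue
        try:
            user_tree = prune_user_tree(
                genome_tree, filtered.taxa, clades.foreground
            )
            res = branch_model_test(aln=filtered, labeled_tree=user_tree, seed=config.seed)
            selection_results.append(res)
        except Exception as exc:
            logger.warning("%s: selection test failed (%s)", gene, exc)
            dispositions[gene] = f"selection error: {exc}"
    selection_candidates = call_candidates(
        selection_results, alpha=config.alpha, min_fg_t=config.min_fg_t
    )
    write_records_table(
        [
            {
                "gene": r.gene, "lnL0": r.lnl0, "lnL1": r.lnl1,
                "omega0": r.omega0, "omega1": r.omega1, "kappa": r.kappa,
                "LRT": r.lrt, "p": r.p_value, "q": r.q_value,
                "foreground_t": r.foreground_t,
                "low_rate_excluded": r.low_rate_excluded,
                "candidate": r.candidate,
            }
            for r in selection_results
        ],
        out_dir / "selection_results.tsv",
        columns=["gene", "lnL0", "lnL1", "omega0", "omega1", "kappa", "LRT",
                 "p", "q", "foreground_t", "low_rate_excluded", "candidate"],
    )

    # ---- combination ------------------------------------------------------
    final = branch_candidates | selection_candidates
    double = branch_candidates & selection_candidates
    for gene in genes:
        if gene in dispositions:
            continue
        tags = []
        if gene in branch_candidates:
            tags.append("branch-screen pass")
        if gene in selection_candidates:
            tags.append("selection candidate")
        dispositions[gene] = "; ".join(tags) if tags else "fail"

    # ---- substitution reports for the final candidates --------------------
    substitution_reports = {}
    background = clades.outgroup | clades.viperinae | clades.azemiopinae
    for gene in sorted(final):
        aln = alignments.get(gene)
        if aln is None:
            continue
        prot = translate_codon_alignment(aln)
        try:
            substitution_reports[gene] = find_foreground_specific_sites(
                prot, clades.foreground, background
            )
        except Exception as exc:
            logger.warning("%s: substitution scan failed (%s)", gene, exc)
    write_records_table(
        [
            {
                "gene": g,
                "count": rep.count,
                "n_scanned": rep.n_scanned,
                "proportion": rep.proportion,
                "sites": ",".join(s.notation for s in rep.sites),
            }
            for g, rep in substitution_reports.items()
        ],
        out_dir / "substitutions.tsv",
        columns=["gene", "count", "n_scanned", "proportion", "sites"],
    )
    write_records_table(
        [
            {
                "gene": g,
                "branch_screen": g in branch_candidates,
                "selection": g in selection_candidates,
                "doubly_supported": g in double,
            }
            for g in sorted(final)
        ],
        out_dir / "candidates.tsv",
        columns=["gene", "branch_screen", "selection", "doubly_supported"],
    )
    write_records_table(
        [{"gene": g, "disposition": dispositions[g]} for g in sorted(dispositions)],
        out_dir / "dispositions.tsv",
    )
    logger.info(
        "branch screen: %d candidates; selection: %d; union: %d; intersection: %d",
        len(branch_candidates), len(selection_candidates), len(final), len(double),
    )
    return ScreenReport(
        branch_candidates=branch_candidates,
        selection_candidates=selection_candidates,
        final_candidates=final,
        doubly_supported=double,
        screen_records=records,
        selection_results=selection_results,
        substitution_reports=substitution_reports,
        dispositions=dispositions,
    )


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (out_dir / "run.log").resolve()
        for h in logger.handlers
    ):
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------


def concatenate_supermatrix(
    alignments: Iterable[Alignment],
    taxa: Sequence[str],
) -> tuple[Alignment, float]:
    """Column-wise concatenation of protein alignments over a shared taxon set.

    Taxa absent from a gene are padded with missing characters.  Returns the
    supermatrix and its data completeness: the fraction of cells that are
    non-missing.
    """
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    total_len = 0
    for aln in alignments:
        L = aln.length
        total_len += L
        for t in taxa:
            parts[t].append(aln.sequences.get(t, "-" * L))
    sequences = {t: "".join(chunks) for t, chunks in parts.items()}
    super_aln = Alignment(name="supermatrix", kind="protein", sequences=sequences)
    total_cells = total_len * len(taxa)
    if total_cells == 0:
        return super_aln, 0.0
    missing = sum(
        sum(c in MISSING_CHARS for c in seq) for seq in sequences.values()
    )
    completeness = 1.0 - missing / total_cells
    return super_aln, completeness
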