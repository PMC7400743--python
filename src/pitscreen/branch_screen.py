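"""Three-step branch-length filter for foreground-accelerated genes.

Each gene is a point per step: step 1 plots the foreground average
root-to-tip length against the outgroup average; step 2 against the non-pit
viper average; step 3 plots the foreground stem length against the longest
non-pit viper root-to-tip length.  A gene survives a step when it lies
strictly above the 1:1 line and (steps 1-2) above an OLS regression line fit
on the genes entering that step.  Survivors of all three steps are candidate
accelerated genes; the screen can then be repeated on unconstrained gene
trees to confirm them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
import math
import warnings

import numpy as np

from .io_formats import CladeConfig, Phylogeny
from .phylo_metrics import CladeMetrics, compute_clade_metrics

__all__ = [
    "RegressionLine",
    "StepResult",
    "ScreenRecord",
    "fit_ols_line",
    "pass_step",
    "run_three_step_screen",
    "rescreen_unconstrained",
]


@dataclass(frozen=True)
class RegressionLine:
    slope: float
    intercept: float
    n_points: int


@dataclass
class StepResult:
    x: float | None
    y: float | None
    passed: bool


@dataclass
class ScreenRecord:
    gene: str
    step1: StepResult
    step2: StepResult
    step3: StepResult

    @property
    def final_pass(self) -> bool:
        return self.step1.passed and self.step2.passed and self.step3.passed


class FitError(ValueError):
    """OLS fit impossible (fewer than two points, or constant x)."""


def fit_ols_line(points: Sequence[tuple[float, float]]) -> RegressionLine:
    """Ordinary least squares of y on x with intercept."""
    pts = [(x, y) for x, y in points if math.isfinite(x) and math.isfinite(y)]
    if len(pts) < 2:
        raise FitError(f"need >=2 points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise FitError("constant x; regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return RegressionLine(float(slope), float(intercept), len(pts))


def pass_step(
    point: tuple[float | None, float | None],
    line: RegressionLine | None = None,
    strict: bool = True,
) -> bool:
    """True iff the point lies above the 1:1 line and, if given, the regression line.

    Undefined (None/non-finite) coordinates fail.  With ``strict=False`` ties
    on either line count as above.
    """
    x, y = point
    if x is None or y is None or not (math.isfinite(x) and math.isfinite(y)):
        return False
    above = (y > x) if strict else (y >= x)
    if line is not None:
        pred = line.slope * x + line.intercept
        above = above and ((y > pred) if strict else (y >= pred))
    return above


def _step_points(metrics: CladeMetrics, step: int) -> tuple[float | None, float | None]:
    if step == 1:
        return metrics.avg_outgroup, metrics.avg_fg_vs_outgroup
    if step == 2:
        return metrics.avg_nonpit_vipers, metrics.avg_fg_vs_vipers
    if step == 3:
        return metrics.max_nonpit_root_to_tip, metrics.stem_fg
    raise ValueError(step)


def run_three_step_screen(
    metrics: Sequence[CladeMetrics],
    strict: bool = True,
    refit_lines: bool = True,
    use_regression: bool = True,
) -> list[ScreenRecord]:
    """Apply the three-step filter to a batch of gene metrics.

    Steps 1 and 2 use both the 1:1 line and an OLS line; the OLS line is fit
    on the genes entering the step (``refit_lines=True``, default) or, with
    ``refit_lines=False``, once on the full input set and reused.  Step 3
    uses the 1:1 line only.  A gene with an undefined metric at a step fails
    that step; if too few points are available to fit a regression line the
    step falls back to the 1:1 line alone and a warning is emitted.

    Because the regression is fit on the pool being screened, the filter is
    pool-dependent; ``use_regression=False`` restricts every step to the 1:1
    line, a pure per-gene rule (useful when re-screening small candidate
    sets, where a refit line would pass through the candidate cloud itself).
    """
    records = [
        ScreenRecord(
            gene=m.gene,
            step1=StepResult(*_step_points(m, 1), False),
            step2=StepResult(*_step_points(m, 2), False),
            step3=StepResult(*_step_points(m, 3), False),
        )
        for m in metrics
    ]

    def fit_on(recs: Iterable[ScreenRecord], step: int) -> RegressionLine | None:
        pts = []
        for r in recs:
            sr = getattr(r, f"step{step}")
            if sr.x is not None and sr.y is not None:
                pts.append((sr.x, sr.y))
        if len(pts) < 3:
            # an OLS line through <=2 points interpolates them exactly, so
            # "strictly above the line" would reject everything
            warnings.warn(
                f"step {step}: only {len(pts)} points; regression degenerate, using 1:1 line only"
            )
            return None
        try:
            return fit_ols_line(pts)
        except FitError as exc:
            warnings.warn(f"step {step}: regression unavailable ({exc}); using 1:1 line only")
            return None

    entering = records
    for step in (1, 2, 3):
        if step == 3 or not use_regression:
            line = None
        else:
            pool = entering if refit_lines else records
            line = fit_on(pool, step)
        survivors = []
        for rec in entering:
            sr = getattr(rec, f"step{step}")
            sr.passed = pass_step((sr.x, sr.y), line, strict=strict)
            if sr.passed:
                survivors.append(rec)
        entering = survivors
    return records


def rescreen_unconstrained(
    candidates: Iterable[str],
    unconstrained_trees: Mapping[str, Phylogeny],
    config: CladeConfig,
    strict: bool = True,
    refit_lines: bool = True,
    use_regression: bool = True,
    viper_origin: str = "viperidae_mrca",
) -> set[str]:
    """Repeat the three-step screen on unconstrained trees of the candidates.

    Candidates without a tree are dropped with a warning.  A candidate whose
    unconstrained tree breaks foreground monophyly has an undefined stem and
    fails step 3.
    """
    metrics = []
    for gene in candidates:
        tree = unconstrained_trees.get(gene)
        if tree is None:
            warnings.warn(f"{gene}: no unconstrained tree; dropped from re-screen")
            continue
        if tree.name != gene:
            tree = tree.copy()
            tree.name = gene
        metrics.append(compute_clade_metrics(tree, config, viper_origin=viper_origin))
    records = run_three_step_screen(
        metrics, strict=strict, refit_lines=refit_lines, use_regression=use_regression
    )
    return {r.gene for r in records if r.final_pass}
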