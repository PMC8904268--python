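"""Relative-expression scoring of bulk expression matrices against a
control group, summarized per cell type via marker gene sets.

The construction: per-group gene medians -> each gene's group median
divided by its control-group median (genes with a near-zero control
median are dropped) -> per cell type, the vector of its marker genes'
ratios in each group, summarized by the median, with Kruskal-Wallis /
Dunn group comparisons attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import SignatureSet
from .stats_tests import TestResult, dunn_posthoc, kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GroupDesign",
    "RelativeExpressionTable",
    "CellTypeScore",
    "CellTypeScorePanel",
    "group_medians",
    "relative_expression",
    "score_cell_types",
    "compare_panel",
]


class ScoringError(ValueError):
    """Raised for invalid scoring inputs."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative gene x sample expression values (FPKM-like units)."""

    values: pd.DataFrame  # genes as index, samples as columns

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise ScoringError(
                f"duplicate gene identifiers: "
                f"{sorted(df.index[df.index.duplicated()].unique())}"
            )
        if df.columns.duplicated().any():
            raise ScoringError("duplicate sample identifiers")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ScoringError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ScoringError("missing expression values")
        if (arr < 0).any():
            gene = df.index[(arr < 0).any(axis=1)][0]
            raise ScoringError(f"negative expression value for gene {gene!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment with a designated control group."""

    assignment: dict[str, str]
    control_group: str

    def __post_init__(self) -> None:
        groups = set(self.assignment.values())
        if len(groups) < 2:
            raise ScoringError(f"need >= 2 groups, got {sorted(groups)}")
        if self.control_group not in groups:
            raise ScoringError(
                f"control group {self.control_group!r} has no samples "
                f"(groups: {sorted(groups)})"
            )

    @property
    def groups(self) -> list[str]:
        """Group labels, control first, then first-appearance order."""
        ordered = [self.control_group]
        for g in self.assignment.values():
            if g not in ordered:
                ordered.append(g)
        return ordered

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]


@dataclass(frozen=True)
class RelativeExpressionTable:
    """Per-gene, per-group median expression relative to the control group."""

    ratios: pd.DataFrame  # genes x groups
    control_group: str
    dropped_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = self.ratios.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ScoringError("ratios must be finite and non-negative")
        ctrl = self.ratios[self.control_group].to_numpy()
        if len(ctrl) and not np.all(ctrl == 1.0):
            raise ScoringError("control-group ratios must equal 1 exactly")

    @property
    def groups(self) -> list[str]:
        return list(self.ratios.columns)


@dataclass
class CellTypeScore:
    """One cell type's ratio vectors and summaries across groups."""

    cell_type: str
    genes: list[str]                      # marker genes present in the table
    ratio_vectors: dict[str, np.ndarray]  # group -> per-gene ratios
    summary: dict[str, float]             # group -> median of the vector
    n_genes: int
    omnibus: TestResult | None = None
    pairwise: dict[str, TestResult] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)
    testable: bool = True


@dataclass
class CellTypeScorePanel:
    """Per-cell-type score vectors for every group, plus absent types."""

    scores: dict[str, CellTypeScore]
    control_group: str
    absent_cell_types: tuple[str, ...] = ()

    @property
    def groups(self) -> list[str]:
        first = next(iter(self.scores.values()))
        return list(first.ratio_vectors)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cell_type, group, gene, ratio) frame."""
        rows = []
        for ct, sc in self.scores.items():
            for grp, vec in sc.ratio_vectors.items():
                for gene, r in zip(sc.genes, vec):
                    rows.append((ct, grp, gene, r))
        return pd.DataFrame(rows, columns=["cell_type", "group", "gene", "ratio"])

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-(cell_type, group) summary with attached test results."""
        rows = []
        for ct, sc in self.scores.items():
            for grp in sc.ratio_vectors:
                rows.append({
                    "cell_type": ct,
                    "group": grp,
                    "summary": sc.summary[grp],
                    "n_genes": sc.n_genes,
                    "p_omnibus": sc.omnibus.p_value if sc.omnibus else np.nan,
                    "p_pairwise_adj": (
                        sc.pairwise[grp].extra["p_adjusted"]
                        if grp in sc.pairwise else np.nan
                    ),
                    "significant": sc.significant.get(grp, False),
                })
        return pd.DataFrame(rows)


def group_medians(expr: ExpressionMatrix, design: GroupDesign) -> pd.DataFrame:
    """Per-gene sample median within each design group.

    Even-count groups use the midpoint of the two central order statistics.
    """
    missing = [s for s in design.assignment if s not in expr.values.columns]
    if missing:
        raise ScoringError(f"design samples missing from matrix: {missing}")
    cols = {}
    for grp in design.groups:
        samples = design.samples_in(grp)
        cols[grp] = np.median(expr.values[samples].to_numpy(), axis=1)
    return pd.DataFrame(cols, index=expr.values.index)


def relative_expression(
    medians: pd.DataFrame,
    control_group: str,
    epsilon: float = 1e-6,
) -> RelativeExpressionTable:
    """Divide each group median by the control median, per gene.

    Genes whose control median is below ``epsilon`` are moved to
    ``dropped_genes``; the retained control column is exactly 1.
    """
    if control_group not in medians.columns:
        raise ScoringError(
            f"control group {control_group!r} not in median table "
            f"(columns: {list(medians.columns)})"
        )
    if epsilon <= 0:
        raise ScoringError(f"epsilon must be positive, got {epsilon}")
    ctrl = medians[control_group]
    keep = ctrl >= epsilon
    dropped = tuple(medians.index[~keep])
    if dropped:
        logger.info("relative_expression: dropped %d genes with control median "
                    "< %g", len(dropped), epsilon)
    if not keep.any():
        raise ScoringError(
            f"all {len(medians)} genes dropped: control median < {epsilon}"
        )
    retained = medians.loc[keep]
    ratios = retained.div(retained[control_group], axis=0)
    # x/x is exactly 1.0 in IEEE arithmetic for finite nonzero x, but make
    # the control-column identity structural rather than incidental.
    ratios[control_group] = 1.0
    return RelativeExpressionTable(
        ratios=ratios, control_group=control_group, dropped_genes=dropped
    )


def score_cell_types(
    rel: RelativeExpressionTable, sigs: SignatureSet
) -> CellTypeScorePanel:
    """Collect each cell type's marker-gene ratio vector per group.

    Cell types with no marker gene present in the table are reported in
    ``absent_cell_types`` with a warning rather than silently skipped.
    """
    scores: dict[str, CellTypeScore] = {}
    absent: list[str] = []
    index = rel.ratios.index
    for ct, genes in sigs.sets.items():
        present = [g for g in genes if g in index]
        if not present:
            logger.warning("cell type %r: no marker gene present in the "
                           "expression table", ct)
            absent.append(ct)
            continue
        if len(present) < len(genes):
            logger.debug("cell type %r: %d of %d marker genes present",
                         ct, len(present), len(genes))
        sub = rel.ratios.loc[present]
        vectors = {grp: sub[grp].to_numpy(copy=True) for grp in rel.groups}
        summary = {grp: float(np.median(vec)) for grp, vec in vectors.items()}
        scores[ct] = CellTypeScore(
            cell_type=ct, genes=present, ratio_vectors=vectors,
            summary=summary, n_genes=len(present),
        )
    if not scores:
        raise ScoringError(
            "no signature gene of any cell type is present in the table"
        )
    return CellTypeScorePanel(
        scores=scores,
        control_group=rel.control_group,
        absent_cell_types=tuple(absent),
    )


def compare_panel(
    panel: CellTypeScorePanel,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    bonferroni_threshold: int | None = None,
) -> CellTypeScorePanel:
    """Attach group-comparison statistics to a score panel, in place.

    Per cell type: a Kruskal-Wallis omnibus over the groups' ratio vectors,
    then Dunn pairwise tests of each non-control group versus control.
    ``adjust`` is ``"bonferroni"`` (default), ``"none"``, or ``"auto"``;
    ``"auto"`` applies Bonferroni only when the number of groups exceeds
    ``bonferroni_threshold`` (default 4).  A group is flagged significant
    when both the omnibus and its adjusted pairwise p fall below ``alpha``.
    Cell types with any ratio vector shorter than 2 are flagged untestable.
    """
    if not 0 < alpha < 1:
        raise ScoringError(f"alpha must be in (0, 1), got {alpha}")
    if adjust not in ("bonferroni", "none", "auto"):
        raise ScoringError(f"unknown adjust scheme {adjust!r}")
    groups = panel.groups
    if len(groups) < 2:
        raise ScoringError("compare_panel requires >= 2 groups")
    if adjust == "auto":
        threshold = 4 if bonferroni_threshold is None else bonferroni_threshold
        adjust = "bonferroni" if len(groups) > threshold else "none"
    control = panel.control_group
    ctrl_idx = groups.index(control)
    for sc in panel.scores.values():
        vecs = [sc.ratio_vectors[g] for g in groups]
        if any(len(v) < 2 for v in vecs):
            logger.warning("cell type %r untestable: ratio vector shorter "
                           "than 2", sc.cell_type)
            sc.testable = False
            sc.significant = {g: False for g in groups if g != control}
            continue
        sc.omnibus = kruskal_wallis(vecs)
        # permutation p at small n, where the normal approximation is poor
        pairwise = dunn_posthoc(vecs, control_index=ctrl_idx, adjust=adjust,
                                method="auto")
        for res in pairwise:
            grp = groups[res.extra["group_index"]]
            sc.pairwise[grp] = res
            sc.significant[grp] = bool(
                sc.omnibus.p_value < alpha and res.extra["p_adjusted"] < alpha
            )
    return panel
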