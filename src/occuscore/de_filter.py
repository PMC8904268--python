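"""Gene-inclusion and differential-expression gates.

Two gates are provided: a read-count prefilter over an integer count
matrix (a gene is kept when enough samples reach a minimum read count,
either every sample or at least k of them — both dialects are explicit,
never a silent default), and a DEG gate combining a strict adjusted-p
bound with an inclusive, symmetric fold-change threshold
(FC >= t for "up", FC <= 1/t for "down").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "DEGTable",
    "FilterSpec",
    "ReadFilterResult",
    "DEGFilterResult",
    "apply_read_count_filter",
    "apply_deg_filter",
]


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class DEGTable:
    """Per-gene DE results: linear fold change (test/control) and adjusted p."""

    table: pd.DataFrame  # columns: gene, fold_change, padj; optional pvalue

    def __post_init__(self) -> None:
        df = self.table
        required = {"gene", "fold_change", "padj"}
        missing = required - set(df.columns)
        if missing:
            raise FilterError(f"DEG table missing columns: {sorted(missing)}")
        fc = df["fold_change"].to_numpy(dtype=float)
        bad = ~(fc > 0) | ~np.isfinite(fc)
        if bad.any():
            gene = df["gene"].iloc[int(np.flatnonzero(bad)[0])]
            raise FilterError(f"non-positive fold change for gene {gene!r}")
        p = df["padj"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
            raise FilterError("adjusted p-values must lie in [0, 1]")

    @classmethod
    def from_log2(cls, df: pd.DataFrame) -> "DEGTable":
        """Build from a table with a ``log2fc`` column instead of linear FC."""
        if "log2fc" not in df.columns:
            raise FilterError("expected a 'log2fc' column")
        out = df.copy()
        out["fold_change"] = np.exp2(out.pop("log2fc").to_numpy(dtype=float))
        return cls(out)


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for the read-count and DEG gates."""

    min_reads: int = 5
    min_samples_mode: Literal["all", "k_of_n"] = "k_of_n"
    min_samples_k: int = 3
    fc_threshold: float = 2.0
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise FilterError(f"min_reads must be >= 0, got {self.min_reads}")
        if self.min_samples_mode not in ("all", "k_of_n"):
            raise FilterError(f"unknown mode {self.min_samples_mode!r}")
        if self.min_samples_mode == "k_of_n" and self.min_samples_k < 1:
            raise FilterError("min_samples_k must be >= 1")
        if self.fc_threshold < 1:
            raise FilterError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if not 0 < self.alpha <= 1:
            raise FilterError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class ReadFilterResult:
    retained_genes: tuple[str, ...]
    n_input: int
    n_retained: int


@dataclass(frozen=True)
class DEGFilterResult:
    table: pd.DataFrame
    n_input: int
    n_retained: int
    n_up: int
    n_down: int


def apply_read_count_filter(
    counts: pd.DataFrame, spec: FilterSpec
) -> ReadFilterResult:
    """Keep genes with >= ``min_reads`` in all samples or in >= k samples.

    ``counts`` has gene rows and sample columns; values must be
    non-negative integers.
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FilterError("read counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise FilterError("read counts must be non-negative")
    n_samples = arr.shape[1]
    hits = (arr >= spec.min_reads).sum(axis=1)
    if spec.min_samples_mode == "all":
        keep = hits == n_samples
    else:
        if spec.min_samples_k > n_samples:
            raise FilterError(
                f"k={spec.min_samples_k} exceeds the {n_samples} samples"
            )
        keep = hits >= spec.min_samples_k
    retained = tuple(str(g) for g in counts.index[keep])
    return ReadFilterResult(
        retained_genes=retained, n_input=len(counts), n_retained=len(retained)
    )


def apply_deg_filter(
    table: DEGTable,
    spec: FilterSpec,
    direction: Literal["up", "down", "both"] = "both",
) -> DEGFilterResult:
    """Gate genes on adjusted p < alpha (strict) and fold change.

    "up" requires FC >= ``fc_threshold`` (inclusive), "down" requires
    FC <= 1/``fc_threshold``, "both" is their union.  Per-direction counts
    are always reported.
    """
    if direction not in ("up", "down", "both"):
        raise FilterError(f"unknown direction {direction!r}")
    df = table.table
    fc = df["fold_change"].to_numpy(dtype=float)
    padj = df["padj"].to_numpy(dtype=float)
    sig = padj < spec.alpha
    up = sig & (fc >= spec.fc_threshold)
    down = sig & (fc <= 1.0 / spec.fc_threshold)
    if direction == "up":
        keep = up
    elif direction == "down":
        keep = down
    else:
        keep = up | down
    return DEGFilterResult(
        table=df.loc[keep].reset_index(drop=True),
        n_input=len(df),
        n_retained=int(keep.sum()),
        n_up=int(up.sum()),
        n_down=int(down.sum()),
    )
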