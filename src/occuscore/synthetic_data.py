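"""Ground-truthed generators for every pipeline stage.

Bulk matrices are noisy linear mixtures of cell-type profiles:
``value(g, s) = sum_c pi_c(s) * P(g, c) * exp(eps)`` with
``eps ~ Normal(0, noise_sigma^2)`` (multiplicative lognormal noise keeps
values non-negative and right-skewed, as FPKM-like data are).  Microscopy
fields are non-overlapping noisy disks with marker signal rendered in a
chosen subcellular localization for a ground-truth subset of nuclei; the
matched negative control shares the nucleus layout but its marker channel
is background noise only.

Reproducibility: a single integer seed is split into one child stream per
generated object (profiles, each sample, placement, rendering), so adding
samples or images never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .bulk_scoring import ExpressionMatrix, GroupDesign
from .de_filter import DEGTable, FilterSpec
from .image_quant import ImageChannelSet
from .signatures import SignatureSet

__all__ = [
    "BulkSimParams",
    "SyntheticBulkTruth",
    "ImageSimParams",
    "SyntheticImageTruth",
    "simulate_bulk",
    "simulate_deg_table",
    "null_deg_pass_probability",
    "simulate_image",
    "simulate_counts",
    "round_half_away",
]


class SimulationError(ValueError):
    pass


def round_half_away(x: float) -> int:
    """Round half away from zero (the documented truth-count rounding rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


# ---------------------------------------------------------------------------
# bulk mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkSimParams:
    """Parameters of the bulk mixture generator.

    ``proportions`` maps each group label to a mixing vector over
    ``cell_types`` (must sum to 1 within 1e-9).  Marker genes express
    ``marker_fold`` times their base level in their own cell type; with
    ``pure_markers`` they express nothing elsewhere.  ``n_filler_genes``
    adds non-specific genes expressed equally in all cell types.
    """

    cell_types: tuple[str, ...]
    proportions: Mapping[str, Sequence[float]]
    markers_per_type: int = 20
    marker_fold: float = 100.0
    pure_markers: bool = False
    n_filler_genes: int = 0
    n_samples: int = 6
    noise_sigma: float = 0.2
    base_expr_range: tuple[float, float] = (5.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) < 1:
            raise SimulationError("need at least one cell type")
        if self.markers_per_type < 1:
            raise SimulationError("markers_per_type must be >= 1")
        if self.marker_fold <= 1:
            raise SimulationError("marker_fold must be > 1")
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be >= 0")
        if self.n_samples < 1:
            raise SimulationError("n_samples must be >= 1")
        if len(self.proportions) < 1:
            raise SimulationError("need at least one group")
        for grp, vec in self.proportions.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (len(self.cell_types),):
                raise SimulationError(
                    f"group {grp!r}: proportions length {arr.size} != "
                    f"{len(self.cell_types)} cell types"
                )
            if (arr < 0).any():
                raise SimulationError(f"group {grp!r}: negative proportion")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise SimulationError(
                    f"group {grp!r}: proportions sum to {arr.sum():.12f}, not 1"
                )

    @property
    def n_genes(self) -> int:
        return len(self.cell_types) * self.markers_per_type + self.n_filler_genes


@dataclass(frozen=True)
class SyntheticBulkTruth:
    """Generator ground truth for a simulated bulk matrix."""

    profiles: pd.DataFrame            # gene x cell type
    proportions: dict[str, np.ndarray]  # sample -> mixing vector
    signatures: SignatureSet
    params: BulkSimParams
    seed: int


def simulate_bulk(
    params: BulkSimParams,
) -> tuple[ExpressionMatrix, GroupDesign, SyntheticBulkTruth]:
    """Generate a mixture expression matrix with known composition.

    With ``noise_sigma = 0`` every value is the exact linear mixture.
    Sample names are ``<group>_<i>``; the control group for the design is
    the first group in ``params.proportions``.
    """
    streams = np.random.SeedSequence(params.seed).spawn(
        1 + len(params.proportions) * params.n_samples
    )
    profile_rng = np.random.default_rng(streams[0])

    cts = list(params.cell_types)
    genes: list[str] = []
    sets: dict[str, list[str]] = {ct: [] for ct in cts}
    profiles = np.empty((params.n_genes, len(cts)))
    row = 0
    for ci, ct in enumerate(cts):
        for mi in range(params.markers_per_type):
            gene = f"{ct}_marker_{mi + 1}"
            genes.append(gene)
            sets[ct].append(gene)
            base = profile_rng.uniform(*params.base_expr_range)
            profiles[row] = 0.0 if params.pure_markers else base
            profiles[row, ci] = base * params.marker_fold
            row += 1
    for fi in range(params.n_filler_genes):
        genes.append(f"filler_{fi + 1}")
        profiles[row] = profile_rng.uniform(*params.base_expr_range)
        row += 1

    assignment: dict[str, str] = {}
    truth_props: dict[str, np.ndarray] = {}
    cols: dict[str, np.ndarray] = {}
    stream_idx = 1
    for grp, vec in params.proportions.items():
        pi = np.asarray(vec, dtype=float)
        clean = profiles @ pi
        for i in range(params.n_samples):
            sample = f"{grp}_{i + 1}"
            rng = np.random.default_rng(streams[stream_idx])
            stream_idx += 1
            if params.noise_sigma > 0:
                noise = np.exp(rng.normal(0.0, params.noise_sigma, params.n_genes))
                cols[sample] = clean * noise
            else:
                cols[sample] = clean.copy()
            assignment[sample] = grp
            truth_props[sample] = pi
    matrix = ExpressionMatrix(pd.DataFrame(cols, index=genes))
    design = GroupDesign(
        assignment=assignment, control_group=next(iter(params.proportions))
    )
    truth = SyntheticBulkTruth(
        profiles=pd.DataFrame(profiles, index=genes, columns=cts),
        proportions=truth_props,
        signatures=SignatureSet(
            sets={ct: list(g) for ct, g in sets.items()},
            provenance=f"simulated; seed={params.seed}",
        ),
        params=params,
        seed=params.seed,
    )
    return matrix, design, truth


# ---------------------------------------------------------------------------
# DE tables and count matrices
# ---------------------------------------------------------------------------

def simulate_deg_table(
    n_genes: int,
    prop_alt: float,
    seed: int = 0,
    *,
    null_log2fc_sd: float = 0.5,
    alt_log2fc_mean: float = 2.0,
    alt_log2fc_sd: float = 0.5,
    alt_padj_max: float = 0.05,
) -> tuple[DEGTable, np.ndarray]:
    """DE results with known truth labels.

    Null genes: log2 fold change ~ Normal(0, ``null_log2fc_sd``), adjusted
    p ~ Uniform(0, 1), independently.  Alternative genes: |log2FC| ~
    Normal(``alt_log2fc_mean``, ``alt_log2fc_sd``) with random sign,
    adjusted p ~ Uniform(0, ``alt_padj_max``).  Returns the table and a
    boolean is-alternative label per gene.
    """
    if not 0 <= prop_alt <= 1:
        raise SimulationError(f"prop_alt must be in [0, 1], got {prop_alt}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = rng.random(n_genes) < prop_alt
    log2fc = rng.normal(0.0, null_log2fc_sd, n_genes)
    padj = rng.random(n_genes)
    n_alt = int(labels.sum())
    if n_alt:
        mags = np.abs(rng.normal(alt_log2fc_mean, alt_log2fc_sd, n_alt))
        signs = rng.choice([-1.0, 1.0], n_alt)
        log2fc[labels] = signs * mags
        padj[labels] = rng.random(n_alt) * alt_padj_max
    table = DEGTable(pd.DataFrame({
        "gene": [f"gene_{i + 1}" for i in range(n_genes)],
        "fold_change": np.exp2(log2fc),
        "padj": padj,
    }))
    return table, labels


def null_deg_pass_probability(
    spec: FilterSpec, null_log2fc_sd: float = 0.5
) -> float:
    """Analytic probability that a null gene passes the DEG gate ("both").

    padj < alpha has probability alpha (uniform null); |log2FC| >=
    log2(fc_threshold) has probability 2 * Phi(-log2(t) / sd); the two are
    independent under the generator's null.
    """
    if null_log2fc_sd == 0:
        tail = 1.0 if spec.fc_threshold <= 1 else 0.0
    else:
        tail = 2.0 * float(
            _norm.sf(math.log2(spec.fc_threshold) / null_log2fc_sd)
        )
    return spec.alpha * tail


def simulate_counts(
    n_genes: int, n_samples: int, seed: int = 0, max_count: int = 10
) -> pd.DataFrame:
    """Uniform small-integer count matrix for read-filter tests."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    arr = rng.integers(0, max_count + 1, size=(n_genes, n_samples))
    return pd.DataFrame(
        arr,
        index=[f"gene_{i + 1}" for i in range(n_genes)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# microscopy fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of the synthetic microscopy field generator."""

    shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 40
    radius_range: tuple[int, int] = (5, 8)
    positive_fraction: float = 0.2
    localization: Literal["nuclear", "cytoplasmic", "apical"] = "nuclear"
    nucleus_intensity: float = 200.0
    marker_intensity: float = 200.0
    background_mean: float = 20.0
    noise_sd: float = 5.0
    min_gap: int = 10
    ring_width: int = 4
    apical_offset: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise SimulationError("positive_fraction must be in [0, 1]")
        if self.localization not in ("nuclear", "cytoplasmic", "apical"):
            raise SimulationError(f"unknown localization {self.localization!r}")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] < 1:
            raise SimulationError("invalid radius_range")
        if self.n_nuclei < 0:
            raise SimulationError("n_nuclei must be >= 0")


@dataclass(frozen=True)
class SyntheticImageTruth:
    """Ground truth of a simulated field: nucleus geometry and positives."""

    centers: tuple[tuple[int, int], ...]
    radii: tuple[int, ...]
    positive_indices: tuple[int, ...]
    params: ImageSimParams
    seed: int

    @property
    def n_positive(self) -> int:
        return len(self.positive_indices)

    def nucleus_mask(
        self, indices: Sequence[int] | None = None, dilate: int = 0
    ) -> np.ndarray:
        """Boolean mask of the selected nuclei's disk footprints."""
        mask = np.zeros(self.params.shape, dtype=bool)
        sel = range(len(self.centers)) if indices is None else indices
        for i in sel:
            (cy, cx), r = self.centers[i], self.radii[i] + dilate
            yy, xx = _disk_coords(cy, cx, r, self.params.shape)
            mask[yy, xx] = True
        return mask


def _disk_coords(
    cy: int, cx: int, r: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    y0, y1 = max(0, int(cy - r) - 1), min(shape[0], int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(shape[1], int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return yy[inside], xx[inside]


def _place_nuclei(
    params: ImageSimParams, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], list[int]]:
    h, w = params.shape
    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    attempts = 0
    margin_extra = max(params.ring_width, params.apical_offset) + 2
    while len(centers) < params.n_nuclei:
        if attempts >= 10_000:
            raise SimulationError(
                f"could not place {params.n_nuclei} non-overlapping nuclei in "
                f"a {h}x{w} field after {attempts} attempts; try fewer nuclei "
                "or a larger field"
            )
        attempts += 1
        r = int(rng.integers(params.radius_range[0], params.radius_range[1] + 1))
        margin = r + margin_extra
        if 2 * margin >= h or 2 * margin >= w:
            raise SimulationError("nucleus radius too large for the field")
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        ok = all(
            (cy - oy) ** 2 + (cx - ox) ** 2
            >= (r + orad + params.min_gap) ** 2
            for (oy, ox), orad in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def _render_marker_footprint(
    truth_idx: int,
    centers: Sequence[tuple[int, int]],
    radii: Sequence[int],
    params: ImageSimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of the marker footprint for one positive nucleus."""
    (cy, cx), r = centers[truth_idx], radii[truth_idx]
    h, w = params.shape
    if params.localization == "nuclear":
        return _disk_coords(cy, cx, r, (h, w))
    outer = r + (params.ring_width if params.localization == "cytoplasmic"
                 else params.apical_offset)
    y0, y1 = max(0, cy - outer - 1), min(h, cy + outer + 2)
    x0, x1 = max(0, cx - outer - 1), min(w, cx + outer + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    ring = (d2 > r**2) & (d2 <= outer**2)
    if params.localization == "apical":
        ring &= yy <= cy  # upper half-ring stands in for the apical arc
    return yy[ring], xx[ring]


def simulate_image(
    params: ImageSimParams,
) -> tuple[ImageChannelSet, ImageChannelSet, SyntheticImageTruth]:
    """Render a field, its matched negative control, and the ground truth.

    The number of positive nuclei is ``round_half_away(positive_fraction *
    n_nuclei)``.  The negative control shares the nucleus layout; its
    marker channel is background noise drawn from the same distribution as
    the field's marker background.
    """
    ss = np.random.SeedSequence(params.seed).spawn(4)
    place_rng = np.random.default_rng(ss[0])
    select_rng = np.random.default_rng(ss[1])
    field_rng = np.random.default_rng(ss[2])
    control_rng = np.random.default_rng(ss[3])

    centers, radii = _place_nuclei(params, place_rng)
    n_pos = round_half_away(params.positive_fraction * params.n_nuclei)
    positive = tuple(
        sorted(select_rng.choice(params.n_nuclei, size=n_pos, replace=False))
    ) if n_pos else ()

    def render(rng: np.random.Generator, with_marker: bool) -> ImageChannelSet:
        h, w = params.shape
        nuc = rng.normal(params.background_mean, params.noise_sd, (h, w))
        mk = rng.normal(params.background_mean, params.noise_sd, (h, w))
        for (cy, cx), r in zip(centers, radii):
            yy, xx = _disk_coords(cy, cx, r, (h, w))
            nuc[yy, xx] = params.nucleus_intensity + rng.normal(
                0.0, params.noise_sd, yy.size
            )
        if with_marker:
            for i in positive:
                yy, xx = _render_marker_footprint(i, centers, radii, params)
                mk[yy, xx] = params.marker_intensity + rng.normal(
                    0.0, params.noise_sd, yy.size
                )
        return ImageChannelSet(
            nuclei_channel=np.clip(nuc, 0.0, None),
            marker_channel=np.clip(mk, 0.0, None),
        )

    field = render(field_rng, with_marker=True)
    control = render(control_rng, with_marker=False)
    truth = SyntheticImageTruth(
        centers=tuple(centers),
        radii=tuple(radii),
        positive_indices=positive,
        params=params,
        seed=params.seed,
    )
    return field, control, truth
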