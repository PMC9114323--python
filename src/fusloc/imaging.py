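"""Per-cell fluorescence quantification.

Implements the integrated-density arithmetic used to measure
nucleocytoplasmic protein and poly(A+) RNA distributions: integrated
density (sum of pixel intensities over an ROI, equivalently mean × area),
background adjustment from a staining-free ROI, cytoplasmic-to-nuclear
ratios, DAPI-normalized totals, nuclear poly(A+) concentration, Pearson
correlation of paired per-cell ratios, and a Kruskal–Wallis + Dunn
multi-group comparison.

Segmentation is out of scope: whole-cell and nucleus label masks are
required inputs (ROIs are drawn upstream).  A convenience thresholding
helper exists for synthetic DAPI channels only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

log = logging.getLogger(__name__)


class MaskValidationError(ValueError):
    """Channels and label masks are mutually inconsistent."""


@dataclass
class CellImageSet:
    """Registered intensity channels plus whole-cell / nucleus label masks.

    ``cell_labels`` and ``nucleus_labels`` share label values (0 is
    background; label *k* is cell *k*); each cell's nucleus mask must be a
    subset of its whole-cell mask.  ``background_roi`` marks a staining-free
    region disjoint from every cell, from which per-channel background means
    are taken.
    """

    channels: dict[str, np.ndarray]
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    background_roi: np.ndarray | None = None

    def validate(self) -> None:
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        ref = self.cell_labels.shape
        for name, shape in shapes.items():
            if shape != ref:
                raise MaskValidationError(
                    f"channel {name!r} shape {shape} != label shape {ref}"
                )
        if self.nucleus_labels.shape != ref:
            raise MaskValidationError("nucleus_labels shape differs from cell_labels")
        if self.background_roi is not None and self.background_roi.shape != ref:
            raise MaskValidationError("background_roi shape differs from cell_labels")
        labels = self.labels()
        for k in labels:
            nuc = self.nucleus_labels == k
            if not nuc.any():
                raise MaskValidationError(f"cell {k}: empty nucleus mask")
            if np.any(nuc & (self.cell_labels != k)):
                raise MaskValidationError(f"cell {k}: nucleus mask not inside whole-cell mask")
        if self.background_roi is not None and np.any(
            self.background_roi.astype(bool) & (self.cell_labels > 0)
        ):
            raise MaskValidationError("background_roi overlaps a cell mask")

    def labels(self) -> list[int]:
        vals = np.unique(self.cell_labels)
        return [int(v) for v in vals if v > 0]


@dataclass
class CellMeasurement:
    """Background-adjusted integrated densities and ratios for one cell/channel."""

    cell_id: int
    channel: str
    whole_id: float
    nuclear_id: float
    cyto_id: float
    whole_area: int
    nuclear_area: int
    background_mean: float
    adjusted_whole_id: float
    adjusted_nuclear_id: float
    adjusted_cyto_id: float
    cn_ratio: float  # NaN when the adjusted nuclear density is not positive
    dapi_normalized_total: float = math.nan
    nuclear_concentration: float = math.nan
    clamped: bool = False  # a negative adjusted density was clamped to 0


def integrated_density(channel: np.ndarray, mask: np.ndarray) -> float:
    """Sum of intensities over the mask (mean pixel intensity × area)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("integrated_density: empty mask")
    return float(np.asarray(channel, dtype=float)[mask].sum())


def background_adjust(
    id_value: float, mask_area: int, background_mean: float, clamp: bool = True
) -> float:
    """Subtract the background contribution from an integrated density.

    Returns ``id_value − background_mean × mask_area``.  Negative results
    are non-physical and are clamped to 0 when ``clamp`` is set (callers
    flag the clamping per cell).
    """
    if mask_area < 1:
        raise ValueError("mask_area must be >= 1")
    adjusted = id_value - background_mean * mask_area
    if clamp and adjusted < 0:
        return 0.0
    return adjusted


def cytoplasmic_nuclear_ratio(adjusted_whole_id: float, adjusted_nuclear_id: float) -> float:
    """(whole − nuclear) / nuclear integrated density; NaN if nuclear ≤ 0.

    Values below the nuclear density (negative cytoplasmic signal) are
    flagged by the caller but returned as-is.
    """
    if adjusted_nuclear_id <= 0:
        return math.nan
    return (adjusted_whole_id - adjusted_nuclear_id) / adjusted_nuclear_id


def dapi_normalized_level(total_id: float, dapi_id: float) -> float:
    """Total intensity normalized to DAPI (corrects focal-plane bias)."""
    if dapi_id <= 0:
        return math.nan
    return total_id / dapi_id


def nuclear_polyA_concentration(nuclear_polyA_id: float, dapi_id: float, nuclear_area: int) -> float:
    """DAPI-adjusted nuclear intensity per unit nuclear area."""
    if dapi_id <= 0:
        raise ValueError("dapi_id must be positive")
    if nuclear_area < 1:
        raise ValueError("nuclear_area must be >= 1")
    return (nuclear_polyA_id / dapi_id) / nuclear_area


def _border_labels(labels: np.ndarray) -> set[int]:
    edges = np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    return {int(v) for v in np.unique(edges) if v > 0}


def quantify_cells(
    images: CellImageSet,
    channels_to_measure: Sequence[str],
    dapi_channel: str | None = None,
    background_correct: bool = True,
    exclude_border: bool = True,
) -> list[CellMeasurement]:
    """Measure every (cell, channel) pair in an image set.

    For each channel the background mean is taken over the staining-free
    ROI (0 if absent or ``background_correct`` is off).  Whole-cell and
    nuclear integrated densities are background-adjusted over their own
    areas; the cytoplasmic density is their difference.  When a DAPI
    channel is named, per-cell DAPI integrated density (nuclear ROI,
    background-adjusted) normalizes the whole-cell total and the nuclear
    concentration.  Cells touching the image border are excluded and
    logged.
    """
    images.validate()
    labels = images.labels()
    if not labels:
        log.warning("quantify_cells: no cells in label mask")
        return []
    border = _border_labels(images.cell_labels) if exclude_border else set()
    if border:
        log.info("quantify_cells: excluding %d border-touching cells", len(border))
    bg_mask = images.background_roi.astype(bool) if images.background_roi is not None else None

    def bg_mean(name: str) -> float:
        if not background_correct or bg_mask is None or not bg_mask.any():
            return 0.0
        return float(np.asarray(images.channels[name], dtype=float)[bg_mask].mean())

    backgrounds = {name: bg_mean(name) for name in set(channels_to_measure) | (
        {dapi_channel} if dapi_channel else set()
    )}

    out: list[CellMeasurement] = []
    for k in labels:
        if k in border:
            continue
        cell_mask = images.cell_labels == k
        nuc_mask = images.nucleus_labels == k
        whole_area = int(cell_mask.sum())
        nuclear_area = int(nuc_mask.sum())

        dapi_id = math.nan
        if dapi_channel is not None:
            dapi_raw = integrated_density(images.channels[dapi_channel], nuc_mask)
            dapi_id = background_adjust(dapi_raw, nuclear_area, backgrounds[dapi_channel])

        for name in channels_to_measure:
            ch = images.channels[name]
            whole_id = integrated_density(ch, cell_mask)
            nuclear_id = integrated_density(ch, nuc_mask)
            cyto_id = whole_id - nuclear_id
            bg = backgrounds[name]
            adj_whole_raw = background_adjust(whole_id, whole_area, bg, clamp=False)
            adj_nuc_raw = background_adjust(nuclear_id, nuclear_area, bg, clamp=False)
            clamped = adj_whole_raw < 0 or adj_nuc_raw < 0
            adj_whole = max(0.0, adj_whole_raw)
            adj_nuc = max(0.0, adj_nuc_raw)
            adj_cyto = adj_whole - adj_nuc
            if adj_cyto < 0:
                clamped = True
                adj_cyto = 0.0
            ratio = cytoplasmic_nuclear_ratio(adj_whole, adj_nuc)
            meas = CellMeasurement(
                cell_id=k,
                channel=name,
                whole_id=whole_id,
                nuclear_id=nuclear_id,
                cyto_id=cyto_id,
                whole_area=whole_area,
                nuclear_area=nuclear_area,
                background_mean=bg,
                adjusted_whole_id=adj_whole,
                adjusted_nuclear_id=adj_nuc,
                adjusted_cyto_id=adj_cyto,
                cn_ratio=ratio,
                clamped=clamped,
            )
            if dapi_channel is not None and dapi_id > 0:
                meas.dapi_normalized_total = dapi_normalized_level(adj_whole, dapi_id)
                meas.nuclear_concentration = nuclear_polyA_concentration(
                    adj_nuc, dapi_id, nuclear_area
                )
            out.append(meas)
    return out


def measurements_to_frame(measurements: Sequence[CellMeasurement]) -> pd.DataFrame:
    """Tabulate per-cell measurements (one row per cell × channel)."""
    cols = [
        "cell_id", "channel", "whole_area", "nuclear_area", "background_mean",
        "whole_id", "nuclear_id", "cyto_id",
        "adjusted_whole_id", "adjusted_nuclear_id", "adjusted_cyto_id",
        "cn_ratio", "dapi_normalized_total", "nuclear_concentration", "clamped",
    ]
    return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in measurements], columns=cols)


def ratio_correlation(
    ratios_a: Sequence[float], ratios_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of paired per-cell ratios.

    Pairs with an undefined (NaN) member are dropped.  Returns (r, p) with
    the two-sided p-value from the t-distribution on n−2 degrees of
    freedom; (NaN, NaN) when fewer than 3 defined pairs remain or either
    vector has zero variance.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ratio vectors must be paired (equal length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan, math.nan
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DunnResult:
    """Kruskal–Wallis omnibus plus Dunn pairwise z-tests."""

    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame = field(repr=False)


def kruskal_dunn(groups: Mapping[str, Sequence[float]], p_adjust: str = "bonferroni") -> DunnResult:
    """Multi-group rank comparison: Kruskal–Wallis then Dunn's z-tests.

    Dunn's statistic for groups i, j uses pooled midranks:
    z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    term T = Σ(t³ − t) / (12(N − 1)).  Pairwise two-sided p-values are
    adjusted by Bonferroni (default) or left raw (``p_adjust=None``).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("kruskal_dunn requires at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    h, p = stats.kruskal(*arrays)
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    mean_ranks = {}
    idx = 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = float(ranks[idx: idx + arr.size].mean())
        idx += arr.size
    rows = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i, j in itertools.combinations(range(len(names)), 2):
        ni, nj = arrays[i].size, arrays[j].size
        se = math.sqrt((n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        if p_adjust == "bonferroni":
            p_adj = min(1.0, p_raw * n_pairs)
        elif p_adjust is None or p_adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown p_adjust {p_adjust!r}")
        rows.append({"group_a": names[i], "group_b": names[j], "z": z,
                     "p_raw": p_raw, "p_adjusted": p_adj})
    return DunnResult(h_statistic=float(h), p_value=float(p), pairwise=pd.DataFrame(rows))


def threshold_nucleus_mask(dapi: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Label nuclei in a clean (synthetic) DAPI channel.

    Global threshold (midpoint of the intensity range by default) followed
    by connected-component labelling.  Intended for simulated images only;
    real micrographs need proper segmentation upstream.
    """
    img = np.asarray(dapi, dtype=float)
    if threshold is None:
        threshold = 0.5 * (img.min() + img.max())
    labels, _ = ndimage.label(img > threshold)
    return labels


__all__ = [
    "CellImageSet",
    "CellMeasurement",
    "MaskValidationError",
    "DunnResult",
    "integrated_density",
    "background_adjust",
    "cytoplasmic_nuclear_ratio",
    "dapi_normalized_level",
    "nuclear_polyA_concentration",
    "quantify_cells",
    "measurements_to_frame",
    "ratio_correlation",
    "kruskal_dunn",
    "threshold_nucleus_mask",
]
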