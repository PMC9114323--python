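"""Synthetic peak tables and cell images with known ground truth.

Every stage of the pipeline can be exercised without any external data:
``simulate_peak_pair`` emits a control/affected pair of HOMER-dialect peak
sets whose expression differs by a known multiplicative effect, and
``simulate_cell_image`` renders disk-shaped cells whose cytoplasmic to
nuclear integrated-density ratio equals a configured truth exactly before
noise.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .imaging import CellImageSet
from .io import PeakRecord, PeakSet

_MAX_PLACEMENT_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Cells could not be placed without overlap within the attempt budget."""


@dataclass
class PeakSimConfig:
    """Generative model for a control / affected peak-table pair.

    Transcript lengths and expression (read counts) are log-normal in
    log10 units, spanning the several orders of magnitude typical of
    nascent-transcript tables.  The affected condition's expression is
    reduced by ``effect_fraction`` (the ground-truth analogue of the ~10%
    reduction the pipeline is meant to recover); multiplicative log-normal
    measurement noise of ``noise_log_sd`` (log10) is applied independently
    per condition.  ``paired=True`` (default) gives both conditions the
    same per-transcript expression base — a matched-transcript design;
    ``paired=False`` draws each condition's lengths and expression
    independently from the same distributions, emulating independently
    called peak tables, which is the regime where the two samples are
    genuinely i.i.d. and an unpaired rank-sum test is calibrated.
    """

    n_transcripts: int = 2000
    length_log_mean: float = 3.5
    length_log_sd: float = 0.6
    expression_log_mean: float = 2.0
    expression_log_sd: float = 1.0
    effect_fraction: float = 0.10
    target_fraction: float = 0.3
    total_aligned_reads: int = 100_000_000
    noise_log_sd: float = 0.02
    count_model: str = "lognormal"  # or "poisson"
    paired: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if not (0.0 <= self.effect_fraction < 1.0):
            raise ValueError("effect_fraction must lie in [0, 1)")
        if not (0.0 <= self.target_fraction <= 1.0):
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.total_aligned_reads <= 0:
            raise ValueError("total_aligned_reads must be positive")
        if self.noise_log_sd < 0 or self.length_log_sd < 0 or self.expression_log_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.count_model not in ("lognormal", "poisson"):
            raise ValueError("count_model must be 'lognormal' or 'poisson'")


def _draw_lengths(rng: np.random.Generator, cfg: PeakSimConfig) -> np.ndarray:
    lengths = np.round(10 ** rng.normal(cfg.length_log_mean, cfg.length_log_sd, cfg.n_transcripts))
    return np.maximum(lengths, 1).astype(np.int64)


def _draw_counts(rng: np.random.Generator, cfg: PeakSimConfig, expected: np.ndarray) -> np.ndarray:
    if cfg.count_model == "poisson":
        return rng.poisson(expected).astype(np.int64)
    noisy = expected * 10 ** rng.normal(0.0, cfg.noise_log_sd, expected.size)
    return np.maximum(np.round(noisy), 0).astype(np.int64)


def _build_peak_set(
    label: str,
    lengths: np.ndarray,
    counts: np.ndarray,
    genes: Sequence[str],
    strands: np.ndarray,
    total_aligned_reads: int,
) -> PeakSet:
    starts = np.concatenate([[0], np.cumsum(lengths[:-1] + 1000)])
    records = [
        PeakRecord(
            peak_id=f"{label}-peak{i + 1}",
            gene_id=genes[i],
            chrom="chr1",
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand="+" if strands[i] else "-",
            raw_reads=float(counts[i]),
        )
        for i in range(len(lengths))
    ]
    return PeakSet(sample_label=label, total_aligned_reads=total_aligned_reads, records=records)


def simulate_peak_pair(config: PeakSimConfig) -> tuple[PeakSet, PeakSet, dict]:
    """Simulate a (control, affected) peak-table pair with known truth.

    Returns the two PeakSets plus a truth record holding the configured
    effect, the target-gene set, and per-transcript expected expression
    for each condition.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    genes = [f"g{i + 1:06d}" for i in range(n)]
    strands = rng.random(n) < 0.5

    lengths_c = _draw_lengths(rng, config)
    base_c = 10 ** rng.normal(config.expression_log_mean, config.expression_log_sd, n)
    if config.paired:
        lengths_a = lengths_c
        base_a = base_c * (1.0 - config.effect_fraction)
    else:
        lengths_a = _draw_lengths(rng, config)
        base_a = 10 ** rng.normal(config.expression_log_mean, config.expression_log_sd, n)
        base_a = base_a * (1.0 - config.effect_fraction)

    counts_c = _draw_counts(rng, config, base_c)
    counts_a = _draw_counts(rng, config, base_a)

    n_targets = int(round(config.target_fraction * n))
    target_genes = sorted(rng.choice(genes, size=n_targets, replace=False).tolist())

    control = _build_peak_set("control", lengths_c, counts_c, genes, strands,
                              config.total_aligned_reads)
    affected = _build_peak_set("affected", lengths_a, counts_a, genes, strands,
                               config.total_aligned_reads)
    truth = {
        "config": asdict(config),
        "effect_fraction": config.effect_fraction,
        "expected_percent_reduction": 100.0 * config.effect_fraction,
        "target_genes": target_genes,
        "expected_reads_control": base_c.tolist(),
        "expected_reads_affected": base_a.tolist(),
    }
    return control, affected, truth


@dataclass
class CellSimConfig:
    """Generative model for a field of disk-shaped cells.

    Each cell is a disk of ``cell_radius`` pixels with a concentric nucleus
    of ``nucleus_radius``; the nuclear channel intensity is uniform and the
    cytoplasmic intensity is chosen per cell so that the ratio of total
    cytoplasmic to nuclear integrated density equals ``true_cn_ratio``
    exactly before noise.  A uniform ``background_level`` is added
    everywhere, then Gaussian noise of sd ``noise_sd`` (clipped at 0).  A
    staining-free square in the top-left corner is reserved as the
    background ROI.
    """

    n_cells: int = 50
    image_shape: tuple[int, int] = (512, 512)
    true_cn_ratio: float = 0.5
    nuclear_intensity: float = 100.0
    background_level: float = 0.0
    noise_sd: float = 0.0
    nucleus_radius: int = 6
    cell_radius: int = 12
    dapi_intensity: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (self.cell_radius > self.nucleus_radius > 0):
            raise ValueError("require cell_radius > nucleus_radius > 0")
        if self.true_cn_ratio < 0:
            raise ValueError("true_cn_ratio must be nonnegative")
        if self.nuclear_intensity <= 0 or self.dapi_intensity <= 0:
            raise ValueError("intensities must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be nonnegative")


def _place_cells(rng: np.random.Generator, cfg: CellSimConfig, bg_box: int) -> list[tuple[int, int]]:
    h, w = cfg.image_shape
    r = cfg.cell_radius
    margin = r + 2  # keep whole cells off the border
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > _MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"could not place {cfg.n_cells} non-overlapping cells of radius {r} "
                f"in a {h}x{w} image within {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        if cy - r <= bg_box and cx - r <= bg_box:  # keep the background ROI staining-free
            continue
        if all((cy - py) ** 2 + (cx - px) ** 2 > (2 * r + 2) ** 2 for py, px in centers):
            centers.append((cy, cx))
    return centers


def simulate_cell_image(config: CellSimConfig) -> tuple[CellImageSet, dict]:
    """Render a synthetic field of cells with exact label masks and truth.

    Channels: ``signal`` (the measured stain) and ``dapi`` (uniform nuclear
    counterstain).  The per-cell truth record stores areas, intensities and
    the exact pre-noise cytoplasmic/nuclear ratio.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    bg_box = max(4 * config.nucleus_radius, 24)
    if bg_box + 2 * (config.cell_radius + 2) >= min(h, w):
        raise ValueError("image too small for background ROI plus cells")
    centers = _place_cells(rng, config, bg_box)

    yy, xx = np.mgrid[0:h, 0:w]
    signal = np.zeros((h, w), dtype=float)
    dapi = np.zeros((h, w), dtype=float)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    per_cell = []
    for k, (cy, cx) in enumerate(centers, start=1):
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell_mask = dist2 <= config.cell_radius**2
        nuc_mask = dist2 <= config.nucleus_radius**2
        cyto_mask = cell_mask & ~nuc_mask
        a_nuc = int(nuc_mask.sum())
        a_cyto = int(cyto_mask.sum())
        i_nuc = config.nuclear_intensity
        # uniform cytoplasmic intensity making the integrated-density ratio exact
        i_cyto = config.true_cn_ratio * i_nuc * a_nuc / a_cyto
        signal[nuc_mask] = i_nuc
        signal[cyto_mask] = i_cyto
        dapi[nuc_mask] = config.dapi_intensity
        cell_labels[cell_mask] = k
        nucleus_labels[nuc_mask] = k
        per_cell.append(
            {
                "cell_id": k,
                "center": [cy, cx],
                "nuclear_area": a_nuc,
                "cyto_area": a_cyto,
                "nuclear_intensity": i_nuc,
                "cyto_intensity": i_cyto,
                "true_cn_ratio": config.true_cn_ratio,
            }
        )

    background_roi = np.zeros((h, w), dtype=bool)
    background_roi[2:bg_box, 2:bg_box] = True

    for img in (signal, dapi):
        img += config.background_level
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=img.shape)
            np.clip(img, 0.0, None, out=img)

    images = CellImageSet(
        channels={"signal": signal, "dapi": dapi},
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        background_roi=background_roi,
    )
    truth = {"config": asdict(config), "cells": per_cell,
             "true_cn_ratio": config.true_cn_ratio}
    return images, truth


def simulate_ratio_pairs(
    n_cells: int, r_target: float, seed: int, log_sd: float = 0.4
) -> tuple[np.ndarray, np.ndarray]:
    """Paired positive per-cell ratio vectors with controlled correlation.

    Draws bivariate standard-normal pairs with population correlation
    ``r_target`` and maps them through exp(log_sd · z) so the ratios stay
    positive.  |r_target| = 1 is degenerate (exactly linear in log space).
    The exp transform attenuates the Pearson correlation of the ratios
    slightly relative to ``r_target`` for 0 < |r| < 1.
    """
    if not (-1.0 <= r_target <= 1.0):
        raise ValueError("r_target must lie in [-1, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_cells)
    if abs(r_target) == 1.0:
        z2 = math.copysign(1.0, r_target) * z1
    else:
        z2 = r_target * z1 + math.sqrt(1.0 - r_target**2) * rng.standard_normal(n_cells)
    return np.exp(log_sd * z1), np.exp(log_sd * z2)


__all__ = [
    "PeakSimConfig",
    "CellSimConfig",
    "PlacementError",
    "simulate_peak_pair",
    "simulate_cell_image",
    "simulate_ratio_pairs",
]
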