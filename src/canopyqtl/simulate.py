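"""Synthetic canopy scenes, founder-mosaic genotypes and phenotypes.

This module generates desk-scale stand-ins for the three data sources
of a UAV phenotyping + MAGIC GWAS study:

* **Canopy scenes** — top-down RGB plot images of 3 x 3 rice plants.
  Each plant is drawn as 8-15 elliptical leaves radiating from its
  centre; a ``spread`` parameter in [0, 1] moves leaf mass outward
  (spreading habit) or keeps it central (closed/upright habit), and a
  global isotropic scale is calibrated by bisection until the rendered
  ground cover matches ``coverage_target``.  Plant pixels are jittered
  around a green (negative a*) colour, background around a soil colour
  (a* near zero), so downstream a*/Otsu segmentation faces a realistic
  but solvable two-class problem.
* **Founder mosaics** — each line x chromosome is a contiguous mosaic
  of the 8 founder labels: founder uniform at the chromosome start,
  breakpoints from a Poisson process in physical position (memoryless,
  expected count = ``breakpoint_rate``), new founder drawn uniformly at
  each breakpoint.
* **Phenotypes** — per environment (year), line value = sum of planted
  per-haplotype QTL effects + independent Gaussian noise; the genetic
  part is shared across environments, mirroring year-stable haplotype
  effects.

Every generator takes an explicit seed and owns its RNG stream; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .haplotypes import HaplotypeMatrix
from .layout import PlotLayout

__all__ = [
    "SimConfig",
    "QTLSpec",
    "CanopyScene",
    "make_snp_map",
    "draw_qtl_effects",
    "gen_canopy_scene",
    "gen_founder_mosaic",
    "gen_phenotypes",
]

# rendering palette: plant jittered around green, background around soil
_PLANT_RGB = np.array([40, 120, 35])
_SOIL_RGB = np.array([110, 95, 80])
_JITTER = 15

# leaf geometry at unit scale (pixels, before spread/coverage scaling)
_LEAF_HALF_LEN = 20.0
_LEAF_HALF_WIDTH = 6.0


@dataclass(frozen=True)
class SimConfig:
    """Population-simulation parameters.

    Defaults follow the study design the generator emulates: 165 inbred
    lines from 8 founders, 12 rice chromosomes, two growing seasons.
    ``breakpoint_rate`` is the expected founder-switch opportunities
    per chromosome per line: an inbred 8-way line accumulates
    crossovers over three funnel meioses plus the selfing generations,
    so with rice chromosomes of roughly 1-1.8 Morgans the plausible
    range is 5-7 breakpoints per chromosome; the default is 6.
    """

    n_lines: int = 165
    n_chroms: int = 12
    n_snps_per_chrom: int = 1134
    breakpoint_rate: float = 6.0
    noise_sd: float = 1.0
    n_environments: int = 2
    seed: int = 0
    chrom_length_bp: int = 30_000_000

    def __post_init__(self) -> None:
        if self.n_lines <= 0 or self.n_chroms <= 0 or self.n_snps_per_chrom <= 0:
            raise ValueError("all counts must be positive")
        if self.breakpoint_rate < 0:
            raise ValueError("breakpoint_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_environments <= 0:
            raise ValueError("n_environments must be positive")


@dataclass(frozen=True)
class QTLSpec:
    """A simulated QTL: SNP index plus one additive effect per founder."""

    snp_index: int
    effects: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.effects) != 8:
            raise ValueError("effects must have exactly 8 entries (one per founder)")


@dataclass
class CanopyScene:
    """A rendered plot image with its ground-truth segmentation."""

    image: np.ndarray
    truth_mask: np.ndarray
    truth_vf: float
    spread: float
    seed: int

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.truth_mask.shape:
            raise ValueError("image and truth_mask must share dimensions")
        realized = float(self.truth_mask.mean())
        if abs(realized - self.truth_vf) > 1e-12:
            raise ValueError("truth_vf must equal the mask's fraction of 1-pixels")


def make_snp_map(cfg: SimConfig) -> pd.DataFrame:
    """Equally spaced SNP positions per chromosome.

    SNP ids are ``c<chrom>_s<index>``; positions are 1-based bp on a
    ``chrom_length_bp`` chromosome, spaced ``L/(n+1)`` apart.
    """
    rows = []
    step = cfg.chrom_length_bp / (cfg.n_snps_per_chrom + 1)
    for ch in range(1, cfg.n_chroms + 1):
        for i in range(cfg.n_snps_per_chrom):
            rows.append((f"c{ch}_s{i}", ch, int(round((i + 1) * step))))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def draw_qtl_effects(seed: int, sd: float = 1.0) -> np.ndarray:
    """Draw a standardized length-8 founder-effect vector.

    Effects are sampled N(0, 1) and rescaled to mean 0 and SD exactly
    ``sd`` across the 8 founders, so that with (near-)uniform founder
    frequencies the QTL contributes a between-line genetic variance of
    ``sd**2`` regardless of the draw.  This is the calibration knob for
    a QTL of controlled heritability: with phenotype noise SD ``s`` the
    QTL explains ``sd^2 / (sd^2 + s^2)`` of the variance.
    """
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, 1.0, 8)
    e = (e - e.mean()) / e.std()
    return e * sd


def _render_mask(
    shape: tuple,
    centres: Sequence[tuple],
    leaves: Sequence[np.ndarray],
    scale: float,
) -> np.ndarray:
    """Union of all leaf ellipses at a global isotropic scale.

    Each leaf row is (angle, half_len, half_width, size_mult); the
    ellipse is anchored with its inner end at the plant centre and its
    major axis pointing along ``angle``, so leaf mass sits at radius
    [0, 2 * half_len * scale] from the plant.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for (cy, cx), plant_leaves in zip(centres, leaves):
        for theta, hl, hw, mult in plant_leaves:
            a = max(scale * mult * hl, 0.5)
            b = max(min(scale * mult * hw, a), 0.5)
            rr, cc = _draw_ellipse(
                cy + a * np.cos(theta),
                cx + a * np.sin(theta),
                a,
                b,
                shape=shape,
                rotation=theta,
            )
            mask[rr, cc] = 1
    return mask


def gen_canopy_scene(
    layout: Optional[PlotLayout] = None,
    coverage_target: float = 0.3,
    spread: float = 0.5,
    seed: int = 0,
    plant_size_jitter: float = 0.1,
) -> CanopyScene:
    """Render one synthetic plot scene at a requested ground cover.

    Parameters
    ----------
    layout
        Plot geometry giving the raster size and the 9 plant centres;
        defaults to the standard 450 x 270 px layout.
    coverage_target
        Desired fraction of plant pixels, in [0, 0.8].  The rendered
        cover is calibrated by bisection on a global leaf scale and is
        guaranteed within +/- 0.03 of the target (typically much
        closer).
    spread
        Architecture dial in [0, 1]: 0 = closed/upright (short leaves,
        mass near the plant centre), 1 = spreading (long leaves, mass
        pushed outward).  Leaf half-length scales with (0.5 + spread).
    plant_size_jitter
        SD of a per-plant log-normal size multiplier (within-line
        variability among the 9 plants).

    Raises
    ------
    ValueError
        If the target is outside [0, 0.8] or cannot be reached for the
        given layout.
    """
    if layout is None:
        layout = PlotLayout()
    if not (0.0 <= coverage_target <= 0.8):
        raise ValueError("coverage_target must lie in [0, 0.8]")
    if not (0.0 <= spread <= 1.0):
        raise ValueError("spread must lie in [0, 1]")
    shape = (layout.plot_height_px, layout.plot_width_px)
    rng = np.random.default_rng(seed)

    # draw all stochastic leaf parameters up front so the bisection
    # below is deterministic and consumes no randomness
    centres = layout.plant_centres_local()
    leaves = []
    for _ in centres:
        n_leaves = int(rng.integers(8, 16))
        mult = float(np.exp(rng.normal(0.0, plant_size_jitter)))
        angles = rng.uniform(0.0, 2.0 * np.pi, n_leaves)
        len_j = rng.uniform(0.8, 1.2, n_leaves)
        wid_j = rng.uniform(0.7, 1.3, n_leaves)
        plant = np.column_stack(
            [
                angles,
                (0.5 + spread) * _LEAF_HALF_LEN * len_j,
                _LEAF_HALF_WIDTH * wid_j,
                np.full(n_leaves, mult),
            ]
        )
        leaves.append(plant)

    if coverage_target == 0.0:
        mask = np.zeros(shape, dtype=np.uint8)
    else:
        lo, hi = 0.0, 6.0
        vf_hi = _render_mask(shape, centres, leaves, hi).mean()
        if vf_hi < coverage_target:
            raise ValueError(
                f"coverage_target {coverage_target} infeasible for this layout "
                f"(max reachable ~{vf_hi:.2f})"
            )
        mask = None
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            cand = _render_mask(shape, centres, leaves, mid)
            vf = cand.mean()
            if abs(vf - coverage_target) <= 0.003:
                mask = cand
                break
            if vf < coverage_target:
                lo = mid
            else:
                hi = mid
        if mask is None:
            cand = _render_mask(shape, centres, leaves, 0.5 * (lo + hi))
            if abs(cand.mean() - coverage_target) > 0.03:
                raise ValueError("coverage calibration failed to converge")
            mask = cand

    # colour the scene: per-pixel uniform jitter around the two palettes
    h, w = shape
    soil = _SOIL_RGB + rng.integers(-_JITTER, _JITTER + 1, (h, w, 3))
    plant = _PLANT_RGB + rng.integers(-_JITTER, _JITTER + 1, (h, w, 3))
    image = np.where(mask[..., None].astype(bool), plant, soil)
    image = np.clip(image, 0, 255).astype(np.uint8)
    return CanopyScene(
        image=image,
        truth_mask=mask,
        truth_vf=float(mask.mean()),
        spread=spread,
        seed=seed,
    )


def gen_founder_mosaic(cfg: SimConfig, snp_map: Optional[pd.DataFrame] = None) -> HaplotypeMatrix:
    """Simulate founder-mosaic genotypes for a MAGIC population.

    Each line x chromosome starts from a founder drawn uniformly from
    the 8; breakpoints are Poisson(``breakpoint_rate``) in number and
    uniform in physical position, and a new founder is drawn uniformly
    at each breakpoint (it may redraw the current one, so the rate of
    *visible* label switches is 7/8 of the breakpoint rate).

    Raises
    ------
    ValueError
        If ``snp_map`` is empty.
    """
    if snp_map is None:
        snp_map = make_snp_map(cfg)
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    rng = np.random.default_rng(cfg.seed)
    values = np.zeros((cfg.n_lines, len(snp_map)), dtype=np.int8)
    chroms = snp_map["chrom"].to_numpy()
    positions = snp_map["pos"].to_numpy()
    for ch in np.unique(chroms):
        cols = np.flatnonzero(chroms == ch)
        pos = positions[cols].astype(float)
        L = float(cfg.chrom_length_bp)
        for i in range(cfg.n_lines):
            n_bp = rng.poisson(cfg.breakpoint_rate)
            founders = rng.integers(1, 9, n_bp + 1)
            if n_bp == 0:
                values[i, cols] = founders[0]
                continue
            breaks = np.sort(rng.uniform(0.0, L, n_bp))
            seg = np.searchsorted(breaks, pos, side="right")
            values[i, cols] = founders[seg]
    line_ids = [f"L{i:04d}" for i in range(cfg.n_lines)]
    return HaplotypeMatrix(values=values, line_ids=line_ids, snp_map=snp_map.reset_index(drop=True))


def gen_phenotypes(
    haplo: HaplotypeMatrix,
    qtls: Sequence[QTLSpec],
    noise_sd: float = 1.0,
    n_environments: int = 2,
    seed: int = 0,
    trait: str = "VF",
    intercept: float = 0.0,
) -> List[pd.DataFrame]:
    """Simulate one phenotype table per environment.

    The genetic value of line *i* is the sum over QTLs of the planted
    effect of its founder label at the QTL SNP, identical in every
    environment; each environment adds its own independent Gaussian
    noise of SD ``noise_sd``.  Lines missing a haplotype label at a QTL
    SNP get a missing phenotype.

    Returns a list of DataFrames (one per environment) with columns
    ``line_id``, ``trait``, ``environment``, ``value``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for q in qtls:
        if not (0 <= q.snp_index < haplo.n_snps):
            raise ValueError(f"QTL snp_index {q.snp_index} out of range")
    rng = np.random.default_rng(seed)
    genetic = np.full(haplo.n_lines, float(intercept))
    for q in qtls:
        labels = haplo.values[:, q.snp_index]
        eff = np.concatenate([[np.nan], np.asarray(q.effects, dtype=float)])
        genetic = genetic + eff[labels]
    tables = []
    for env in range(1, n_environments + 1):
        noise = rng.normal(0.0, noise_sd, haplo.n_lines) if noise_sd > 0 else 0.0
        tables.append(
            pd.DataFrame(
                {
                    "line_id": haplo.line_ids,
                    "trait": trait,
                    "environment": env,
                    "value": genetic + noise,
                }
            )
        )
    return tables
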