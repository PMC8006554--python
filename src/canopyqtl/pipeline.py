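"""End-to-end reproducible pipeline: simulate -> image -> VF/AT -> GWAS.

A :class:`RunConfig` fixes every knob (layout, simulation, segmentation,
AT, GWAS, seed); :func:`run_pipeline` then executes the full flow on
synthetic data and writes per-stage tables, figures and a
machine-readable ``summary.json``.  The summary is a pure function of
the config: two runs with the same config produce byte-identical JSON
(wall-times go to a separate log file).

Flow: founder-mosaic genotypes and QTL-driven latent traits are
simulated for ``n_lines`` lines in ``n_environments`` environments
(years); each line's latent vegetation fraction drives the ground cover
of a rendered canopy scene, and a latent architecture trait drives its
spread.  Scenes are segmented on the a* channel (measured VF), the nine
plant tiles are merged and scored (measured AT), and a Kruskal-Wallis
haplotype scan is run on the measured VF per environment, with peaks,
effect vectors and the cross-year effect correlation reported.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .archery import compute_at, define_regions, merge_tiles
from .gwas import EffectVector, effect_correlation, haplotype_effects, run_gwas, significance_tier
from .haplotypes import HaplotypeMatrix
from .io import layout_to_json, write_phenotypes, write_scene
from .layout import PlotLayout, PlotRegion, extract_plant_tiles
from .simulate import QTLSpec, SimConfig, gen_canopy_scene, gen_founder_mosaic, gen_phenotypes, make_snp_map
from .vegetation import compute_vf, rgb_to_astar, segment_plants

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a pipeline run (JSON-serialisable)."""

    outdir: str = "canopyqtl_run"
    seed: int = 0
    # population
    n_lines: int = 60
    n_chroms: int = 6
    n_snps_per_chrom: int = 100
    breakpoint_rate: float = 6.0
    n_environments: int = 2
    # latent traits: VF in percent, architecture spread in [0, 1]
    vf_intercept: float = 30.0
    vf_noise_sd: float = 3.0
    vf_qtl_snp_index: int = 50
    vf_qtl_effects: Tuple[float, ...] = (-4.0, -3.0, -3.0, -2.0, 2.0, 5.0, 3.0, 2.0)
    spread_intercept: float = 0.5
    spread_noise_sd: float = 0.06
    spread_qtl_snp_index: int = 250
    spread_qtl_effects: Tuple[float, ...] = (0.12, 0.08, 0.10, 0.06, -0.06, -0.12, -0.08, -0.10)
    sdw_per_vf: float = 0.2
    sdw_noise_sd: float = 1.0
    # imaging / segmentation / AT
    plant_size_jitter: float = 0.1
    tile_side: Optional[int] = None
    shape_mode: str = "square-annuli"
    plant_side: str = "low"
    n_example_scenes: int = 4
    # GWAS
    min_groups: int = 3
    min_group_size: int = 2
    min_distance: int = 100
    n_top: int = 8

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "vf_qtl_effects" in d:
            d["vf_qtl_effects"] = tuple(d["vf_qtl_effects"])
        if "spread_qtl_effects" in d:
            d["spread_qtl_effects"] = tuple(d["spread_qtl_effects"])
        return cls(**d)


@dataclass
class RunReport:
    """Outcome of a pipeline run."""

    summary: Dict
    outdir: Path
    summary_path: Path


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _measure_scene(scene, layout: PlotLayout, tile_side: int, regions, plant_side: str):
    """Segment one scene and score it: returns (vf_percent, at)."""
    astar = rgb_to_astar(scene.image)
    mask = segment_plants(astar, plant_side=plant_side)
    vf = compute_vf(mask).vf
    region = PlotRegion(plot_id="scene", image=mask.values, plant_centres=layout.plant_centres_local())
    tiles = extract_plant_tiles(region, tile_side)
    mean_mask = merge_tiles(tiles)
    try:
        at = compute_at(mean_mask, regions).at
    except ValueError:
        at = float("nan")
    return vf, at


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic pipeline described by ``config``."""
    t_start = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    log: List[str] = []

    def stage(name: str, t0: float) -> None:
        log.append(f"{name}: {time.perf_counter() - t0:.2f} s")

    # --- stage 1: genotypes -------------------------------------------------
    t0 = time.perf_counter()
    sim = SimConfig(
        n_lines=config.n_lines,
        n_chroms=config.n_chroms,
        n_snps_per_chrom=config.n_snps_per_chrom,
        breakpoint_rate=config.breakpoint_rate,
        noise_sd=config.vf_noise_sd,
        n_environments=config.n_environments,
        seed=config.seed,
    )
    snp_map = make_snp_map(sim)
    try:
        haplo = gen_founder_mosaic(sim, snp_map)
    except Exception as e:  # pragma: no cover - re-raise with stage context
        raise RuntimeError(f"stage 'genotypes' failed: {e}") from e
    haplo.to_tsv(outdir / "genotypes.tsv", outdir / "map.tsv")
    stage("genotypes", t0)

    # --- stage 2: latent traits --------------------------------------------
    t0 = time.perf_counter()
    vf_tables = gen_phenotypes(
        haplo,
        [QTLSpec(config.vf_qtl_snp_index, config.vf_qtl_effects)],
        noise_sd=config.vf_noise_sd,
        n_environments=config.n_environments,
        seed=config.seed + 1,
        trait="VF_latent",
        intercept=config.vf_intercept,
    )
    spread_tables = gen_phenotypes(
        haplo,
        [QTLSpec(config.spread_qtl_snp_index, config.spread_qtl_effects)],
        noise_sd=config.spread_noise_sd,
        n_environments=config.n_environments,
        seed=config.seed + 2,
        trait="spread_latent",
        intercept=config.spread_intercept,
    )
    stage("latent traits", t0)

    # --- stage 3: imaging + measurement ------------------------------------
    t0 = time.perf_counter()
    layout = PlotLayout()
    tile_side = config.tile_side or layout.default_tile_side()
    regions = define_regions(tile_side, config.shape_mode)
    scenes_dir = outdir / "scenes"
    scenes_dir.mkdir(exist_ok=True)
    rng_sdw = np.random.default_rng([config.seed, 77])
    records = []
    for env in range(1, config.n_environments + 1):
        vf_latent = vf_tables[env - 1]["value"].to_numpy()
        spread_latent = np.clip(spread_tables[env - 1]["value"].to_numpy(), 0.0, 1.0)
        for i, line_id in enumerate(haplo.line_ids):
            coverage = float(np.clip(vf_latent[i] / 100.0, 0.02, 0.75))
            scene_seed = (config.seed * 1_000_003 + env * 100_000 + i) % (2**31)
            scene = gen_canopy_scene(
                layout,
                coverage_target=coverage,
                spread=float(spread_latent[i]),
                seed=scene_seed,
                plant_size_jitter=config.plant_size_jitter,
            )
            vf_meas, at_meas = _measure_scene(scene, layout, tile_side, regions, config.plant_side)
            sdw = config.sdw_per_vf * vf_latent[i] + rng_sdw.normal(0.0, config.sdw_noise_sd)
            records.append((line_id, "VF", env, vf_meas))
            records.append((line_id, "AT", env, at_meas))
            records.append((line_id, "SDW", env, sdw))
            records.append((line_id, "VF_latent", env, float(vf_latent[i])))
            records.append((line_id, "spread_latent", env, float(spread_latent[i])))
            if env == 1 and i < config.n_example_scenes:
                write_scene(scene, scenes_dir / line_id)
    pheno = pd.DataFrame(records, columns=["line_id", "trait", "environment", "value"])
    write_phenotypes(pheno, outdir / "phenotypes.csv")
    layout_to_json(layout, outdir / "layout.json")
    stage("imaging", t0)

    # --- stage 4: GWAS ------------------------------------------------------
    t0 = time.perf_counter()
    peaks_by_env = {}
    effects_by_env: Dict[int, EffectVector] = {}
    results_by_env = {}
    for env in range(1, config.n_environments + 1):
        res = run_gwas(
            haplo, pheno, "VF", env,
            min_groups=config.min_groups, min_group_size=config.min_group_size,
        )
        results_by_env[env] = res
        peaks = res.find_peaks(min_distance=config.min_distance, n_top=config.n_top)
        peaks.to_csv(outdir / f"peaks_env{env}.tsv", sep="\t", index=False)
        res.table.to_csv(outdir / f"gwas_VF_env{env}.tsv", sep="\t", index=False)
        peaks_by_env[env] = peaks
    top_env1 = peaks_by_env[1]
    eff_corr = {"r": float("nan"), "p": float("nan"), "n_used": 0, "snp_id": None}
    if len(top_env1) and config.n_environments >= 2:
        snp = str(top_env1.iloc[0]["snp_id"])
        for env in (1, 2):
            effects_by_env[env] = haplotype_effects(haplo, pheno, snp, "VF", env)
        r, p, n_used = effect_correlation(effects_by_env[1], effects_by_env[2])
        eff_corr = {"r": r, "p": p, "n_used": n_used, "snp_id": snp,
                    "tier": significance_tier(p)}
        eff_df = pd.DataFrame({f"env{e}": v.as_series() for e, v in effects_by_env.items()})
        eff_df.to_csv(outdir / "effects_top_peak.tsv", sep="\t")
    stage("gwas", t0)

    # --- stage 5: trait correlations + figures ------------------------------
    t0 = time.perf_counter()
    wide = pheno[pheno["environment"] == 1].pivot(index="line_id", columns="trait", values="value")
    traits = ["VF", "AT", "SDW"]
    corr = {}
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            sub = wide[[a, b]].dropna()
            if len(sub) >= 3 and sub[a].std() > 0 and sub[b].std() > 0:
                r, p = stats.pearsonr(sub[a], sub[b])
                corr[f"{a}-{b}"] = {"r": float(r), "p": float(p), "n": len(sub),
                                    "tier": significance_tier(float(p))}
    spread_at = wide.join(
        pheno[(pheno["environment"] == 1) & (pheno["trait"] == "spread_latent")]
        .set_index("line_id")["value"].rename("spread"),
    )[["AT", "spread"]].dropna()
    rho_spread_at = float(stats.spearmanr(spread_at["spread"], spread_at["AT"]).statistic)
    vf_err = (wide["VF"] - pheno[(pheno["environment"] == 1) & (pheno["trait"] == "VF_latent")]
              .set_index("line_id")["value"].clip(2.0, 75.0)).abs()

    _make_figures(outdir, wide, results_by_env, effects_by_env, config)
    stage("report", t0)

    summary = {
        "config": dataclasses.asdict(config),
        "n_lines": config.n_lines,
        "n_snps": int(haplo.n_snps),
        "vf_mean_env1": float(wide["VF"].mean()),
        "vf_abs_error_mean": float(vf_err.mean()),
        "at_mean_env1": float(wide["AT"].mean()),
        "spearman_spread_at": rho_spread_at,
        "trait_correlations_env1": corr,
        "peaks": {
            str(env): peaks_by_env[env].to_dict(orient="records")
            for env in peaks_by_env
        },
        "effect_correlation_top_peak": eff_corr,
    }
    summary = _round_floats(summary)
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.append(f"total: {time.perf_counter() - t_start:.2f} s")
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    return RunReport(summary=summary, outdir=outdir, summary_path=summary_path)


def _make_figures(outdir: Path, wide: pd.DataFrame, results_by_env, effects_by_env, config: RunConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3))
    for ax, trait in zip(axes, ["VF", "AT", "SDW"]):
        ax.hist(wide[trait].dropna(), bins=20, color="tab:green")
        ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(outdir / "trait_distributions.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(wide["VF"], wide["SDW"], s=10)
    ax.set_xlabel("VF (%)")
    ax.set_ylabel("SDW")
    fig.tight_layout()
    fig.savefig(outdir / "vf_vs_sdw.png", dpi=100)
    plt.close(fig)

    for env, res in results_by_env.items():
        ax = res.manhattan(min_distance=config.min_distance, n_top=config.n_top)
        ax.figure.tight_layout()
        ax.figure.savefig(outdir / f"manhattan_env{env}.png", dpi=100)
        plt.close(ax.figure)

    if effects_by_env:
        fig, ax = plt.subplots(figsize=(5, 4))
        for env, eff in effects_by_env.items():
            ax.plot(range(1, 9), eff.means, "o-", label=f"env {env}")
        ax.set_xticks(range(1, 9))
        ax.set_xticklabels(["AK", "BE", "TC", "MI", "SU", "TK", "HO", "RU"])
        ax.set_ylabel("mean VF (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "effects_top_peak.png", dpi=100)
        plt.close(fig)
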