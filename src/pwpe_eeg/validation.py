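"""Simulation studies validating pipeline calibration and recovery.

Each driver builds a small synthetic study from scratch, runs the
relevant pipeline stages, and returns the quantities a calibration or
recovery analysis needs: family-wise error under the global null,
recovery of a planted frontocentral sensory-pwPE effect, and ANCOVA
recovery of a symptom-linked amplitude modulation. Problem sizes are
deliberately scaled down from the full study (fewer subjects/trials,
coarser lattice) so that repeated replicates are affordable; the
statistical machinery exercised is identical to the full-size path.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import BetaMap, Grid, build_design, first_level_fit, make_grid, \
    project_epochs, smooth_volumes
from .hgf import filter_sequence
from .inference import ClusterResult, StatMap, cluster_inference
from .preprocess import preprocess_epochs
from .simulate import (CohortSpec, EffectSpec, NoiseSpec, ParadigmSpec,
                       gen_cohort, gen_subject_eeg, gen_tone_sequence,
                       subject_scales)

__all__ = ["null_fwer_study", "make_null_grid", "effect_recovery_run",
           "ancova_recovery_run", "simulate_first_level"]


def make_null_grid(shape: tuple[int, int, int] = (8, 8, 30)) -> Grid:
    """A fully in-mask lattice for direct second-level calibration studies."""
    nx, ny, nt = shape
    return Grid(x=np.arange(nx, dtype=float), y=np.arange(ny, dtype=float),
                times=100.0 + 2.0 * np.arange(nt),
                mask=np.ones((nx, ny), bool),
                weights=np.zeros((nx * ny, 1)), scalp_idx=np.array([0]),
                time_idx=np.arange(nt), voxel=(1.0, 1.0, 2.0))


def _null_betas(rng: np.random.Generator, n_subjects: int,
                grid: Grid) -> list[BetaMap]:
    shape = grid.shape
    return [BetaMap(beta=rng.standard_normal(shape),
                    intercept=np.zeros(shape), resvar=np.ones(shape),
                    df=100, xtx_inv_slope=1.0, grid=grid, regressor="null",
                    subject=f"s{i}") for i in range(n_subjects)]


def null_fwer_study(n_replicates: int = 200, n_subjects: int = 10,
                    shape: tuple[int, int, int] = (8, 8, 30),
                    n_perm: int = 500, alpha: float = 0.05,
                    cdt_p: float = 0.001, seed: int = 0) -> dict:
    """Empirical family-wise error of the sign-flip cluster inference.

    Subject beta maps are i.i.d. standard normal (global null). Returns
    the fraction of replicates in which any cluster (resp. any peak)
    reaches corrected significance at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    grid = make_null_grid(shape)
    any_cluster = 0
    any_peak = 0
    for r in range(n_replicates):
        betas = _null_betas(rng, n_subjects, grid)
        _, clusters = cluster_inference(
            betas, cdt_p=cdt_p, alpha=alpha, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)))
        if any(c.p_cluster_fwe < alpha for c in clusters):
            any_cluster += 1
        if any(c.p_peak_fwe < alpha for c in clusters):
            any_peak += 1
    return {"fwer_cluster": any_cluster / n_replicates,
            "fwer_peak": any_peak / n_replicates,
            "n_replicates": n_replicates}


def simulate_first_level(paradigm: ParadigmSpec, effects: list[EffectSpec],
                         noise: NoiseSpec, regressor: str,
                         subject_scale: float, seed: int,
                         grid: Grid | None = None,
                         voxel: tuple[float, float] = (12.0, 12.0),
                         time_step: float = 8.0,
                         ) -> tuple[BetaMap, Grid]:
    """One subject end to end: tones -> HGF -> EEG -> preprocess -> GLM."""
    seq = gen_tone_sequence(paradigm, seed)
    traj = filter_sequence(seq)
    epochs = gen_subject_eeg(seq, traj, effects, noise,
                             subject_scale=subject_scale, seed=seed + 1,
                             paradigm=paradigm)
    clean = preprocess_epochs(epochs)
    if grid is None:
        grid = make_grid(clean, voxel=voxel, time_step=time_step)
    vols = smooth_volumes(project_epochs(clean, grid), grid)
    design = build_design(traj, clean, regressor)
    return first_level_fit(vols, design, grid), grid


def effect_recovery_run(seed: int, n_subjects: int = 8, n_trials: int = 200,
                        effect: EffectSpec | None = None,
                        noise: NoiseSpec | None = None,
                        n_perm: int = 200, cdt_p: float = 0.001,
                        grid: Grid | None = None,
                        ) -> tuple[StatMap, list[ClusterResult], Grid]:
    """Group recovery of a planted sensory-pwPE effect at default SNR."""
    effect = effect or EffectSpec()
    noise = noise or NoiseSpec()
    paradigm = ParadigmSpec(n_trials=n_trials)
    betas = []
    for s in range(n_subjects):
        bm, grid = simulate_first_level(paradigm, [effect], noise,
                                        effect.regressor, 1.0,
                                        seed=seed * 1000 + s * 7, grid=grid)
        betas.append(bm)
    smap, clusters = cluster_inference(betas, cdt_p=cdt_p, n_perm=n_perm,
                                       seed=seed)
    return smap, clusters, grid


def ancova_recovery_run(seed: int, n_chr: int = 31, n_trials: int = 200,
                        effect: EffectSpec | None = None,
                        noise: NoiseSpec | None = None,
                        effect_link: float = 0.5, n_perm: int = 200,
                        cdt_p: float = 0.001, grid: Grid | None = None,
                        exclude_top: int = 0,
                        ) -> tuple[StatMap, list[ClusterResult], np.ndarray,
                                   Grid]:
    """ANCOVA recovery of a SIPS-linked effect-amplitude modulation.

    Subject effect amplitude scales as 1 + effect_link * z(SIPS
    positive); the ANCOVA F map of beta on the SIPS score should
    recover a significant positive slope at the planted cluster.
    ``exclude_top`` drops that many highest-scoring subjects before the
    test (the converter-exclusion harness).
    """
    effect = effect or EffectSpec()
    noise = noise or NoiseSpec()
    paradigm = ParadigmSpec(n_trials=n_trials)
    cohort_spec = CohortSpec(n_hc=1, n_chr=n_chr, effect_link=effect_link)
    cohort = gen_cohort(cohort_spec, seed)
    chr_rows = cohort[cohort["group"] == "CHR"].reset_index(drop=True)
    scales = subject_scales(cohort, cohort_spec)[
        (cohort["group"] == "CHR").to_numpy()]
    sips = chr_rows["sips_positive"].to_numpy(float)
    if exclude_top:
        keep = np.argsort(-sips)[exclude_top:]
        chr_rows = chr_rows.iloc[keep].reset_index(drop=True)
        scales, sips = scales[keep], sips[keep]
    betas = []
    for s in range(len(chr_rows)):
        bm, grid = simulate_first_level(paradigm, [effect], noise,
                                        effect.regressor, float(scales[s]),
                                        seed=seed * 1000 + s * 11, grid=grid)
        betas.append(bm)
    smap, clusters = cluster_inference(betas, covariate=sips, cdt_p=cdt_p,
                                       n_perm=n_perm, seed=seed)
    return smap, clusters, sips, grid
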