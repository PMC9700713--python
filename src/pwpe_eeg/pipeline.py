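"""End-to-end orchestration: simulate -> HGF -> preprocess -> GLM -> group.

A single config (YAML/JSON or :class:`PipelineConfig`) drives all
stages. Every run emits a manifest with the config hash, per-file
digests and seeds, sufficient to re-run identically; one master seed
deterministically derives all per-subject and per-permutation seeds.
"""
from __future__ import annotations

import dataclasses
import hashlib
import zlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigurationError
from .containers import EpochSet, ToneSequence
from .glm import (BetaMap, Grid, build_design, first_level_fit_multi,
                  make_grid)
from .hgf import HGFParams, PriorConfig, filter_sequence, fit_bayes_optimal
from .inference import (StatMap, classic_mmn, cluster_inference,
                        group_difference, max_intensity_projection,
                        quantile_split_erp)
from .preprocess import preprocess_epochs, rejection_log
from .simulate import (CohortSpec, EffectSpec, NoiseSpec, ParadigmSpec,
                       gen_cohort, gen_subject_eeg, gen_tone_sequence,
                       subject_scales)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "derive_seed", "cmd_simulate",
           "cmd_run", "cmd_report"]


def derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and index path."""
    return int(np.random.SeedSequence([int(master), *map(int, key)])
               .generate_state(1)[0] % (2 ** 31))


def _from_mapping(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) and \
                f.name in ("epoch_window", "window", "channels", "voxel",
                           "fwhm", "sips_positive", "sips_negative",
                           "sips_disorganised", "sips_general", "age_hc",
                           "age_chr") else v
    return cls(**kwargs)


@dataclass
class HGFConfig:
    fit: bool = True
    kappa: float = 1.0
    omega2: float = -3.0
    omega3: float = -6.0
    prior_omega2_mean: float = -3.0
    prior_omega2_var: float = 16.0
    prior_omega3_mean: float = -6.0
    prior_omega3_var: float = 16.0

    def params(self) -> HGFParams:
        return HGFParams(kappa=self.kappa, omega2=self.omega2,
                         omega3=self.omega3)

    def prior(self) -> PriorConfig:
        return PriorConfig(self.prior_omega2_mean, self.prior_omega2_var,
                           self.prior_omega3_mean, self.prior_omega3_var)


@dataclass
class PreprocessConfig:
    amplitude_threshold: float = 100.0
    eog_threshold: float = 250.0
    max_channel_fraction: float = 0.20


@dataclass
class GLMConfig:
    regressors: tuple[str, ...] = ("epsilon2", "epsilon3")
    voxel: tuple[float, float] = (4.25, 5.38)
    window: tuple[float, float] = (100.0, 400.0)
    time_step: float | None = None
    fwhm: tuple[float, float] = (16.0, 16.0)
    zscore: bool = True
    rectify: bool = False


@dataclass
class InferenceConfig:
    cdt_p: float = 0.001
    alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 6
    ancova_regressors: tuple[str, ...] = ("epsilon2",)
    converter_exclusion_n: int = 3


@dataclass
class PipelineConfig:
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: list[EffectSpec] = field(default_factory=lambda: [EffectSpec()])
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hgf: HGFConfig = field(default_factory=HGFConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    glm: GLMConfig = field(default_factory=GLMConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        sub = {"paradigm": ParadigmSpec, "cohort": CohortSpec,
               "noise": NoiseSpec, "hgf": HGFConfig,
               "preprocess": PreprocessConfig, "glm": GLMConfig,
               "inference": InferenceConfig}
        kwargs = {}
        for key, val in data.items():
            if key in sub:
                kwargs[key] = _from_mapping(sub[key], val)
            elif key == "effects":
                kwargs[key] = [_from_mapping(EffectSpec, e) for e in val]
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: conv(getattr(o, f.name)) for f in fields(o)
                        if f.name != "channels"}
            if isinstance(o, (tuple, list)):
                return [conv(x) for x in o]
            if isinstance(o, np.generic):
                return o.item()
            return o
        return conv(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, config: PipelineConfig, files: list[Path],
                    warnings: list[str]) -> Path:
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "files": {str(p.relative_to(out)): _file_digest(p)
                  for p in sorted(files)},
        "warnings": warnings,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------- #
# simulate

def cmd_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write the synthetic study to disk: cohort TSV, tones, epochs, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = gen_cohort(config.cohort, derive_seed(config.seed, 0))
    scales = subject_scales(cohort, config.cohort)
    cohort_path = out / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)
    files = [cohort_path]
    truth = {"effects": [dataclasses.asdict(e) for e in config.effects],
             "subject_scale": {}, "blink_trials": {}}
    for i, row in cohort.iterrows():
        sid = row["subject"]
        seq = gen_tone_sequence(config.paradigm, derive_seed(config.seed, 1, i))
        traj = filter_sequence(seq, config.hgf.params())
        epochs = gen_subject_eeg(seq, traj, config.effects, config.noise,
                                 subject_scale=float(scales[i]),
                                 seed=derive_seed(config.seed, 2, i),
                                 paradigm=config.paradigm)
        tone_path = out / f"tones_{sid}.tsv"
        seq.to_tsv(tone_path)
        epoch_path = out / f"epochs_{sid}.h5"
        epochs.save_h5(epoch_path)
        files += [tone_path, epoch_path]
        truth["subject_scale"][sid] = float(scales[i])
        truth["blink_trials"][sid] = epochs.meta["blink_trials"]
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    files.append(truth_path)
    _write_manifest(out, config, files, warnings=[])
    return out


# ---------------------------------------------------------------------- #
# run

def _save_statmap(smap: StatMap, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for key, arr in (("values", smap.values), ("x", smap.grid.x),
                         ("y", smap.grid.y), ("times", smap.grid.times),
                         ("mask", smap.grid.mask)):
            f.create_dataset(key, data=arr, track_times=False)
        if smap.slope is not None:
            f.create_dataset("slope", data=smap.slope, track_times=False)
        f.attrs.update({"kind": smap.kind, "df1": smap.df[0],
                        "df2": smap.df[1], "contrast": smap.contrast,
                        "provenance": smap.provenance})


def _cluster_table(clusters) -> pd.DataFrame:
    cols = ["cluster", "extent", "peak_F", "peak_x_mm", "peak_y_mm",
            "peak_t_ms", "p_cluster_FWE", "p_peak_FWE", "window_start_ms",
            "window_end_ms"]
    if not clusters:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([c.to_row() for c in clusters])[cols]


def first_level_pipeline(epochs: EpochSet, traj, config: PipelineConfig,
                         grid: Grid | None = None, subject: str = ""
                         ) -> tuple[dict[str, BetaMap], Grid, EpochSet]:
    """Preprocess one subject's epochs and fit one GLM per regressor."""
    pp = config.preprocess
    clean = preprocess_epochs(epochs, pp.amplitude_threshold,
                              pp.eog_threshold, pp.max_channel_fraction)
    if grid is None:
        grid = make_grid(clean, voxel=config.glm.voxel,
                         window=config.glm.window,
                         time_step=config.glm.time_step)
    designs = {reg: build_design(traj, clean, reg, zscore=config.glm.zscore,
                                 rectify=config.glm.rectify)
               for reg in config.glm.regressors}
    betas = first_level_fit_multi(clean, designs, grid, fwhm=config.glm.fwhm,
                                  subject=subject)
    return betas, grid, clean


def cmd_run(config: PipelineConfig, fixtures_dir: str | Path,
            out_dir: str | Path) -> Path:
    """Execute hgf -> preprocess -> first-level -> group on a fixture set."""
    fixtures = Path(fixtures_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(fixtures / "cohort.tsv", sep="\t")
    files: list[Path] = []
    warnings: list[str] = []

    grid: Grid | None = None
    betas: dict[str, dict[str, BetaMap]] = {r: {} for r in
                                            config.glm.regressors}
    retained = {}
    for _, row in cohort.iterrows():
        sid = row["subject"]
        seq = ToneSequence.from_tsv(fixtures / f"tones_{sid}.tsv")
        if config.hgf.fit:
            params, diag = fit_bayes_optimal(seq, config.hgf.prior(),
                                             config.hgf.params())
        else:
            params, diag = config.hgf.params(), {"fit": "disabled"}
        traj = filter_sequence(seq, params)
        traj_path = out / f"trajectories_{sid}.tsv"
        traj.to_tsv(traj_path)
        files.append(traj_path)
        (out / f"hgf_{sid}.json").write_text(json.dumps(
            {"params": dataclasses.asdict(params), "diagnostics": diag},
            indent=2))
        files.append(out / f"hgf_{sid}.json")
        epochs = EpochSet.load_h5(fixtures / f"epochs_{sid}.h5")
        try:
            sub_betas, grid, clean = first_level_pipeline(
                epochs, traj, config, grid, subject=sid)
        except Exception as err:
            raise type(err)(f"subject {sid}, first-level stage: {err}") \
                from err
        retained[sid] = int(clean.kept.sum())
        log_path = out / f"rejection_{sid}.tsv"
        rejection_log(clean, log_path)
        files.append(log_path)
        for reg, bm in sub_betas.items():
            betas[reg][sid] = bm

    inf = config.inference
    groups = {g: cohort.loc[cohort["group"] == g, "subject"].tolist()
              for g in ("HC", "CHR")}
    for reg in config.glm.regressors:
        for gname, sids in groups.items():
            if len(sids) < 3:
                continue
            stack = [betas[reg][s] for s in sids]
            smap, clusters = cluster_inference(
                stack, cdt_p=inf.cdt_p, alpha=inf.alpha, n_perm=inf.n_perm,
                seed=derive_seed(config.seed, 3, zlib.crc32(reg.encode()) % 1000,
                                 0 if gname == "HC" else 1),
                connectivity=inf.connectivity)
            tbl = out / f"clusters_{gname}_{reg}.tsv"
            _cluster_table(clusters).to_csv(tbl, sep="\t", index=False)
            mp = out / f"statmap_{gname}_{reg}.h5"
            _save_statmap(smap, mp)
            files += [tbl, mp]
        if len(groups["HC"]) >= 2 and len(groups["CHR"]) >= 2:
            diff = group_difference([betas[reg][s] for s in groups["CHR"]],
                                    [betas[reg][s] for s in groups["HC"]])
            warnings.append(diff.provenance)
            mp = out / f"statmap_diff_{reg}.h5"
            _save_statmap(diff, mp)
            files.append(mp)

    # ANCOVA of CHR betas against SIPS positive totals
    chr_rows = cohort[cohort["group"] == "CHR"]
    if len(chr_rows) >= 5:
        sips = chr_rows["sips_positive"].to_numpy(float)
        for reg in inf.ancova_regressors:
            if reg not in betas:
                continue
            stack = [betas[reg][s] for s in chr_rows["subject"]]
            smap, clusters = cluster_inference(
                stack, covariate=sips, cdt_p=inf.cdt_p, alpha=inf.alpha,
                n_perm=inf.n_perm,
                seed=derive_seed(config.seed, 4, zlib.crc32(reg.encode()) % 1000),
                connectivity=inf.connectivity)
            tbl = out / f"clusters_ancova_{reg}.tsv"
            _cluster_table(clusters).to_csv(tbl, sep="\t", index=False)
            _save_statmap(smap, out / f"statmap_ancova_{reg}.h5")
            files += [tbl, out / f"statmap_ancova_{reg}.h5"]
            # converter-exclusion harness: drop the highest-covariate subjects
            k = inf.converter_exclusion_n
            if len(stack) - k >= 5:
                keep = np.argsort(-sips)[k:]
                _, cl_excl = cluster_inference(
                    [stack[i] for i in keep], covariate=sips[keep],
                    cdt_p=inf.cdt_p, alpha=inf.alpha, n_perm=inf.n_perm,
                    seed=derive_seed(config.seed, 5, zlib.crc32(reg.encode()) % 1000),
                    connectivity=inf.connectivity)
                tbl = out / f"clusters_ancova_{reg}_excl{k}.tsv"
                _cluster_table(cl_excl).to_csv(tbl, sep="\t", index=False)
                files.append(tbl)

    summary = {"retained_trials": retained,
               "mean_retained": float(np.mean(list(retained.values())))}
    (out / "retention.json").write_text(json.dumps(summary, indent=2,
                                                   sort_keys=True))
    files.append(out / "retention.json")
    _write_manifest(out, config, files, warnings)
    return out


# ---------------------------------------------------------------------- #
# report

def cmd_report(results_dir: str | Path, out_dir: str | Path | None = None,
               fixtures_dir: str | Path | None = None) -> Path:
    """Render MIP PNGs and a markdown summary from a results directory."""
    import h5py
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = Path(results_dir)
    out = Path(out_dir) if out_dir else results / "report"
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Pipeline report", ""]
    missing = []
    if not (results / "manifest.json").exists():
        missing.append("manifest.json")
    for table in sorted(results.glob("clusters_*.tsv")):
        name = table.stem.replace("clusters_", "")
        df = pd.read_csv(table, sep="\t")
        lines.append(f"## {name}")
        sig = df[df["p_cluster_FWE"] < 0.05] if len(df) else df
        if len(sig) == 0:
            lines.append("no significant clusters")
        else:
            for _, r in sig.iterrows():
                lines.append(
                    f"- cluster {int(r['cluster'])}: extent {int(r['extent'])}"
                    f", peak F = {r['peak_F']:.1f} at {r['peak_t_ms']:.0f} ms"
                    f", window {r['window_start_ms']:.0f}-"
                    f"{r['window_end_ms']:.0f} ms"
                    f", p_FWE(cluster) = {r['p_cluster_FWE']:.4f}")
        lines.append("")
        map_path = results / f"statmap_{name}.h5"
        if map_path.exists():
            with h5py.File(map_path, "r") as f:
                values = f["values"][()]
                times = f["times"][()]
                y = f["y"][()]
            mip = values.max(axis=0)  # collapse left-right
            fig, ax = plt.subplots(figsize=(6, 3))
            im = ax.imshow(mip, aspect="auto", origin="lower",
                           extent=[times[0], times[-1], y[0], y[-1]],
                           cmap="jet")
            ax.set_xlabel("peristimulus time (ms)")
            ax.set_ylabel("posterior - anterior (mm)")
            ax.set_title(f"MIP {name}")
            fig.colorbar(im, ax=ax, label="F")
            fig.tight_layout()
            fig.savefig(out / f"mip_{name}.png", dpi=100)
            plt.close(fig)
            lines.append(f"![MIP]({out.name}/mip_{name}.png)")
            lines.append("")
    if fixtures_dir is not None:
        lines += _erp_summaries(Path(fixtures_dir), results, out)
    if missing:
        lines.append("## Missing inputs")
        lines += [f"- {m}" for m in missing]
    (out / "summary.md").write_text("\n".join(lines))
    return out


def _erp_summaries(fixtures: Path, results: Path, out: Path) -> list[str]:
    """Classic MMN and 15% quantile-split ERP figures for one subject."""
    import matplotlib.pyplot as plt

    epoch_files = sorted(fixtures.glob("epochs_*.h5"))
    if not epoch_files:
        return ["## ERP summaries", "no epoch fixtures found", ""]
    sid = epoch_files[0].stem.replace("epochs_", "")
    epochs = preprocess_epochs(EpochSet.load_h5(epoch_files[0]))
    lines = ["## ERP summaries", f"subject {sid}"]
    try:
        ci = epochs.channels.index("Fz")
    except ValueError:
        ci = 0
    mmn = classic_mmn(epochs)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharex=True)
    axes[0].plot(epochs.times, mmn[ci])
    axes[0].axhline(0, color="k", lw=0.5)
    axes[0].set_title(f"classic MMN (standard - deviant), "
                      f"{epochs.channels.names[ci]}")
    axes[0].set_xlabel("time (ms)")
    axes[0].set_ylabel("uV")
    traj_path = results / f"trajectories_{sid}.tsv"
    if traj_path.exists():
        reg = pd.read_csv(traj_path, sep="\t")["epsilon2"].to_numpy()
        high, low, times = quantile_split_erp(epochs, reg[epochs.kept],
                                              q=0.15)
        axes[1].plot(times, high[ci], label="top 15% eps2")
        axes[1].plot(times, low[ci], label="bottom 15% eps2")
        axes[1].legend(fontsize=7)
        axes[1].set_title("quantile-split ERP")
        axes[1].set_xlabel("time (ms)")
    fig.tight_layout()
    fig.savefig(out / f"erp_{sid}.png", dpi=100)
    plt.close(fig)
    lines += [f"![ERP]({out.name}/erp_{sid}.png)", ""]
    return lines
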