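"""End-to-end orchestration: simulate -> fit -> group statistics -> figures.

Each stage writes plain CSV tables (and optional PNG figures) under the
configured output directory; a manifest records the master seed, the
config hash and a digest over all written files, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import group_stats, io, psychometrics, stimuli, synthetic
from .config import PipelineConfig
from .hrf import CONDITIONS, FitConfig, fit_joint_hrf, normalize_peaks

__all__ = ["run_pipeline", "fit_cohort", "bundle_digest"]


def _log(config: PipelineConfig, msg: str) -> None:
    if config.verbosity > 0:
        print(f"[chromasupp] {msg}")


def fit_cohort(timecourses: pd.DataFrame, n_starts: int = 5,
               base_seed: int = 0) -> dict:
    """Joint HRF fit for every (subject, area) group of a tidy table.

    Fit seeds are derived deterministically from `base_seed` and the group
    index, so the whole cohort fit is reproducible.
    """
    blocks = io.timecourses_to_blocks(timecourses)
    fits = {}
    for i, (key, conds) in enumerate(sorted(blocks.items())):
        cfg = FitConfig(n_starts=n_starts, seed=base_seed + i)
        fits[key] = fit_joint_hrf(conds, cfg)
    return fits


def _anova_outputs(values: pd.DataFrame, out_dir: Path, stem: str) -> dict:
    """RM-ANOVA + Tukey HSD on a tidy (subject, condition, value) frame."""
    anova = group_stats.rm_anova_oneway(values)
    tukey = group_stats.tukey_hsd(values, anova)
    anova.to_frame().to_csv(out_dir / f"{stem}_anova.csv", index=False)
    pd.DataFrame([
        {"condition_a": c.pair[0], "condition_b": c.pair[1],
         "mean_difference": c.mean_difference, "q": c.q,
         "p_adjusted": c.p_adjusted}
        for c in tukey
    ]).to_csv(out_dir / f"{stem}_tukey.csv", index=False)
    return {"anova": anova, "tukey": tukey}


def _run_fmri(config: PipelineConfig, out_dir: Path) -> dict:
    experiment = "control" if config.experiment == "fmri-control" else "main"
    rng = np.random.default_rng(config.seed)
    sim_seed = int(rng.integers(2**31))
    fit_seed = int(rng.integers(2**31))

    _log(config, f"simulating {config.n_subjects}-subject {experiment} cohort "
                 f"(seed {sim_seed})")
    timecourses, truth = synthetic.study_bold_cohort(
        sim_seed, n_subjects=config.n_subjects, experiment=experiment)
    io.write_timecourses(timecourses, out_dir / "timecourses.csv")
    truth.to_csv(out_dir / "true_peaks.csv", index=False)

    _log(config, f"fitting joint HRF model ({config.hrf_fit_starts} starts/fit)")
    fits = fit_cohort(timecourses, n_starts=config.hrf_fit_starts,
                      base_seed=fit_seed)
    for (subject, area), fit in fits.items():
        io.write_fit_report(io.fit_report(subject, area, fit),
                            out_dir / f"fit_{subject}_{area.replace('/', '')}.json")
    peaks = io.peaks_frame(fits)
    peaks.to_csv(out_dir / "peaks.csv", index=False)

    normalized = []
    for (subject, area), fit in fits.items():
        norm = normalize_peaks(fit.peaks)
        for c, v in norm.items():
            normalized.append({"subject": subject, "area": area,
                               "condition": c, "value": v})
    norm_df = pd.DataFrame(normalized)
    norm_df.to_csv(out_dir / "normalized_peaks.csv", index=False)

    values = peaks.rename(columns={"peak": "value"})[
        ["subject", "condition", "value"]]
    stats = _anova_outputs(values, out_dir, "peaks")

    if config.make_figures:
        _figures_fmri(norm_df, peaks, out_dir)

    cond_means = norm_df.groupby("condition")["value"].mean()
    _log(config, "normalized peak means: "
         + ", ".join(f"{c} {cond_means[c]:+.3f}" for c in CONDITIONS))
    _log(config, f"ANOVA F({stats['anova'].df_cond},{stats['anova'].df_resid}) "
                 f"= {stats['anova'].f_value:.3f}, p = {stats['anova'].p_value:.4f}")
    return {"fits": fits, "peaks": peaks, "normalized": norm_df, **stats}


def _run_psycho(config: PipelineConfig, out_dir: Path) -> dict:
    rng = np.random.default_rng(config.seed)
    sim_seed = int(rng.integers(2**31))
    n = max(config.n_subjects, 3)
    _log(config, f"simulating {n}-observer 2AFC cohort (seed {sim_seed})")
    trials = synthetic.study_2afc_cohort(sim_seed, n_subjects=n)
    io.write_trials(trials, out_dir / "trials.csv")

    rows = []
    for subject, sub_trials in trials.groupby("subject"):
        rates = psychometrics.aggregate_rates(sub_trials)
        for chroma, table in rates.groupby("chroma"):
            fit = psychometrics.fit_psychometric(
                table, method=config.psychometric_method)
            rows.append({"subject": subject, "chroma": chroma,
                         "mu": fit.mu, "sigma": fit.sigma,
                         "method": fit.method, "n_trials": fit.n_trials,
                         "flags": ";".join(fit.flags)})
    sigmas = pd.DataFrame(rows)
    sigmas.to_csv(out_dir / "sigmas.csv", index=False)

    mean_sigma = sigmas.groupby("subject")["sigma"].mean().to_dict()
    exclusion = psychometrics.exclude_subjects(mean_sigma)
    (out_dir / "exclusion.json").write_text(json.dumps({
        "rule": "mean sigma over conditions > 3 x cohort median",
        "threshold": exclusion.threshold,
        "retained": exclusion.retained,
        "excluded": exclusion.excluded,
        "margins": exclusion.margins,
    }, indent=1, sort_keys=True))
    _log(config, f"excluded observers: {exclusion.excluded or 'none'}")

    retained = sigmas[sigmas["subject"].isin(exclusion.retained)]
    values = retained.rename(columns={"chroma": "condition",
                                      "sigma": "value"})[
        ["subject", "condition", "value"]]
    stats = _anova_outputs(values, out_dir, "sigma")

    if config.make_figures:
        _figures_psycho(retained, out_dir)

    cond_means = retained.groupby("chroma")["sigma"].mean()
    _log(config, "mean sigma: "
         + ", ".join(f"{c} {cond_means[c]:.4f}" for c in CONDITIONS))
    _log(config, f"ANOVA F({stats['anova'].df_cond},{stats['anova'].df_resid}) "
                 f"= {stats['anova'].f_value:.3f}, p = {stats['anova'].p_value:.4f}")
    return {"sigmas": sigmas, "exclusion": exclusion, **stats}


def _run_stimuli(config: PipelineConfig, out_dir: Path) -> None:
    """Render one example stimulus set for the configured experiment."""
    rng = np.random.default_rng(config.seed)
    seed = int(rng.integers(2**31))
    if config.experiment == "psycho":
        img = stimuli.render_grating(stimuli.GratingSpec(), seed=seed)
        stimuli.save_stimulus(img, out_dir / "grating_reference")
        mask = stimuli.render_texture(stimuli.TextureSpec.psycho_mask(), seed,
                                      geometry=stimuli.PSYCHO_DISPLAY)
        stimuli.save_stimulus(mask, out_dir / "mask")
    else:
        background = ("black" if config.experiment == "fmri-control"
                      else "texture")
        spec = stimuli.PatchPatternSpec(chroma_condition="/6",
                                        background=background)
        img = stimuli.render_patch_pattern(spec, seed)
        stimuli.save_stimulus(img, out_dir / "patch_pattern")
        mode = "patches_only" if background == "black" else "full"
        stimuli.save_stimulus(stimuli.scramble(img, seed + 1, mode=mode),
                              out_dir / "scrambled")


def _figures_fmri(norm_df, peaks, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = norm_df.groupby("condition")["value"].mean().reindex(CONDITIONS)
    sems = (norm_df.groupby("condition")["value"].std(ddof=1)
            / np.sqrt(norm_df.groupby("condition")["value"].size())
            ).reindex(CONDITIONS)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(CONDITIONS, means, yerr=sems, capsize=3, color="0.6")
    ax.set_ylabel("normalized peak (% signal change)")
    ax.set_xlabel("Chroma condition")
    fig.tight_layout()
    fig.savefig(out_dir / "normalized_peaks.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(peaks.drop_duplicates(["subject", "area"])["ev"], bins=20,
            color="0.6")
    ax.set_xlabel("error value (EV)")
    ax.set_ylabel("fits")
    fig.tight_layout()
    fig.savefig(out_dir / "ev_histogram.png", dpi=120)
    plt.close(fig)


def _figures_psycho(sigmas, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = sigmas.groupby("chroma")["sigma"].mean().reindex(CONDITIONS)
    sems = (sigmas.groupby("chroma")["sigma"].std(ddof=1)
            / np.sqrt(sigmas.groupby("chroma")["sigma"].size())
            ).reindex(CONDITIONS)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(CONDITIONS, means, yerr=sems, capsize=3, color="0.6")
    ax.set_ylabel("psychometric sigma (contrast units)")
    ax.set_xlabel("Chroma condition")
    fig.tight_layout()
    fig.savefig(out_dir / "sigma_means.png", dpi=120)
    plt.close(fig)


def bundle_digest(out_dir) -> str:
    """sha256 over all files of a result bundle (sorted relative paths)."""
    out_dir = Path(out_dir)
    digest = hashlib.sha256()
    for path in sorted(p for p in out_dir.rglob("*") if p.is_file()
                       and p.name != "manifest.json"):
        digest.update(str(path.relative_to(out_dir)).encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured experiment end to end.

    Stages: render example stimuli, simulate the cohort, fit, run group
    statistics, write figures and a manifest.  Output files are a pure
    function of the config (including the master seed); a failed stage
    raises with the stage name while earlier outputs remain on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    stages = [("stimuli", _run_stimuli)]
    if config.experiment in ("fmri-main", "fmri-control"):
        stages.append(("fmri", _run_fmri))
    else:
        stages.append(("psycho", _run_psycho))
    for name, stage in stages:
        try:
            out = stage(config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if out:
            results[name] = out

    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "defaults_used": {
            "ev_denominator_clamp": 1e-3,
            "peak_definition": "dense-grid max of full fitted curve, drift included",
            "peak_normalization": "subtract four-condition mean",
            "psychometric_method": config.psychometric_method,
            "exclusion_rule": "mean sigma > 3 x cohort median",
        },
        "bundle_digest": bundle_digest(out_dir),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    _log(config, f"bundle digest {manifest['bundle_digest'][:16]} "
                 f"written to {out_dir}")
    results["manifest"] = manifest
    return results
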