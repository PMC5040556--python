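"""End-to-end orchestration: simulate -> preprocess -> map -> consistency ->
similarity -> single-case statistics, with seeded substreams and provenance.

Every source of randomness is derived from one master seed via named
substreams, so a fixed configuration reproduces every simulation and
bootstrap bit for bit.
"""

from __future__ import annotations

import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .case_stats import crawford_howell_t, jzs_bayes_factor
from .config import PipelineConfig
from .consistency import different_digit_null, split_half_dice
from .hrf import HRFParams
from .paradigm import (
    make_block_schedule,
    make_travelling_wave_schedule,
    write_events,
)
from .preprocess import gaussian_smooth, highpass_filter
from .similarity import (
    compare_to_controls,
    mean_overlap,
    pattern_component_similarity,
    stack_runs,
)
from .synthetic import (
    GroundTruthMap,
    NoiseModel,
    PatternGroundTruth,
    make_digit_strip,
    pair_correlated_second_moment,
    simulate_block_patterns,
    simulate_run,
    write_ground_truth,
)
from .travelling_wave import (
    build_reference_models,
    gradient_map,
    map_digits,
)
from .volume import Volume4D, save_int_volume, save_volume

__all__ = ["derive_seed", "run_pipeline", "make_fixtures", "simulate_subject_runs"]


def derive_seed(master: int, label: str) -> int:
    """Deterministic per-stage substream seed from the master seed."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(label.encode())])
        .generate_state(1)[0]
    )


def _hrf(config: PipelineConfig) -> HRFParams:
    return HRFParams(
        peak_delay=config.hrf_peak_delay, dispersion=config.hrf_dispersion
    )


def _noise(config: PipelineConfig, seed: int) -> NoiseModel:
    return NoiseModel(
        sigma=config.noise_sigma,
        drift_amplitude=config.drift_amplitude,
        drift_period=config.drift_period_s,
        ar_coefficient=config.ar_coefficient,
        seed=seed,
    )


def simulate_subject_runs(
    config: PipelineConfig, truth: GroundTruthMap, seed_label: str = "tw-runs"
) -> list[tuple[Volume4D, str]]:
    """Two forward + two backward travelling-wave runs for one subject."""
    runs = []
    for k, direction in enumerate(["forward", "backward", "forward", "backward"]):
        sched = make_travelling_wave_schedule(
            direction,
            config.n_digits,
            config.block_duration,
            config.n_cycles,
            config.lead_in,
        )
        seed = derive_seed(config.seed, f"{seed_label}-{k}")
        vol = simulate_run(
            sched, truth, _hrf(config), config.tr, _noise(config, seed)
        )
        runs.append((vol, direction))
    return runs


def preprocess_runs(
    runs: list[tuple[Volume4D, str]], config: PipelineConfig
) -> list[tuple[Volume4D, str]]:
    out = []
    for vol, direction in runs:
        vol = gaussian_smooth(vol, config.smoothing_fwhm_mm, config.voxel_size_mm)
        vol = highpass_filter(vol, config.highpass_cutoff_s)
        out.append((vol, direction))
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full synthetic-subject analysis; returns the report dict.

    Writes winner/gradient maps (NIfTI), the Dice and similarity matrices
    (TSV), a JSON report and a provenance log under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"{time.strftime('%Y-%m-%dT%H:%M:%S')} somatomap {__version__} "
        f"config_hash={config.config_hash()} seed={config.seed}"
    ]

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} [{stage}] {msg}")

    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "preset": config.preset,
    }

    try:
        # --- simulate -----------------------------------------------------
        truth = make_digit_strip(
            config.grid_shape,
            config.n_digits,
            config.strip_axis,
            config.band_width_voxels,
            config.amplitude,
            config.tuning_width,
        )
        write_ground_truth(truth, out / "ground_truth")
        runs = simulate_subject_runs(config, truth)
        sched = make_travelling_wave_schedule(
            "forward",
            config.n_digits,
            config.block_duration,
            config.n_cycles,
            config.lead_in,
        )
        write_events(sched, out / "events_forward.tsv")
        log("simulate", f"{len(runs)} runs, grid {config.grid_shape}")

        # --- preprocess ---------------------------------------------------
        runs = preprocess_runs(runs, config)
        log(
            "preprocess",
            f"fwhm={config.smoothing_fwhm_mm}mm cutoff={config.highpass_cutoff_s}s",
        )

        # --- map ----------------------------------------------------------
        n_volumes = runs[0][0].n_volumes
        bank = build_reference_models(
            config.tr,
            config.cycle_duration,
            config.n_cycles,
            config.block_duration,
            _hrf(config),
            config.lead_in,
            n_volumes=n_volumes,
        )
        dpm, profile = map_digits(runs, bank, config.n_digits, q=config.fdr_q)
        save_int_volume(dpm.winner, out / "winner_map.nii.gz")
        save_int_volume(gradient_map(profile).winning_lag, out / "gradient_map.nii.gz")
        responsive = truth.responsive
        correct = (dpm.winner == truth.preferred_digit) & responsive
        report["map"] = {
            "n_lags": bank.n_lags,
            "n_assigned": int((dpm.winner > 0).sum()),
            "recovery_pct": float(100.0 * correct.sum() / responsive.sum()),
        }
        log("map", f"recovery {report['map']['recovery_pct']:.1f}%")

        # --- consistency --------------------------------------------------
        dmat = split_half_dice(
            runs[:2], runs[2:], bank, config.n_digits, config.threshold_z
        )
        pd.DataFrame(
            dmat.values,
            index=[f"D{d}_halfA" for d in range(1, 6)],
            columns=[f"D{d}_halfB" for d in range(1, 6)],
        ).to_csv(out / "dice_matrix.tsv", sep="\t")
        null, exceeds = different_digit_null(
            dmat,
            n_iterations=config.consistency_iterations,
            seed=derive_seed(config.seed, "dice-null"),
        )
        report["consistency"] = {
            "same_mean": dmat.same_mean,
            "different_mean": dmat.different_mean,
            "null_ci": [null.ci_low, null.ci_high],
            "same_exceeds_null": exceeds,
        }
        log("consistency", f"same={dmat.same_mean:.3f} diff={dmat.different_mean:.3f}")

        # --- similarity ---------------------------------------------------
        second_moment = pair_correlated_second_moment(0.5, (0, 1))
        ptruth = PatternGroundTruth(
            second_moment=second_moment,
            n_voxels=config.pattern_n_voxels,
            n_runs=config.pattern_n_runs,
            noise_sigma=config.pattern_noise_sigma,
        )
        case_patterns = stack_runs(
            list(
                simulate_block_patterns(
                    ptruth, seed=derive_seed(config.seed, "patterns-case")
                )
            )
        )
        case_sim = pattern_component_similarity(case_patterns)
        pd.DataFrame(
            case_sim.r,
            index=[f"D{d}" for d in range(1, 6)],
            columns=[f"D{d}" for d in range(1, 6)],
        ).to_csv(out / "similarity_matrix.tsv", sep="\t")
        controls = []
        for c in range(config.n_controls):
            pats = stack_runs(
                list(
                    simulate_block_patterns(
                        ptruth, seed=derive_seed(config.seed, f"patterns-ctrl-{c}")
                    )
                )
            )
            controls.append(pattern_component_similarity(pats))
        comparison = compare_to_controls(
            case_sim,
            controls,
            n_iterations=config.similarity_iterations,
            seed=derive_seed(config.seed, "similarity-boot"),
        )
        report["similarity"] = {
            "mean_overlap": mean_overlap(case_sim),
            "case_mean_rho": comparison.case_mean_rho,
            "controls_ci": [
                comparison.controls_ci.ci_low,
                comparison.controls_ci.ci_high,
            ],
            "within_control_range": comparison.within_control_range,
        }
        log("similarity", f"mean_overlap={report['similarity']['mean_overlap']:.3f}")

        # --- casestats ----------------------------------------------------
        ctrl_overlaps = [mean_overlap(m) for m in controls]
        ch = crawford_howell_t(mean_overlap(case_sim), ctrl_overlaps, tails="two")
        bf = jzs_bayes_factor(
            comparison.case_rhos, comparison.pair_rhos, cauchy_scale=0.707
        )
        report["casestats"] = {
            "crawford_t": ch.t,
            "crawford_df": ch.df,
            "crawford_p": ch.p,
            "case_vs_controls_bf10": bf.bf10,
        }
        log("casestats", f"t({ch.df})={ch.t:.2f}, p={ch.p:.3f}")
    except Exception as exc:  # name the failing stage, then re-raise
        stage = log_lines[-1].split("[")[-1].split("]")[0] if "[" in log_lines[-1] else "init"
        log("error", f"pipeline aborted after stage '{stage}': {exc}")
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise

    config.to_yaml(out / "config.yaml")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return report


FIXTURE_PRESETS = ("noiseless", "moderate-noise", "null")


def make_fixtures(preset: str, seed: int, out_dir) -> Path:
    """Write small NIfTI phantoms + events + ground truth for a named preset."""
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig.from_preset("ultra_high", seed=seed)
    if preset == "noiseless":
        config.noise_sigma = 0.0
        config.drift_amplitude = 0.0
        config.tuning_width = 0.0
    elif preset == "null":
        config.amplitude = 0.0
    truth = make_digit_strip(
        config.grid_shape,
        config.n_digits,
        config.strip_axis,
        config.band_width_voxels,
        config.amplitude,
        config.tuning_width,
    )
    write_ground_truth(truth, out / "ground_truth")
    for k, direction in enumerate(["forward", "backward"]):
        sched = make_travelling_wave_schedule(
            direction,
            config.n_digits,
            config.block_duration,
            config.n_cycles,
            config.lead_in,
        )
        vol = simulate_run(
            sched,
            truth,
            _hrf(config),
            config.tr,
            _noise(config, derive_seed(seed, f"fixture-{preset}-{k}")),
        )
        save_volume(vol, out / f"run-{k}_{direction}.nii.gz")
        write_events(sched, out / f"run-{k}_{direction}_events.tsv")
    block = make_block_schedule(order_seed=derive_seed(seed, "fixture-block"))
    write_events(block, out / "block_events.tsv")
    config.to_yaml(out / "config.yaml")
    return out
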