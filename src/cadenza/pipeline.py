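"""End-to-end orchestration: stimuli -> PPM -> IC -> behavior -> statistics.

A run is a pure function of its :class:`RunConfig`: the same configuration
produces byte-identical outputs and a manifest listing every file with its
checksum.  Stages can be toggled; a skipped stage is recorded as such in the
manifest.  The optional tract-FA regression stage demonstrates the
white-matter analysis on synthetic FA values with a planted association to
the SP-index (there is no diffusion data in a simulation run); the file is
labelled accordingly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    PopulationParams,
    condition_means,
    filter_trials,
    motor_cell_means,
    simulate_trials,
    structure_cell_means,
)
from .cluster import VolumeSpec, convention_sensitivity, estimate_cluster_threshold
from .ic import (
    compute_ic_profiles,
    context_effect,
    deltas_to_json,
    profiles_to_dataframe,
    violation_effects,
)
from .ppm import PPM
from .stats import (
    movement_cost,
    multiple_regression,
    paired_t_bonferroni,
    rm_anova_2x2,
    rm_anova_2x2x2,
    sp_index,
)
from .stimuli import (
    build_stimulus_set,
    encode_motor,
    encode_structural,
    motor_alphabet,
    stimuli_to_dataframe,
    stimuli_to_json,
    structural_alphabet,
    validate_design,
)

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger("cadenza.pipeline")


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run."""

    output_dir: str = "cadenza_run"
    stimulus_seed: int = 0
    simulation_seed: int = 1
    mc_seed: int = 2
    max_order: int = 4
    escape: str = "C"
    exclusion: bool = False
    n_subjects: int = 26
    population: dict = field(default_factory=dict)  # PopulationParams overrides
    run_stats: bool = True
    run_cluster: bool = False
    cluster_iterations: int = 1000
    cluster_fwhm_mm: float = 8.0
    cluster_voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    cluster_connectivity: int = 18
    cluster_two_tailed: bool = False
    make_plot: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages and return the run manifest."""
    out = Path(config.output_dir)
    if not out.exists():
        out.mkdir(parents=True)
        log.info("created output directory %s", out)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "files": {},
    }

    def _write(name: str, text: str) -> Path:
        path = out / name
        path.write_text(text)
        manifest["files"][name] = _sha256(path)
        return path

    def _stage(name: str):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)

        def _done(status: str = "done"):
            manifest["stages"][name] = {
                "status": status,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("stage %s: %s", name, status)

        return _done

    # -- stimuli ------------------------------------------------------------
    done = _stage("stimuli")
    try:
        stim_set = build_stimulus_set(seed=config.stimulus_seed)
        report = validate_design(stim_set)
        all_seqs = [s for seqs in stim_set.conditions.values() for s in seqs]
        _write("stimuli.json", stimuli_to_json(all_seqs))
        _write(
            "stimuli.csv",
            stimuli_to_dataframe(all_seqs + list(stim_set.training_corpus)).to_csv(
                index=False
            ),
        )
        _write(
            "design_report.json",
            json.dumps(
                {
                    "passed": report.passed,
                    "checks": {k: {"ok": ok, "detail": msg} for k, (ok, msg) in report.checks.items()},
                    "n_base_sequences": report.n_base_sequences,
                    "n_distinct_chords": report.n_distinct_chords,
                    "n_standard_fingerings": report.n_standard_fingerings,
                    "max_fingerings_per_chord": report.max_fingerings_per_chord,
                    "n_training_sequences": report.n_training_sequences,
                    "black_key_imbalance": report.black_key_imbalance,
                },
                indent=2,
            ),
        )
    except Exception as exc:  # pragma: no cover - defensive
        done("failed")
        raise RuntimeError(f"stage 'stimuli' failed: {exc}") from exc
    done()

    # -- PPM training -------------------------------------------------------
    done = _stage("ppm")
    try:
        train_struct = [encode_structural(s) for s in stim_set.training_corpus]
        train_motor = [encode_motor(s) for s in stim_set.training_corpus]
        struct_model = PPM(
            train_struct, structural_alphabet(), max_order=config.max_order,
            escape=config.escape, exclusion=config.exclusion,
        ).fit()
        motor_model = PPM(
            train_motor, motor_alphabet(), max_order=config.max_order,
            escape=config.escape, exclusion=config.exclusion,
        ).fit()
        _write("model_structural.json", struct_model.to_json())
        _write("model_motor.json", motor_model.to_json())
    except Exception as exc:  # pragma: no cover
        done("failed")
        raise RuntimeError(f"stage 'ppm' failed: {exc}") from exc
    done()

    # -- IC profiles --------------------------------------------------------
    done = _stage("ic")
    try:
        profiles = compute_ic_profiles(struct_model, motor_model, stim_set)
        _write("ic_profiles.csv", profiles_to_dataframe(profiles).to_csv(index=False))
        _write("ic_deltas.json", deltas_to_json(profiles))
        if config.make_plot:
            from .ic import plot_profiles

            plot_path = out / "ic_profiles.png"
            plot_profiles(profiles, plot_path)
            manifest["files"]["ic_profiles.png"] = _sha256(plot_path)
    except Exception as exc:  # pragma: no cover
        done("failed")
        raise RuntimeError(f"stage 'ic' failed: {exc}") from exc
    done()

    # -- behavior -----------------------------------------------------------
    done = _stage("behavior")
    try:
        params = PopulationParams(**config.population)
        trials = simulate_trials(
            stim_set, profiles, n_subjects=config.n_subjects, params=params,
            seed=config.simulation_seed,
        )
        valid, excl_report = filter_trials(trials)
        _write("trials.csv", trials.to_csv(index=False))
        _write("exclusion_report.json", json.dumps(excl_report, indent=2))
    except Exception as exc:  # pragma: no cover
        done("failed")
        raise RuntimeError(f"stage 'behavior' failed: {exc}") from exc
    done()

    # -- statistics ---------------------------------------------------------
    done = _stage("stats")
    if not config.run_stats:
        done("skipped")
    else:
        try:
            rt_means, err_counts = condition_means(valid, error_trials=trials)
            structure_anova = rm_anova_2x2(structure_cell_means(rt_means))
            motor_anova = rm_anova_2x2(
                motor_cell_means(rt_means), factors=("structure", "movement")
            )
            err_long = (
                err_counts.stack(future_stack=True)
                .rename_axis(["subject_id", "condition"])
                .reset_index()
                .query("condition in @_ERR_CONDS")
                .melt(
                    id_vars=["subject_id", "condition"],
                    value_vars=["key_errors", "finger_errors"],
                    var_name="error_type",
                    value_name="n_errors",
                )
            )
            err_long["structure"] = err_long["condition"].str.split("-").str[1]
            err_long["movement"] = np.where(
                err_long["condition"].str.startswith("motor"), "nonstandard", "standard"
            )
            error_anova = rm_anova_2x2x2(err_long)

            post = paired_t_bonferroni(
                [
                    (
                        rt_means["baseline-irregular"].to_numpy(),
                        rt_means["baseline-regular"].to_numpy(),
                    ),
                    (
                        rt_means["structure-irregular"].to_numpy(),
                        rt_means["structure-regular"].to_numpy(),
                    ),
                ],
                n_comparisons=2,
            )
            sp = sp_index(rt_means)
            cost = movement_cost(rt_means)

            # synthetic tract-FA regression demo: FA of a "ventral" tract with
            # a planted standardized association (0.6) to the SP-index, plus an
            # unrelated "dorsal" tract
            rng = np.random.default_rng(config.simulation_seed + 10007)
            z_sp = (sp - sp.mean()) / sp.std(ddof=1)
            fa_ventral = 0.45 + 0.03 * (
                0.6 * z_sp.to_numpy()
                + np.sqrt(1 - 0.6**2) * rng.standard_normal(len(sp))
            )
            fa_dorsal = 0.45 + 0.03 * rng.standard_normal(len(sp))
            reg = multiple_regression(
                sp.to_numpy(),
                pd.DataFrame(
                    {"fa_ventral_synthetic": fa_ventral, "fa_dorsal_synthetic": fa_dorsal}
                ),
            )

            stats_doc = {
                "structure_rt_anova": structure_anova.table.to_dict(orient="index"),
                "motor_rt_anova": motor_anova.table.to_dict(orient="index"),
                "error_anova": error_anova.table.to_dict(orient="index"),
                "posthoc_structure": post.to_dict(orient="records"),
                "sp_index_ms": sp.round(6).to_dict(),
                "movement_cost_ms": cost.round(6).to_dict(),
                "fa_regression_synthetic": {
                    "predictors": list(reg.predictors),
                    "standardized_betas": reg.standardized_betas.tolist(),
                    "t": reg.t_values.tolist(),
                    "p": reg.p_values.tolist(),
                    "adjusted_r_squared": reg.adjusted_r_squared,
                },
            }
            _write("stats.json", json.dumps(stats_doc, indent=2, sort_keys=True))
            _write(
                "stats.txt",
                "\n\n".join(
                    [
                        structure_anova.summary(),
                        motor_anova.summary(),
                        error_anova.summary(),
                        f"mean SP-index: {sp.mean():.1f} ms",
                        f"mean movement cost: {cost.mean():.1f} ms",
                        reg.summary(),
                    ]
                ),
            )
        except Exception as exc:  # pragma: no cover
            done("failed")
            raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
        done()

    # -- cluster Monte Carlo ------------------------------------------------
    done = _stage("cluster")
    if not config.run_cluster:
        done("skipped")
    else:
        try:
            result = estimate_cluster_threshold(
                VolumeSpec(),
                fwhm_mm=config.cluster_fwhm_mm,
                voxel_p=config.cluster_voxel_p,
                alpha=config.cluster_alpha,
                n_iterations=config.cluster_iterations,
                connectivity=config.cluster_connectivity,
                two_tailed=config.cluster_two_tailed,
                seed=config.mc_seed,
            )
            sens = convention_sensitivity(
                VolumeSpec(),
                fwhm_mm=config.cluster_fwhm_mm,
                voxel_p=config.cluster_voxel_p,
                alpha=config.cluster_alpha,
                n_iterations=max(100, config.cluster_iterations // 5),
                seed=config.mc_seed + 1,
            )
            _write(
                "cluster_mc.json",
                json.dumps(
                    {
                        "summary": result.summary(),
                        "threshold_voxels": result.threshold_voxels,
                        "achieved_fw_p": result.achieved_fw_p,
                        "n_iterations": result.n_iterations,
                        "connectivity": result.connectivity,
                        "two_tailed": result.two_tailed,
                        "max_extent_null": result.max_extent_null.tolist(),
                        "convention_sensitivity": [
                            {
                                "connectivity": r.connectivity,
                                "two_tailed": r.two_tailed,
                                "threshold_voxels": r.threshold_voxels,
                            }
                            for r in sens
                        ],
                    },
                    indent=2,
                ),
            )
        except Exception as exc:  # pragma: no cover
            done("failed")
            raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc
        done()

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


_ERR_CONDS = [
    "baseline-regular", "baseline-irregular", "motor-regular", "motor-irregular",
]
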