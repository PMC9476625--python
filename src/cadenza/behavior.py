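"""Synthetic performance data with the statistical structure the analyses assume.

Each simulated pianist imitates every base sequence once per condition
(6 conditions x 26 sequences = 156 trials).  Reaction times of the final
chord are log-normal around a subject-specific baseline plus linear effects
of the final chord's structural and motor information content (IC), so that
condition differences are driven by the model surprisal exactly where the
design puts it: irregular endings raise structural IC (more in long than
short contexts), nonstandard fingerings raise motor IC.  Key errors become
more likely with structural IC and finger errors with motor IC, so motor
violations inflate finger errors more than key errors.  The three keystrokes
of a chord scatter around the chord onset with a configurable asynchrony.

``filter_trials`` applies the behavioral inclusion pipeline: (1) penultimate
and final chord correct in keys and fingers, (2) keystroke span of both
chords at most 150 ms, (3) final-chord RT below 3000 ms, (4) a single-pass
per-participant trim of RTs deviating more than 2 SD from the participant's
mean across conditions.  Default generator parameters are calibrated so that
retention lands near 69% of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ic import ICProfile
from .stimuli import CONDITIONS, StimulusSet

__all__ = [
    "SubjectParams",
    "PopulationParams",
    "simulate_trials",
    "filter_trials",
    "condition_means",
    "structure_cell_means",
    "motor_cell_means",
]

RT_CUTOFF_MS = 3000.0
SYNC_WINDOW_MS = 150.0
SD_TRIM = 2.0


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one simulated pianist."""

    subject_id: int
    baseline_rt_ms: float
    ic_sensitivity_struct_ms_per_bit: float
    ic_sensitivity_motor_ms_per_bit: float
    noise_sd_log: float
    key_error_base: float
    key_error_per_bit: float
    finger_error_base: float
    finger_error_per_bit: float
    asynchrony_sd_ms: float

    def __post_init__(self):
        if self.baseline_rt_ms <= 0:
            raise ValueError("baseline RT must be positive")
        if self.noise_sd_log < 0 or self.asynchrony_sd_ms < 0:
            raise ValueError("noise parameters must be non-negative")
        for p in (self.key_error_base, self.finger_error_base):
            if not (0.0 <= p <= 1.0):
                raise ValueError("error probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationParams:
    """Population distribution from which subject parameters are drawn.

    The defaults encode moderate, realistic effects: a ~900 ms baseline with
    ~80 ms between-subject spread, a few milliseconds of slowing per bit of
    surprisal at either level, 15% multiplicative trial noise, and error and
    asynchrony rates that leave roughly 69% of trials after the exclusion
    pipeline.
    """

    baseline_rt_ms: float = 900.0
    baseline_sd_ms: float = 80.0
    struct_sensitivity_ms_per_bit: float = 6.0
    struct_sensitivity_sd: float = 1.5
    motor_sensitivity_ms_per_bit: float = 8.0
    motor_sensitivity_sd: float = 1.5
    noise_sd_log: float = 0.15
    key_error_base: float = 0.06
    key_error_per_bit: float = 0.005
    finger_error_base: float = 0.06
    finger_error_per_bit: float = 0.005
    asynchrony_sd_ms: float = 45.0

    def draw_subjects(self, n_subjects: int, rng: np.random.Generator) -> list[SubjectParams]:
        if n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        subjects = []
        for sid in range(1, n_subjects + 1):
            subjects.append(
                SubjectParams(
                    subject_id=sid,
                    baseline_rt_ms=float(
                        max(200.0, rng.normal(self.baseline_rt_ms, self.baseline_sd_ms))
                    ),
                    ic_sensitivity_struct_ms_per_bit=float(
                        max(0.0, rng.normal(self.struct_sensitivity_ms_per_bit,
                                            self.struct_sensitivity_sd))
                    ) if self.struct_sensitivity_ms_per_bit != 0 else 0.0,
                    ic_sensitivity_motor_ms_per_bit=float(
                        max(0.0, rng.normal(self.motor_sensitivity_ms_per_bit,
                                            self.motor_sensitivity_sd))
                    ) if self.motor_sensitivity_ms_per_bit != 0 else 0.0,
                    noise_sd_log=self.noise_sd_log,
                    key_error_base=self.key_error_base,
                    key_error_per_bit=self.key_error_per_bit,
                    finger_error_base=self.finger_error_base,
                    finger_error_per_bit=self.finger_error_per_bit,
                    asynchrony_sd_ms=self.asynchrony_sd_ms,
                )
            )
        return subjects


def _final_ic_lookup(
    ic_profiles: Sequence[ICProfile],
) -> dict[tuple[str, str], Mapping[int, float]]:
    table: dict[tuple[str, str], Mapping[int, float]] = {}
    for p in ic_profiles:
        table[(p.level, p.condition)] = dict(zip(p.base_ids, p.final_ic))
    return table


def simulate_trials(
    stimulus_set: StimulusSet,
    ic_profiles: Sequence[ICProfile],
    n_subjects: int = 26,
    params: PopulationParams | Sequence[SubjectParams] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one performance of every sequence x condition per subject.

    Returns one row per trial with keystroke onsets (three per chord for the
    penultimate and final chords), the trial RT (mean of the three final
    onsets, time-locked to the final photo), correctness flags and the final
    chord's IC at both levels.  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = PopulationParams()
    if isinstance(params, PopulationParams):
        subjects = params.draw_subjects(n_subjects, rng)
    else:
        subjects = list(params)
        if len(subjects) != n_subjects:
            raise ValueError("explicit subject list must match n_subjects")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    ic = _final_ic_lookup(ic_profiles)
    rows = []
    for cond_name, cond in CONDITIONS.items():
        struct_ic = ic[("structural", cond_name)]
        motor_ic = ic[("motor", cond_name)]
        for seq in stimulus_set.conditions[cond_name]:
            rows.append(
                (
                    cond_name, cond.block, cond.structure, cond.context,
                    cond.movement, seq.base_id,
                    struct_ic[seq.base_id], motor_ic[seq.base_id],
                )
            )
    trial_info = pd.DataFrame(
        rows,
        columns=[
            "condition", "block", "structure", "context", "movement",
            "base_id", "ic_struct_final", "ic_motor_final",
        ],
    )

    n_trials = len(trial_info)
    frames = []
    for sp in subjects:
        mu = (
            sp.baseline_rt_ms
            + sp.ic_sensitivity_struct_ms_per_bit * trial_info["ic_struct_final"].to_numpy()
            + sp.ic_sensitivity_motor_ms_per_bit * trial_info["ic_motor_final"].to_numpy()
        )
        # multiplicative log-normal noise with unit mean
        noise = rng.normal(0.0, sp.noise_sd_log, n_trials)
        rt = mu * np.exp(noise - 0.5 * sp.noise_sd_log**2)

        jit_f = rng.normal(0.0, sp.asynchrony_sd_ms, (n_trials, 3))
        jit_f -= jit_f.mean(axis=1, keepdims=True)
        onsets_f = rt[:, None] + jit_f
        jit_p = rng.normal(0.0, sp.asynchrony_sd_ms, (n_trials, 3))
        jit_p -= jit_p.mean(axis=1, keepdims=True)
        onsets_p = (rt[:, None] - 2000.0) + jit_p  # chords presented 2 s apart

        p_key = np.clip(
            sp.key_error_base
            + sp.key_error_per_bit * trial_info["ic_struct_final"].to_numpy(),
            0.0, 0.95,
        )
        p_finger = np.clip(
            sp.finger_error_base
            + sp.finger_error_per_bit * trial_info["ic_motor_final"].to_numpy(),
            0.0, 0.95,
        )
        df = trial_info.copy()
        df.insert(0, "subject_id", sp.subject_id)
        df["onset_f1"], df["onset_f2"], df["onset_f3"] = onsets_f.T
        df["onset_p1"], df["onset_p2"], df["onset_p3"] = onsets_p.T
        df["rt_ms"] = onsets_f.mean(axis=1)
        df["span_final_ms"] = onsets_f.max(axis=1) - onsets_f.min(axis=1)
        df["span_penult_ms"] = onsets_p.max(axis=1) - onsets_p.min(axis=1)
        df["correct_keys"] = rng.random(n_trials) >= p_key
        df["correct_fingers"] = rng.random(n_trials) >= p_finger
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    return trials


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the four sequential inclusion rules; return valid trials + report.

    Rules: (1) correct keys and fingers; (2) keystroke span of the penultimate
    and final chord <= 150 ms; (3) final RT strictly below 3000 ms; (4) single
    per-participant pass removing RTs more than 2 SD from the participant's
    mean across conditions.  With zero RT spread the 2-SD rule removes nothing.
    """
    if trials.empty:
        raise ValueError("no trials to filter")
    n_total = len(trials)

    ok1 = trials["correct_keys"] & trials["correct_fingers"]
    after1 = trials[ok1]

    ok2 = (after1["span_final_ms"] <= SYNC_WINDOW_MS) & (
        after1["span_penult_ms"] <= SYNC_WINDOW_MS
    )
    after2 = after1[ok2]

    ok3 = after2["rt_ms"] < RT_CUTOFF_MS
    after3 = after2[ok3]

    grp = after3.groupby("subject_id")["rt_ms"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    ok4 = (after3["rt_ms"] - mean).abs() <= SD_TRIM * sd
    valid = after3[ok4].copy()

    report = {
        "n_total": int(n_total),
        "removed_errors": int(n_total - len(after1)),
        "removed_asynchrony": int(len(after1) - len(after2)),
        "removed_rt_cutoff": int(len(after2) - len(after3)),
        "removed_sd_trim": int(len(after3) - len(valid)),
        "n_valid": int(len(valid)),
        "retention": float(len(valid) / n_total),
    }
    return valid, report


def condition_means(
    trials: pd.DataFrame, error_trials: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per subject x condition mean RT and key/finger error counts.

    RT means are computed over the trials passed in (normally the valid
    trials); error counts over ``error_trials`` if given (normally the full,
    unfiltered table, as errors are a dependent variable in their own right).
    Cells without a single valid trial carry NaN, never zero.
    """
    rt = (
        trials.groupby(["subject_id", "condition"])["rt_ms"]
        .mean()
        .unstack("condition")
        .reindex(columns=list(CONDITIONS))
    )
    src = error_trials if error_trials is not None else trials
    err = (
        src.assign(
            key_errors=lambda d: ~d["correct_keys"],
            finger_errors=lambda d: ~d["correct_fingers"],
        )
        .groupby(["subject_id", "condition"])[["key_errors", "finger_errors"]]
        .sum()
        .unstack("condition")
    )
    return rt, err


def _cell_means(
    rt_means: pd.DataFrame, mapping: dict[str, tuple[str, str]], factors: tuple[str, str]
) -> pd.DataFrame:
    """Long-format per-subject cell means for a 2x2 repeated-measures analysis."""
    rows = []
    for cond, levels in mapping.items():
        if cond not in rt_means.columns:
            raise KeyError(f"condition {cond!r} missing from the RT table")
        for sid, val in rt_means[cond].items():
            rows.append(
                {"subject_id": sid, factors[0]: levels[0], factors[1]: levels[1],
                 "rt_ms": val}
            )
    return pd.DataFrame(rows)


def structure_cell_means(rt_means: pd.DataFrame) -> pd.DataFrame:
    """STRUCTURE x CONTEXT cells from the baseline and structure blocks."""
    mapping = {
        "baseline-regular": ("regular", "long"),
        "baseline-irregular": ("irregular", "long"),
        "structure-regular": ("regular", "short"),
        "structure-irregular": ("irregular", "short"),
    }
    return _cell_means(rt_means, mapping, ("structure", "context"))


def motor_cell_means(rt_means: pd.DataFrame) -> pd.DataFrame:
    """STRUCTURE x MOVEMENT cells from the baseline and motor blocks."""
    mapping = {
        "baseline-regular": ("regular", "standard"),
        "baseline-irregular": ("irregular", "standard"),
        "motor-regular": ("regular", "nonstandard"),
        "motor-irregular": ("irregular", "nonstandard"),
    }
    return _cell_means(rt_means, mapping, ("structure", "movement"))
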