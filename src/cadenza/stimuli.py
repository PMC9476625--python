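"""Rule-based chord-sequence stimulus design and symbolic encoders.

The experimental design emulated here: 26 five-chord progressions composed
by the rules of classical harmony in six major tonalities (D, E, Bb, Ab, A,
Eb), every sequence closing with an authentic cadence (V -> I).  Right-hand
three-note chords are voiced in close position on a 27-key keyboard, each
assigned one of six standard fingerings (the chord-to-finger mapping is
deliberately not fixed, so a recurring chord can carry several fingerings).
Three manipulations derive six conditions from each base sequence:

* structure: the final chord is either the Tonic (regular) or a Neapolitan
  chord — a minor subdominant whose fifth is replaced by a diminished sixth
  (irregular); its pitch content equals the major triad a semitone above the
  tonic, so Tonic chords of one tonality recur as Neapolitans of another.
* context: the full five-chord sequence (long) or only its last two chords
  (short); the penultimate chord is identical across all conditions.
* movement: the final chord is played with a standard fingering or one of
  the nonstandard configurations 2-3-5 / 2-4-5.

A separate 60-sequence training corpus in the six complementary tonalities
(C, G, B, F, Db, Gb) — structurally and motorically correct throughout —
feeds the PPM models.  Two encoders translate sequences into the model's
symbol sets: harmonic function x inversion (tonality-invariant), and
fingering triples.

The default design plan (template selections and register anchors per
tonality) is frozen so that the published design counts hold by
construction: 26 sequences, 50 distinct chords, 6 standard fingerings, at
least one chord realized with 3 different fingerings, everything within the
27-key range.  ``validate_design`` re-checks all of this on any generated
set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ppm import Alphabet

__all__ = [
    "KeyboardModel",
    "Tonality",
    "Chord",
    "Fingering",
    "Condition",
    "StimulusSequence",
    "StimulusSet",
    "DesignReport",
    "TEMPLATES",
    "TEST_DESIGN",
    "TRAINING_DESIGN",
    "STANDARD_FINGERINGS",
    "NONSTANDARD_FINGERINGS",
    "generate_base_sequences",
    "build_training_corpus",
    "build_stimulus_set",
    "neapolitan_of",
    "apply_structure_manipulation",
    "truncate_context",
    "apply_fingering_manipulation",
    "encode_structural",
    "encode_motor",
    "structural_alphabet",
    "motor_alphabet",
    "validate_design",
    "stimuli_to_json",
    "stimuli_to_dataframe",
    "CONDITIONS",
]

_PC_NAMES = {
    0: "C", 1: "Db", 2: "D", 3: "Eb", 4: "E", 5: "F",
    6: "Gb", 7: "G", 8: "Ab", 9: "A", 10: "Bb", 11: "B",
}
_BLACK_PCS = {1, 3, 6, 8, 10}


@dataclass(frozen=True)
class KeyboardModel:
    """The MR-compatible piano: 27 weighted keys, key 1 = F3 (MIDI 53)."""

    n_keys: int = 27
    lowest_pitch: int = 53

    @property
    def highest_pitch(self) -> int:
        return self.lowest_pitch + self.n_keys - 1

    def key_of(self, midi: int) -> int:
        if not (self.lowest_pitch <= midi <= self.highest_pitch):
            raise ValueError(f"MIDI pitch {midi} outside the {self.n_keys}-key range")
        return midi - self.lowest_pitch + 1

    def midi_of(self, key: int) -> int:
        if not (1 <= key <= self.n_keys):
            raise ValueError(f"key index {key} outside 1..{self.n_keys}")
        return self.lowest_pitch + key - 1


@dataclass(frozen=True)
class Tonality:
    name: str
    tonic_pitch_class: int
    mode: str = "major"

    def __post_init__(self):
        if not (0 <= self.tonic_pitch_class <= 11):
            raise ValueError("tonic pitch class must be 0..11")
        if self.mode != "major":
            raise ValueError("only major tonalities are supported")


# Harmonic functions: (scale-degree offset of the root, triad quality)
_FUNCTIONS = {
    "Tonic": (0, "major"),
    "Supertonic": (2, "minor"),
    "Subdominant": (5, "major"),
    "Dominant": (7, "major"),
    "Submediant": (9, "minor"),
}
_INVERSIONS = ("root", "first", "second")
_QUALITY_INTERVALS = {"major": (0, 4, 7), "minor": (0, 3, 7)}


@dataclass(frozen=True)
class Chord:
    """A three-key right-hand chord with its harmonic interpretation."""

    keys: tuple[int, int, int]
    tonality: str
    function: str
    inversion: str
    keyboard: KeyboardModel = field(default=KeyboardModel(), compare=False)

    def __post_init__(self):
        if len(self.keys) != 3 or not (self.keys[0] < self.keys[1] < self.keys[2]):
            raise ValueError(f"keys must be a strictly ascending triple, got {self.keys}")
        for k in self.keys:
            if not (1 <= k <= self.keyboard.n_keys):
                raise ValueError(f"key {k} outside the {self.keyboard.n_keys}-key keyboard")

    @property
    def midi(self) -> tuple[int, int, int]:
        return tuple(self.keyboard.midi_of(k) for k in self.keys)

    @property
    def pitch_classes(self) -> tuple[int, int, int]:
        return tuple(m % 12 for m in self.midi)

    @property
    def pitch_class_set(self) -> frozenset[int]:
        return frozenset(self.pitch_classes)

    @property
    def n_black_keys(self) -> int:
        return sum(1 for pc in self.pitch_classes if pc in _BLACK_PCS)

    @property
    def span(self) -> int:
        return self.keys[2] - self.keys[0]

    def __str__(self) -> str:  # pragma: no cover
        notes = "-".join(_PC_NAMES[pc].lower() for pc in self.pitch_classes)
        return f"{self.tonality}:{self.function}/{self.inversion} [{notes}]"


STANDARD_FINGERINGS = (
    (1, 2, 3), (1, 2, 4), (1, 2, 5), (1, 3, 4), (1, 3, 5), (1, 4, 5),
)
NONSTANDARD_FINGERINGS = ((2, 3, 5), (2, 4, 5))


@dataclass(frozen=True)
class Fingering:
    digits: tuple[int, int, int]

    def __post_init__(self):
        d = self.digits
        if len(d) != 3 or not (1 <= d[0] < d[1] < d[2] <= 5):
            raise ValueError(f"fingering must be a strictly ascending triple in 1..5, got {d}")
        if d not in STANDARD_FINGERINGS and d not in NONSTANDARD_FINGERINGS:
            raise ValueError(f"unknown fingering {d}")

    @property
    def standardness(self) -> str:
        return "standard" if self.digits in STANDARD_FINGERINGS else "nonstandard"

    @property
    def token(self) -> str:
        return "-".join(str(d) for d in self.digits)


_BLOCKS = ("baseline", "structure", "motor")


@dataclass(frozen=True)
class Condition:
    block: str = "baseline"
    structure: str = "regular"
    context: str = "long"
    movement: str = "standard"

    def __post_init__(self):
        if self.block not in _BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.structure not in ("regular", "irregular"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.context not in ("long", "short"):
            raise ValueError(f"unknown context {self.context!r}")
        if self.movement not in ("standard", "nonstandard"):
            raise ValueError(f"unknown movement {self.movement!r}")
        if self.movement == "nonstandard" and self.block != "motor":
            raise ValueError("nonstandard movement occurs only in motor blocks")
        if self.context == "short" and self.block != "structure":
            raise ValueError("short context occurs only in structure blocks")

    @property
    def label(self) -> str:
        return f"{self.block}-{self.structure}"


#: The six experimental conditions, keyed by "<block>-<structure>".
CONDITIONS = {
    "baseline-regular": Condition("baseline", "regular", "long", "standard"),
    "baseline-irregular": Condition("baseline", "irregular", "long", "standard"),
    "structure-regular": Condition("structure", "regular", "short", "standard"),
    "structure-irregular": Condition("structure", "irregular", "short", "standard"),
    "motor-regular": Condition("motor", "regular", "long", "nonstandard"),
    "motor-irregular": Condition("motor", "irregular", "long", "nonstandard"),
}


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered list of (chord, fingering) events with design tags."""

    events: tuple[tuple[Chord, Fingering], ...]
    tonality: str
    base_id: int
    condition: Condition = Condition()
    template: str = ""

    def __post_init__(self):
        expected = 2 if self.condition.context == "short" else 5
        if len(self.events) != expected:
            raise ValueError(
                f"{self.condition.context} sequences have {expected} events, "
                f"got {len(self.events)}"
            )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def chords(self) -> tuple[Chord, ...]:
        return tuple(c for c, _ in self.events)

    @property
    def fingerings(self) -> tuple[Fingering, ...]:
        return tuple(f for _, f in self.events)

    @property
    def final(self) -> tuple[Chord, Fingering]:
        return self.events[-1]

    @property
    def penultimate(self) -> tuple[Chord, Fingering]:
        return self.events[-2]


@dataclass(frozen=True)
class StimulusSet:
    """The full design: 26 base sequences, six derived conditions, training corpus."""

    base_sequences: tuple[StimulusSequence, ...]
    conditions: Mapping[str, tuple[StimulusSequence, ...]]
    training_corpus: tuple[StimulusSequence, ...]
    seed: int = 0


# ---------------------------------------------------------------------------
# Cadential templates: (function, inversion) progressions, all ending V -> I.
# ---------------------------------------------------------------------------

TEMPLATES: dict[str, tuple[tuple[str, str], ...]] = {
    # I  vi  IV  V  I
    "T1": (("Tonic", "root"), ("Submediant", "root"), ("Subdominant", "root"),
           ("Dominant", "root"), ("Tonic", "root")),
    # I  IV6  ii6  V  I
    "T2": (("Tonic", "root"), ("Subdominant", "first"), ("Supertonic", "first"),
           ("Dominant", "root"), ("Tonic", "root")),
    # I6  IV  I64  V  I
    "T3": (("Tonic", "first"), ("Subdominant", "root"), ("Tonic", "second"),
           ("Dominant", "root"), ("Tonic", "root")),
    # vi  ii6  I64  V  I
    "T4": (("Submediant", "root"), ("Supertonic", "first"), ("Tonic", "second"),
           ("Dominant", "root"), ("Tonic", "root")),
    # I  I6  ii  V  I
    "T5": (("Tonic", "root"), ("Tonic", "first"), ("Supertonic", "root"),
           ("Dominant", "root"), ("Tonic", "root")),
    # I  vi  ii6  V  I
    "T6": (("Tonic", "root"), ("Submediant", "root"), ("Supertonic", "first"),
           ("Dominant", "root"), ("Tonic", "root")),
    # I  V6  I6  V  I
    "T7": (("Tonic", "root"), ("Dominant", "first"), ("Tonic", "first"),
           ("Dominant", "root"), ("Tonic", "root")),
    # I6  ii  I64  V  I
    "T8": (("Tonic", "first"), ("Supertonic", "root"), ("Tonic", "second"),
           ("Dominant", "root"), ("Tonic", "root")),
}

# Frozen design plan: (tonality, tonic pc, register anchor, template ids).
# Template selections and anchors realize the published design counts
# (50 distinct chords over 26 sequences) on the 27-key keyboard.
TEST_DESIGN: tuple[tuple[str, int, str, tuple[str, ...]], ...] = (
    ("D", 2, "low", ("T1", "T2", "T3", "T5", "T6")),
    ("A", 9, "high", ("T2", "T4", "T5", "T6", "T7")),
    ("E", 4, "low", ("T5", "T6", "T7", "T8")),
    ("Bb", 10, "low", ("T2", "T4", "T5", "T7")),
    ("Ab", 8, "low", ("T1", "T2", "T3", "T5")),
    ("Eb", 3, "high", ("T1", "T3", "T5", "T6")),
)

# Training tonalities are disjoint from the test set; each contributes ten
# sequences (all eight templates plus two repeats), 60 sequences in total.
_TRAIN_EXTRA = (("T1", "T2"), ("T3", "T4"), ("T5", "T6"), ("T7", "T8"),
                ("T1", "T2"), ("T3", "T4"))
TRAINING_DESIGN: tuple[tuple[str, int, str, tuple[str, ...]], ...] = tuple(
    (name, pc, anchor, tuple(sorted(TEMPLATES)) + _TRAIN_EXTRA[i])
    for i, (name, pc, anchor) in enumerate(
        (("C", 0, "low"), ("G", 7, "high"), ("B", 11, "low"),
         ("F", 5, "high"), ("Db", 1, "low"), ("Gb", 6, "high"))
    )
)


# ---------------------------------------------------------------------------
# Voicing
# ---------------------------------------------------------------------------


def _voice(
    tonic_pc: int,
    function: str,
    inversion: str,
    anchor: str,
    keyboard: KeyboardModel,
    tonality_name: str,
) -> Chord:
    """Close-position voicing of a harmonic function on the keyboard.

    The bass takes the lowest (anchor="low") or highest (anchor="high")
    feasible octave; upper voices stack minimally above it.
    """
    degree, quality = _FUNCTIONS[function]
    root_pc = (tonic_pc + degree) % 12
    iv = _QUALITY_INTERVALS[quality]
    pcs = [(root_pc + i) % 12 for i in iv]
    order = {"root": (0, 1, 2), "first": (1, 2, 0), "second": (2, 0, 1)}[inversion]
    stacked = [pcs[i] for i in order]

    candidates = []
    for bass in range(keyboard.lowest_pitch, keyboard.highest_pitch + 1):
        if bass % 12 != stacked[0]:
            continue
        notes = [bass]
        ok = True
        for pc in stacked[1:]:
            step = (pc - notes[-1]) % 12 or 12
            nxt = notes[-1] + step
            if nxt > keyboard.highest_pitch:
                ok = False
                break
            notes.append(nxt)
        if ok:
            candidates.append(tuple(notes))
    if not candidates:
        raise ValueError(
            f"{function}/{inversion} in {tonality_name} is unrealizable on the keyboard"
        )
    notes = candidates[0] if anchor == "low" else candidates[-1]
    return Chord(
        keys=tuple(keyboard.key_of(m) for m in notes),
        tonality=tonality_name,
        function=function,
        inversion=inversion,
        keyboard=keyboard,
    )


def neapolitan_of(
    tonality: Tonality | str,
    keyboard: KeyboardModel = KeyboardModel(),
    anchor: str | None = None,
) -> Chord:
    """The structurally irregular final chord of a tonality.

    Rule: take the subdominant triad, make it minor (lower its third), and
    replace its fifth by the diminished sixth (one semitone up).  The
    resulting pitch content equals the major triad a semitone above the
    tonic (e.g. in C major: F-Ab-Db, the Db-major triad).
    """
    if isinstance(tonality, str):
        tonic_pc, anchor_default = _design_lookup(tonality)
        name = tonality
    else:
        tonic_pc, name = tonality.tonic_pitch_class, tonality.name
        anchor_default = "low"
    anchor = anchor or anchor_default
    sub = _voice(tonic_pc, "Subdominant", "root", anchor, keyboard, name)
    m = sub.midi
    notes = (m[0], m[1] - 1, m[2] + 1)
    if notes[2] > keyboard.highest_pitch:
        raise ValueError(f"Neapolitan of {name} is unrealizable on the keyboard")
    return Chord(
        keys=tuple(keyboard.key_of(x) for x in notes),
        tonality=name,
        function="Neapolitan",
        inversion="first",  # the bass carries the third of the triad
        keyboard=keyboard,
    )


def _design_lookup(name: str) -> tuple[int, str]:
    for n, pc, anchor, _ in TEST_DESIGN + TRAINING_DESIGN:
        if n == name:
            return pc, anchor
    raise KeyError(f"tonality {name!r} is not part of the design")


# ---------------------------------------------------------------------------
# Fingering assignment
# ---------------------------------------------------------------------------

# Span-conditional candidate fingerings; rotation over recurrences of the
# same chord realizes the flexible chord-to-finger mapping.
_NARROW = ((1, 3, 5), (1, 2, 4), (1, 2, 3))   # close triads, span <= 7 keys
_MEDIUM = ((1, 3, 5), (1, 3, 4), (1, 2, 4))   # span 8
_WIDE = ((1, 3, 5), (1, 2, 5), (1, 4, 5))     # span >= 9
_FINAL_FINGERING = Fingering((1, 3, 5))


def _candidates_for(chord: Chord) -> tuple[tuple[int, int, int], ...]:
    if chord.span <= 7:
        return _NARROW
    if chord.span == 8:
        return _MEDIUM
    return _WIDE


def _assign_fingerings(
    chord_rows: Sequence[tuple[int, int, Chord]], seed: int
) -> dict[tuple[int, int], Fingering]:
    """Deterministic fingering plan for a pool of chord events.

    ``chord_rows`` holds (sequence index, position index, chord).  Final
    chords (position 5) take the canonical 1-3-5; elsewhere recurrences of
    the same key triple rotate through the chord's candidate list, with a
    per-chord starting phase derived from the keys and the seed.
    """
    occurrence: dict[tuple[int, int, int], int] = {}
    plan: dict[tuple[int, int], Fingering] = {}
    for seq_i, pos_i, chord in chord_rows:
        if pos_i == 4:
            plan[(seq_i, pos_i)] = _FINAL_FINGERING
            continue
        cands = _candidates_for(chord)
        k = occurrence.get(chord.keys, 0)
        occurrence[chord.keys] = k + 1
        phase = (sum(chord.keys) + seed) % len(cands)
        plan[(seq_i, pos_i)] = Fingering(cands[(phase + k) % len(cands)])
    return plan


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def _generate_pool(
    design: Sequence[tuple[str, int, str, tuple[str, ...]]],
    seed: int,
    keyboard: KeyboardModel,
    id_offset: int = 0,
) -> list[StimulusSequence]:
    rows: list[tuple[str, int, str, str]] = []  # tonality, pc, anchor, template
    for name, pc, anchor, template_ids in design:
        for tid in template_ids:
            if tid not in TEMPLATES:
                raise ValueError(f"unknown template id {tid!r}")
            if TEMPLATES[tid][-2:] != (("Dominant", "root"), ("Tonic", "root")):
                raise ValueError(f"template {tid!r} does not end with an authentic cadence")
            rows.append((name, pc, anchor, tid))

    chord_rows: list[tuple[int, int, Chord]] = []
    seq_meta: list[tuple[str, str, list[Chord]]] = []
    for seq_i, (name, pc, anchor, tid) in enumerate(rows):
        chords = [
            _voice(pc, func, inv, anchor, keyboard, name)
            for func, inv in TEMPLATES[tid]
        ]
        seq_meta.append((name, tid, chords))
        chord_rows.extend((seq_i, pos_i, c) for pos_i, c in enumerate(chords))

    plan = _assign_fingerings(chord_rows, seed)
    sequences = []
    for seq_i, (name, tid, chords) in enumerate(seq_meta):
        events = tuple(
            (c, plan[(seq_i, pos_i)]) for pos_i, c in enumerate(chords)
        )
        sequences.append(
            StimulusSequence(
                events=events,
                tonality=name,
                base_id=id_offset + seq_i + 1,
                condition=Condition(),
                template=tid,
            )
        )
    return sequences


def generate_base_sequences(
    design: Sequence[tuple[str, int, str, tuple[str, ...]]] = TEST_DESIGN,
    seed: int = 0,
    keyboard: KeyboardModel = KeyboardModel(),
) -> list[StimulusSequence]:
    """The 26 base five-chord sequences (regular endings, standard fingers)."""
    return _generate_pool(design, seed, keyboard)


def build_training_corpus(
    design: Sequence[tuple[str, int, str, tuple[str, ...]]] = TRAINING_DESIGN,
    seed: int = 0,
    keyboard: KeyboardModel = KeyboardModel(),
) -> list[StimulusSequence]:
    """The 60 structurally and motorically correct training sequences."""
    corpus = _generate_pool(design, seed, keyboard)
    if len(corpus) != 60:
        raise ValueError(f"training design yields {len(corpus)} sequences, expected 60")
    return corpus


# ---------------------------------------------------------------------------
# Condition manipulations
# ---------------------------------------------------------------------------


def apply_structure_manipulation(
    seq: StimulusSequence, structure: str, keyboard: KeyboardModel = KeyboardModel()
) -> StimulusSequence:
    """Regular (identity) or irregular ending: final chord -> Neapolitan."""
    if structure == "regular":
        return seq
    if structure != "irregular":
        raise ValueError(f"structure must be regular or irregular, got {structure!r}")
    _, anchor = _design_lookup(seq.tonality)
    neap = neapolitan_of(seq.tonality, keyboard, anchor)
    final_chord, final_fing = seq.final
    events = seq.events[:-1] + ((neap, final_fing),)
    block = seq.condition.block
    cond = replace(seq.condition, structure="irregular", block=block)
    return replace(seq, events=events, condition=cond)


def truncate_context(seq: StimulusSequence) -> StimulusSequence:
    """Short-context variant: only the last two chords are presented."""
    if len(seq.events) != 5:
        raise ValueError(f"can only truncate 5-event sequences, got {len(seq.events)}")
    cond = Condition(
        block="structure",
        structure=seq.condition.structure,
        context="short",
        movement="standard",
    )
    return replace(seq, events=seq.events[-2:], condition=cond)


def apply_fingering_manipulation(
    seq: StimulusSequence, movement: str, seed: int = 0
) -> StimulusSequence:
    """Standard (identity) or nonstandard final fingering (2-3-5 / 2-4-5).

    The two nonstandard configurations are balanced across base ids.
    """
    if movement == "standard":
        return seq
    if movement != "nonstandard":
        raise ValueError(f"movement must be standard or nonstandard, got {movement!r}")
    if len(seq.events) != 5:
        raise ValueError("nonstandard fingerings apply to long (motor-block) sequences")
    digits = NONSTANDARD_FINGERINGS[(seq.base_id + seed) % 2]
    chord, _ = seq.final
    events = seq.events[:-1] + ((chord, Fingering(digits)),)
    cond = Condition(
        block="motor",
        structure=seq.condition.structure,
        context="long",
        movement="nonstandard",
    )
    return replace(seq, events=events, condition=cond)


def build_stimulus_set(
    seed: int = 0, keyboard: KeyboardModel = KeyboardModel()
) -> StimulusSet:
    """Generate the full design: base pool, six conditions, training corpus."""
    base = generate_base_sequences(seed=seed, keyboard=keyboard)
    baseline_reg = tuple(
        replace(s, condition=Condition("baseline", "regular", "long", "standard"))
        for s in base
    )
    baseline_irr = tuple(
        apply_structure_manipulation(s, "irregular", keyboard) for s in baseline_reg
    )
    conditions = {
        "baseline-regular": baseline_reg,
        "baseline-irregular": baseline_irr,
        "structure-regular": tuple(truncate_context(s) for s in baseline_reg),
        "structure-irregular": tuple(truncate_context(s) for s in baseline_irr),
        "motor-regular": tuple(
            apply_fingering_manipulation(s, "nonstandard", seed) for s in baseline_reg
        ),
        "motor-irregular": tuple(
            apply_fingering_manipulation(s, "nonstandard", seed) for s in baseline_irr
        ),
    }
    training = tuple(build_training_corpus(seed=seed, keyboard=keyboard))
    return StimulusSet(
        base_sequences=tuple(base),
        conditions=conditions,
        training_corpus=training,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Symbolic encoders
# ---------------------------------------------------------------------------


def encode_structural(seq: StimulusSequence) -> list[str]:
    """Harmonic-function tokens ("function/inversion"); tonality-invariant."""
    return [f"{c.function}/{c.inversion}" for c in seq.chords]


def encode_motor(seq: StimulusSequence) -> list[str]:
    """Fingering tokens ("d1-d2-d3"); independent of the keys pressed."""
    return [f.token for f in seq.fingerings]


def structural_alphabet() -> Alphabet:
    """All function/inversion tokens of the design plus the violation token."""
    tokens: list[str] = []
    for tpl in TEMPLATES.values():
        for func, inv in tpl:
            tok = f"{func}/{inv}"
            if tok not in tokens:
                tokens.append(tok)
    tokens.append("Neapolitan/first")
    return Alphabet(tokens)


def motor_alphabet() -> Alphabet:
    """The six standard plus the two nonstandard fingering tokens."""
    return Alphabet(
        ["-".join(map(str, d)) for d in STANDARD_FINGERINGS + NONSTANDARD_FINGERINGS]
    )


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------


@dataclass
class DesignReport:
    """Outcome of every design assertion plus the headline design counts."""

    checks: dict[str, tuple[bool, str]]
    n_base_sequences: int
    n_distinct_chords: int
    n_standard_fingerings: int
    max_fingerings_per_chord: int
    n_training_sequences: int
    black_key_imbalance: float

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    @property
    def failures(self) -> list[str]:
        return [f"{name}: {msg}" for name, (ok, msg) in self.checks.items() if not ok]

    def summary(self) -> str:
        lines = ["Design validation report", "-" * 40]
        for name, (ok, msg) in self.checks.items():
            lines.append(f"[{'ok' if ok else 'FAIL'}] {name}: {msg}")
        return "\n".join(lines)


def validate_design(stim_set: StimulusSet, black_key_tol: float = 0.5) -> DesignReport:
    """Assert the published design counts and balancing constraints."""
    checks: dict[str, tuple[bool, str]] = {}
    base = stim_set.base_sequences

    n_base = len(base)
    checks["26 base sequences of 5 chords"] = (
        n_base == 26 and all(len(s) == 5 for s in base),
        f"{n_base} sequences, lengths {sorted({len(s) for s in base})}",
    )

    triples = [c.keys for s in base for c in s.chords]
    n_chords = len(set(triples))
    checks["50 distinct chords"] = (n_chords == 50, f"{n_chords} distinct key triples")

    fingerings = {f.digits for s in base for f in s.fingerings}
    nonstandard_used = fingerings - set(STANDARD_FINGERINGS)
    checks["6 standard fingerings, none nonstandard"] = (
        len(fingerings) == 6 and not nonstandard_used,
        f"{sorted(fingerings)}",
    )

    per_chord: dict[tuple[int, int, int], set[tuple[int, int, int]]] = {}
    for s in base:
        for c, f in s.events:
            per_chord.setdefault(c.keys, set()).add(f.digits)
    max_fing = max(len(v) for v in per_chord.values())
    example = max(per_chord.items(), key=lambda kv: len(kv[1]))
    checks["a recurring chord carries 3 fingerings"] = (
        max_fing >= 3,
        f"chord keys {example[0]} with {sorted(example[1])}",
    )

    kb = base[0].chords[0].keyboard
    in_range = all(1 <= k <= kb.n_keys for t in triples for k in t)
    checks["all chords fit the 27-key keyboard"] = (
        in_range, f"keyboard of {kb.n_keys} keys"
    )

    cadence = all(
        s.chords[-2].function == "Dominant" and s.chords[-1].function == "Tonic"
        for s in base
    )
    checks["authentic cadence endings"] = (cadence, "V -> I in every base sequence")

    # penultimate invariance across the six conditions
    invariant = True
    for i in range(len(base)):
        ref_c, ref_f = stim_set.conditions["baseline-regular"][i].penultimate
        for cond_seqs in stim_set.conditions.values():
            c, f = cond_seqs[i].penultimate
            if c.keys != ref_c.keys or f.digits != ref_f.digits:
                invariant = False
    checks["penultimate chord invariant across conditions"] = (
        invariant, "keys and fingers of event 4 identical in all six conditions"
    )

    # Tonic/Neapolitan pitch-content reuse for semitone-apart tonality pairs
    tonalities = {name: pc for name, pc, _, _ in TEST_DESIGN}
    reuse_ok, reuse_pairs = True, []
    for name, pc in tonalities.items():
        upper = [n for n, p in tonalities.items() if p == (pc + 1) % 12]
        if not upper:
            continue
        neap = neapolitan_of(name, kb, _design_lookup(name)[1])
        tonic = _voice(tonalities[upper[0]], "Tonic", "root",
                       _design_lookup(upper[0])[1], kb, upper[0])
        if neap.pitch_class_set != tonic.pitch_class_set:
            reuse_ok = False
        reuse_pairs.append(f"{name}->{upper[0]}")
    checks["Tonic/Neapolitan pitch-content reuse"] = (
        reuse_ok, f"pairs {reuse_pairs}"
    )

    # black/white balance of final chords, regular vs irregular
    reg_black = np.mean(
        [s.chords[-1].n_black_keys for s in stim_set.conditions["baseline-regular"]]
    )
    irr_black = np.mean(
        [s.chords[-1].n_black_keys for s in stim_set.conditions["baseline-irregular"]]
    )
    imbalance = float(abs(reg_black - irr_black))
    checks["black/white key balance of final chords"] = (
        imbalance <= black_key_tol,
        f"|{reg_black:.3f} - {irr_black:.3f}| = {imbalance:.3f} <= {black_key_tol}",
    )

    # training corpus
    train = stim_set.training_corpus
    train_ok = (
        len(train) == 60
        and all(len(s) == 5 for s in train)
        and not any(c.function == "Neapolitan" for s in train for c in s.chords)
        and all(f.standardness == "standard" for s in train for f in s.fingerings)
    )
    checks["training corpus: 60 correct sequences"] = (
        train_ok, f"{len(train)} sequences, regular endings, standard fingerings"
    )

    test_alpha = set(structural_alphabet().symbols) - {"Neapolitan/first"}
    train_tokens = {tok for s in train for tok in encode_structural(s)}
    checks["training tokens within test alphabet minus violations"] = (
        train_tokens <= test_alpha, f"{len(train_tokens)} training tokens"
    )

    return DesignReport(
        checks=checks,
        n_base_sequences=n_base,
        n_distinct_chords=n_chords,
        n_standard_fingerings=len(fingerings & set(STANDARD_FINGERINGS)),
        max_fingerings_per_chord=max_fing,
        n_training_sequences=len(train),
        black_key_imbalance=imbalance,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _seq_record(seq: StimulusSequence) -> dict:
    return {
        "base_id": seq.base_id,
        "tonality": seq.tonality,
        "template": seq.template,
        "condition": {
            "block": seq.condition.block,
            "structure": seq.condition.structure,
            "context": seq.condition.context,
            "movement": seq.condition.movement,
        },
        "events": [
            {
                "keys": list(c.keys),
                "midi": list(c.midi),
                "pitch_classes": list(c.pitch_classes),
                "function": c.function,
                "inversion": c.inversion,
                "fingering": list(f.digits),
            }
            for c, f in seq.events
        ],
    }


def stimuli_to_json(sequences: Iterable[StimulusSequence]) -> str:
    return json.dumps([_seq_record(s) for s in sequences], indent=2)


def stimuli_to_dataframe(sequences: Iterable[StimulusSequence]) -> pd.DataFrame:
    rows = []
    for s in sequences:
        for pos, (c, f) in enumerate(s.events, start=1):
            rows.append(
                {
                    "base_id": s.base_id,
                    "tonality": s.tonality,
                    "template": s.template,
                    "block": s.condition.block,
                    "structure": s.condition.structure,
                    "context": s.condition.context,
                    "movement": s.condition.movement,
                    "position": pos,
                    "keys": "-".join(map(str, c.keys)),
                    "function": c.function,
                    "inversion": c.inversion,
                    "fingering": f.token,
                }
            )
    return pd.DataFrame(rows)
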