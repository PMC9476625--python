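"""Prediction by Partial Matching (PPM) variable-order Markov models.

A PPM model learns n-gram statistics of symbolic sequences up to a bounded
context length and predicts each event by blending maximum-likelihood
estimates from the longest matching context down to an order ``-1`` floor
that is uniform over the declared alphabet.  The escape mechanism (methods
A, C or D) decides how much probability mass each context level passes down
to shorter contexts.  Because the floor is uniform over the full alphabet,
every declared symbol — including symbols never seen in training, such as
violation tokens — receives strictly positive probability, and the
information content (surprisal) ``-log2 p`` of any event is finite.

Two smoothing regimes are provided:

* ``exclusion=False`` (default): interpolated smoothing.  At every order the
  escape mass multiplies the *full* lower-order distribution, for seen and
  unseen symbols alike.  This normalizes exactly and is the common choice in
  music-cognition PPM implementations.
* ``exclusion=True``: classic back-off with symbol exclusion.  Symbols
  predicted at a higher order are excluded from all lower-order estimates;
  seen symbols take their local estimate only.

Training is a pure count over n-grams; fitted models are frozen and never
updated by prediction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "PPM",
    "FittedPPM",
    "EventPrediction",
    "SequencePrediction",
    "train_model",
    "predict_event",
    "predict_sequence",
    "information_content",
]

_FORMAT_VERSION = 1
_ESCAPE_METHODS = ("A", "C", "D")


class Alphabet:
    """Ordered finite set of symbol tokens.

    Every symbol that can occur at prediction time must be declared here,
    including tokens absent from the training corpus.
    """

    def __init__(self, symbols: Iterable[str]):
        symbols = list(symbols)
        if not symbols:
            raise ValueError("alphabet must contain at least one symbol")
        seen = set()
        for s in symbols:
            if not isinstance(s, str) or not s:
                raise ValueError(f"symbols must be non-empty strings, got {s!r}")
            if s in seen:
                raise ValueError(f"duplicate symbol in alphabet: {s!r}")
            seen.add(s)
        self.symbols: tuple[str, ...] = tuple(symbols)
        self._index = {s: i for i, s in enumerate(self.symbols)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, token: object) -> bool:
        return token in self._index

    def __iter__(self):
        return iter(self.symbols)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alphabet) and self.symbols == other.symbols

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"symbol {token!r} is not in the alphabet") from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alphabet({list(self.symbols)!r})"


def information_content(probability: float) -> float:
    """Information content (surprisal) in bits, ``-log2(p)``."""
    if not (0.0 < probability <= 1.0):
        raise ValueError(f"probability must lie in (0, 1], got {probability}")
    return -math.log2(probability)


@dataclass(frozen=True)
class EventPrediction:
    """Predictive distribution at one sequence position and the realized event.

    ``ic_bits`` is the information content of the realized symbol under the
    distribution, ``-log2 p(realized | context)``.
    """

    position: int
    distribution: Mapping[str, float]
    realized: str
    probability: float
    ic_bits: float


@dataclass(frozen=True)
class SequencePrediction:
    """Per-event predictions for one sequence (positions 1..n)."""

    predictions: tuple[EventPrediction, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    @property
    def ic_bits(self) -> np.ndarray:
        return np.array([p.ic_bits for p in self.predictions], dtype=float)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p.probability for p in self.predictions], dtype=float)


class PPM:
    """PPM model specification bound to a training corpus.

    Parameters
    ----------
    corpus
        Non-empty list of symbol sequences. Contexts never cross sequence
        boundaries.
    alphabet
        The closed symbol alphabet. Every corpus symbol must be a member.
    max_order
        Longest context length used (>= 0).
    escape
        Escape method, one of ``"A"``, ``"C"`` (default), ``"D"``.
    exclusion
        Enable PPM symbol exclusion during escape (default off).
    """

    def __init__(
        self,
        corpus: Sequence[Sequence[str]],
        alphabet: Alphabet | Iterable[str],
        max_order: int = 4,
        escape: str = "C",
        exclusion: bool = False,
    ):
        if not isinstance(alphabet, Alphabet):
            alphabet = Alphabet(alphabet)
        if not isinstance(max_order, (int, np.integer)) or max_order < 0:
            raise ValueError(f"max_order must be a non-negative integer, got {max_order}")
        if escape not in _ESCAPE_METHODS:
            raise ValueError(f"escape must be one of {_ESCAPE_METHODS}, got {escape!r}")
        corpus = [tuple(seq) for seq in corpus]
        if not corpus:
            raise ValueError("training corpus is empty")
        for seq in corpus:
            for sym in seq:
                if sym not in alphabet:
                    raise ValueError(f"corpus symbol {sym!r} is not in the alphabet")
        self.corpus = corpus
        self.alphabet = alphabet
        self.max_order = int(max_order)
        self.escape = escape
        self.exclusion = bool(exclusion)

    def fit(self) -> "FittedPPM":
        """Count all n-grams of orders 0..max_order and return a frozen model."""
        counts: dict[tuple[str, ...], dict[str, int]] = {}
        for seq in self.corpus:
            for i, sym in enumerate(seq):
                for order in range(0, min(self.max_order, i) + 1):
                    ctx = tuple(seq[i - order : i])
                    bucket = counts.setdefault(ctx, {})
                    bucket[sym] = bucket.get(sym, 0) + 1
        return FittedPPM(
            alphabet=self.alphabet,
            max_order=self.max_order,
            escape=self.escape,
            exclusion=self.exclusion,
            counts=counts,
        )


class FittedPPM:
    """Frozen PPM model: an immutable n-gram count store plus smoothing rules.

    Prediction never mutates the counts; predicting any number of sequences
    leaves the serialized model bit-identical.
    """

    def __init__(
        self,
        alphabet: Alphabet,
        max_order: int,
        escape: str,
        exclusion: bool,
        counts: Mapping[tuple[str, ...], Mapping[str, int]],
    ):
        if escape not in _ESCAPE_METHODS:
            raise ValueError(f"escape must be one of {_ESCAPE_METHODS}")
        self.alphabet = alphabet
        self.max_order = int(max_order)
        self.escape = escape
        self.exclusion = bool(exclusion)
        self._counts = {
            tuple(ctx): dict(c) for ctx, c in counts.items()
        }
        for ctx, bucket in self._counts.items():
            if len(ctx) > self.max_order:
                raise ValueError(f"context {ctx!r} longer than max_order={max_order}")
            for sym, n in bucket.items():
                if sym not in alphabet or any(s not in alphabet for s in ctx):
                    raise ValueError(f"count entry {ctx!r} -> {sym!r} outside alphabet")
                if n < 0:
                    raise ValueError("negative count")
        self.frozen = True

    # -- count access ------------------------------------------------------

    @property
    def counts(self) -> dict[tuple[str, ...], dict[str, int]]:
        """A defensive copy of the n-gram count table."""
        return {ctx: dict(c) for ctx, c in self._counts.items()}

    def count(self, context: Sequence[str], symbol: str) -> int:
        return self._counts.get(tuple(context), {}).get(symbol, 0)

    # -- smoothing ---------------------------------------------------------

    def _local_and_escape(self, bucket: Mapping[str, int]):
        """Per-symbol local mass and escape mass for one context level."""
        n = sum(bucket.values())
        t = sum(1 for c in bucket.values() if c > 0)
        if n == 0:
            return {}, 1.0
        if self.escape == "A":
            local = {s: c / (n + 1) for s, c in bucket.items() if c > 0}
            esc = 1.0 / (n + 1)
        elif self.escape == "C":
            local = {s: c / (n + t) for s, c in bucket.items() if c > 0}
            esc = t / (n + t)
        else:  # D
            local = {s: (c - 0.5) / n for s, c in bucket.items() if c > 0}
            esc = t / (2.0 * n)
        return local, esc

    def distribution(self, context: Sequence[str]) -> dict[str, float]:
        """Full predictive distribution over the alphabet given a context.

        The context is truncated on the left to ``max_order`` symbols.
        """
        ctx = tuple(context)
        for s in ctx:
            if s not in self.alphabet:
                raise ValueError(f"context symbol {s!r} is not in the alphabet")
        if len(ctx) > self.max_order:
            ctx = ctx[len(ctx) - self.max_order :]
        if self.exclusion:
            dist = self._dist_exclusion(ctx, frozenset())
        else:
            dist = self._dist_interpolated(ctx)
        return dist

    def _dist_interpolated(self, ctx: tuple[str, ...]) -> dict[str, float]:
        # Bottom-up blending: p_k = local_k + esc_k * p_{k-1}; order -1 uniform.
        k = len(self.alphabet)
        p = {s: 1.0 / k for s in self.alphabet}
        for order in range(0, len(ctx) + 1):
            sub = ctx[len(ctx) - order :]
            bucket = self._counts.get(sub)
            if not bucket:
                continue  # unseen context: escape with full mass
            local, esc = self._local_and_escape(bucket)
            p = {s: local.get(s, 0.0) + esc * p[s] for s in self.alphabet}
        return p

    def _dist_exclusion(
        self, ctx: tuple[str, ...], excluded: frozenset[str]
    ) -> dict[str, float]:
        if len(excluded) >= len(self.alphabet):
            # degenerate: nothing left to predict at lower orders
            return {}
        bucket = {
            s: c
            for s, c in self._counts.get(ctx, {}).items()
            if c > 0 and s not in excluded
        }
        if not bucket:
            if ctx:
                return self._dist_exclusion(ctx[1:], excluded)
            remaining = [s for s in self.alphabet if s not in excluded]
            u = 1.0 / len(remaining)
            return {s: u for s in remaining}
        local, esc = self._local_and_escape(bucket)
        seen = frozenset(bucket)
        if ctx:
            lower = self._dist_exclusion(ctx[1:], excluded | seen)
        else:
            remaining = [s for s in self.alphabet if s not in excluded | seen]
            lower = (
                {s: 1.0 / len(remaining) for s in remaining} if remaining else {}
            )
        out = dict.fromkeys(
            (s for s in self.alphabet if s not in excluded), 0.0
        )
        for s, v in local.items():
            out[s] = v
        if lower:
            for s, v in lower.items():
                out[s] += esc * v
        else:
            # no symbols left below: renormalize the local mass
            z = sum(out.values())
            out = {s: v / z for s, v in out.items()}
        return out

    # -- prediction --------------------------------------------------------

    def predict_event(
        self, context: Sequence[str], realized: str, position: int = 1
    ) -> EventPrediction:
        """Predict one event from its context and score the realized symbol."""
        if realized not in self.alphabet:
            raise ValueError(f"realized symbol {realized!r} is not in the alphabet")
        dist = self.distribution(context)
        p = dist[realized]
        return EventPrediction(
            position=position,
            distribution=dist,
            realized=realized,
            probability=p,
            ic_bits=information_content(p),
        )

    def predict_sequence(self, sequence: Sequence[str]) -> SequencePrediction:
        """Score every event of a sequence; context resets at the start."""
        seq = tuple(sequence)
        preds = []
        for i, sym in enumerate(seq):
            ctx = seq[max(0, i - self.max_order) : i]
            preds.append(self.predict_event(ctx, sym, position=i + 1))
        return SequencePrediction(predictions=tuple(preds))

    def mean_ic(self, sequences: Iterable[Sequence[str]]) -> float:
        """Mean per-event information content over a set of sequences."""
        ics = [p.ic_bits for seq in sequences for p in self.predict_sequence(seq)]
        return float(np.mean(ics))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format_version": _FORMAT_VERSION,
            "alphabet": list(self.alphabet.symbols),
            "max_order": self.max_order,
            "escape": self.escape,
            "exclusion": self.exclusion,
            "counts": [
                {"context": list(ctx), "continuations": bucket}
                for ctx, bucket in sorted(self._counts.items())
            ],
        }
        return json.dumps(doc, indent=None, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FittedPPM":
        doc = json.loads(text)
        if doc.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version: {doc.get('format_version')!r}"
            )
        counts = {
            tuple(rec["context"]): {s: int(n) for s, n in rec["continuations"].items()}
            for rec in doc["counts"]
        }
        return cls(
            alphabet=Alphabet(doc["alphabet"]),
            max_order=doc["max_order"],
            escape=doc["escape"],
            exclusion=doc["exclusion"],
            counts=counts,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "FittedPPM":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def summary(self) -> str:
        n_ctx = len(self._counts)
        n_events = sum(self._counts.get((), {}).values())
        lines = [
            "Fitted PPM model",
            f"  alphabet size : {len(self.alphabet)}",
            f"  max order     : {self.max_order}",
            f"  escape method : {self.escape}",
            f"  exclusion     : {'on' if self.exclusion else 'off'}",
            f"  contexts seen : {n_ctx}",
            f"  events trained: {n_events}",
        ]
        return "\n".join(lines)


# -- spec-surface convenience wrappers --------------------------------------


def train_model(
    corpus: Sequence[Sequence[str]],
    alphabet: Alphabet | Iterable[str],
    max_order: int = 4,
    escape_method: str = "C",
    exclusion_enabled: bool = False,
) -> FittedPPM:
    """Train a frozen PPM model on a corpus (see :class:`PPM`)."""
    return PPM(
        corpus, alphabet, max_order=max_order, escape=escape_method,
        exclusion=exclusion_enabled,
    ).fit()


def predict_event(
    model: FittedPPM, context: Sequence[str], realized: str
) -> EventPrediction:
    return model.predict_event(context, realized)


def predict_sequence(model: FittedPPM, sequence: Sequence[str]) -> SequencePrediction:
    return model.predict_sequence(sequence)
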