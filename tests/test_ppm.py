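"""PPM model: training counts, escape smoothing, oracle equivalence, freezing."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cadenza.ppm import (
    PPM,
    Alphabet,
    FittedPPM,
    information_content,
    train_model,
)

# ---------------------------------------------------------------------------
# independent oracle: per-symbol recursive evaluation of the escape equations
# ---------------------------------------------------------------------------


def _local_esc(bucket, escape):
    n = sum(bucket.values())
    t = len([c for c in bucket.values() if c > 0])
    if n == 0:
        return {}, 1.0
    if escape == "A":
        return {s: c / (n + 1) for s, c in bucket.items()}, 1 / (n + 1)
    if escape == "C":
        return {s: c / (n + t) for s, c in bucket.items()}, t / (n + t)
    return {s: (c - 0.5) / n for s, c in bucket.items()}, t / (2 * n)


def oracle_interpolated(counts, alphabet, ctx, sym, escape):
    """Top-down recursion: p(sym|ctx) = local(sym|ctx) + esc(ctx) p(sym|ctx[1:])."""
    if ctx is None:
        return 1.0 / len(alphabet)
    bucket = counts.get(tuple(ctx), {})
    shorter = ctx[1:] if ctx else None
    local, esc = _local_esc(bucket, escape)
    return local.get(sym, 0.0) + esc * oracle_interpolated(
        counts, alphabet, shorter, sym, escape
    )


def oracle_exclusion(counts, alphabet, ctx, sym, escape):
    """Per-symbol walk down the escape chain with symbol exclusion: the
    probability is the product of escape masses above the first level where
    the symbol is countable, times its local mass there."""
    excluded = set()
    prob = 1.0
    context = tuple(ctx)
    while True:
        bucket = {
            s: c for s, c in counts.get(context, {}).items()
            if c > 0 and s not in excluded
        }
        if bucket:
            local, esc = _local_esc(bucket, escape)
            if excluded | set(bucket) == set(alphabet):
                # nothing left to escape to: the escape mass is renormalized
                # over this level's local estimates
                return prob * local[sym] / (1.0 - esc) if sym in local else 0.0
            if sym in local:
                return prob * local[sym]
            prob *= esc
            excluded |= set(bucket)
        if context:
            context = context[1:]
            continue
        remaining = [s for s in alphabet if s not in excluded]
        return prob * (1.0 / len(remaining)) if sym in remaining else 0.0


def _random_corpus(rng, alphabet, n_seqs, max_len):
    return [
        [str(rng.choice(alphabet)) for _ in range(rng.integers(1, max_len + 1))]
        for _ in range(n_seqs)
    ]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_training_counts_enumerate_ngrams():
    model = train_model([["a", "b", "a", "b"]], ["a", "b"], max_order=1)
    assert model.count(("a",), "b") == 2
    assert model.count(("b",), "a") == 1
    assert model.count((), "a") == 2
    assert model.count((), "b") == 2


def test_training_is_deterministic_and_frozen():
    corpus = [["a", "b", "b"], ["b", "a"]]
    m1 = train_model(corpus, ["a", "b"], max_order=2)
    m2 = train_model(corpus, ["a", "b"], max_order=2)
    assert m1.to_json() == m2.to_json()
    assert m1.frozen


def test_training_rejects_bad_input():
    with pytest.raises(ValueError, match="empty"):
        train_model([], ["a"], max_order=1)
    with pytest.raises(ValueError, match="'z'"):
        train_model([["a", "z"]], ["a", "b"], max_order=1)
    with pytest.raises(ValueError):
        PPM([["a"]], ["a"], max_order=-1)


def test_contexts_do_not_cross_sequence_boundaries():
    model = train_model([["a", "b"], ["b", "a"]], ["a", "b"], max_order=2)
    # "b" at the end of sequence 1 never continues into sequence 2's "b"
    assert model.count(("b",), "b") == 0
    assert model.count(("a", "b"), "b") == 0


# ---------------------------------------------------------------------------
# information content
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("p,expected", [(1.0, 0.0), (0.5, 1.0), (0.25, 2.0)])
def test_information_content_closed_form(p, expected):
    assert information_content(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p", [0.0, -0.1, 1.1])
def test_information_content_rejects_invalid(p):
    with pytest.raises(ValueError):
        information_content(p)


# ---------------------------------------------------------------------------
# prediction: hand-worked values (computed by hand before the implementation)
# ---------------------------------------------------------------------------

_HAND_VALUES = {
    # corpus [[a,b,a,b]], alphabet {a,b,c}, max_order 1, context (a,)
    "C": {"b": 22 / 27, "a": 4 / 27, "c": 1 / 27},
    "A": {"b": 37 / 45, "a": 7 / 45, "c": 1 / 45},
    "D": {"b": 83 / 96, "a": 11 / 96, "c": 2 / 96},
}


@pytest.mark.parametrize("escape", ["A", "C", "D"])
def test_escape_recursion_matches_hand_arithmetic(escape):
    model = train_model([["a", "b", "a", "b"]], ["a", "b", "c"], 1, escape)
    dist = model.distribution(("a",))
    for sym, expected in _HAND_VALUES[escape].items():
        assert dist[sym] == pytest.approx(expected, abs=1e-12)


def test_exclusion_backoff_matches_hand_arithmetic():
    # escape C with exclusion: p(b|a)=2/3, p(a|a)=2/9, p(c|a)=1/9
    model = train_model([["a", "b", "a", "b"]], ["a", "b", "c"], 1, "C", True)
    dist = model.distribution(("a",))
    assert dist["b"] == pytest.approx(2 / 3, abs=1e-12)
    assert dist["a"] == pytest.approx(2 / 9, abs=1e-12)
    assert dist["c"] == pytest.approx(1 / 9, abs=1e-12)


def test_singleton_alphabet_is_certain():
    model = train_model([["a", "a"]], ["a"], max_order=1)
    pred = model.predict_event(("a",), "a")
    assert pred.probability == pytest.approx(1.0, abs=1e-12)
    assert pred.ic_bits == pytest.approx(0.0, abs=1e-12)


def test_unseen_symbol_more_surprising_than_frequent_continuation(struct_model):
    dist = struct_model.distribution(("Dominant/root",))
    ic_seen = -math.log2(dist["Tonic/root"])
    ic_unseen = -math.log2(dist["Neapolitan/first"])
    assert ic_unseen > ic_seen


def test_prediction_rejects_out_of_alphabet_symbols():
    model = train_model([["a", "b"]], ["a", "b"], max_order=1)
    with pytest.raises(ValueError):
        model.predict_event(("a",), "z")
    with pytest.raises(ValueError):
        model.distribution(("z",))


# ---------------------------------------------------------------------------
# oracle equivalence + distribution invariants over random small models
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("exclusion", [False, True])
def test_oracle_equivalence_random_models(seed, exclusion):
    """Implementation equals an independently coded recursive evaluation of
    the escape equations on alphabets <= 4 and orders <= 2, to 1e-10."""
    rng = np.random.default_rng(seed)
    alphabet = ["a", "b", "c", "d"][: rng.integers(2, 5)]
    corpus = _random_corpus(rng, alphabet, n_seqs=rng.integers(1, 5), max_len=6)
    max_order = int(rng.integers(0, 3))
    for escape in ("A", "C", "D"):
        model = PPM(corpus, alphabet, max_order, escape, exclusion).fit()
        counts = model.counts
        oracle = oracle_exclusion if exclusion else oracle_interpolated
        for ctx_len in range(max_order + 1):
            for ctx in itertools.product(alphabet, repeat=ctx_len):
                dist = model.distribution(ctx)
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
                for sym in alphabet:
                    assert dist[sym] > 0
                    expected = oracle(counts, alphabet, ctx, sym, escape)
                    assert dist[sym] == pytest.approx(expected, abs=1e-10)


@given(
    corpus=hst.lists(
        hst.lists(hst.sampled_from(["a", "b", "c"]), min_size=1, max_size=6),
        min_size=1, max_size=4,
    ),
    max_order=hst.integers(min_value=0, max_value=3),
    escape=hst.sampled_from(["A", "C", "D"]),
    exclusion=hst.booleans(),
    ctx=hst.lists(hst.sampled_from(["a", "b", "c"]), max_size=3),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_distribution_normalizes_and_is_positive(corpus, max_order, escape, exclusion, ctx):
    """Every predictive distribution sums to 1 and gives every alphabet
    symbol (seen or unseen) strictly positive probability."""
    model = PPM(corpus, ["a", "b", "c", "z"], max_order, escape, exclusion).fit()
    dist = model.distribution(ctx)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(p > 0 for p in dist.values())
    assert set(dist) == {"a", "b", "c", "z"}


@pytest.mark.parametrize("seed", range(4))
def test_frequency_monotonicity(seed):
    """More frequent continuations of a context never get lower probability."""
    rng = np.random.default_rng(100 + seed)
    alphabet = ["a", "b", "c", "d"]
    corpus = _random_corpus(rng, alphabet, n_seqs=6, max_len=8)
    for escape in ("A", "C", "D"):
        model = PPM(corpus, alphabet, max_order=2, escape=escape).fit()
        for ctx, bucket in model.counts.items():
            dist = model.distribution(ctx)
            for x, y in itertools.permutations(alphabet, 2):
                if bucket.get(x, 0) > bucket.get(y, 0):
                    assert dist[x] >= dist[y]


def test_frozen_purity_serialization_unchanged_by_prediction(struct_model, stim_set):
    from cadenza.stimuli import encode_structural

    before = struct_model.to_json()
    for seq in stim_set.base_sequences:
        struct_model.predict_sequence(encode_structural(seq))
    assert struct_model.to_json() == before


# ---------------------------------------------------------------------------
# sequence prediction
# ---------------------------------------------------------------------------


def test_predict_sequence_empty_and_deterministic():
    model = train_model([["a", "b", "a"]], ["a", "b"], max_order=2)
    assert len(model.predict_sequence([])) == 0
    s1 = model.predict_sequence(["a", "b", "a", "b"]).ic_bits
    s2 = model.predict_sequence(["a", "b", "a", "b"]).ic_bits
    np.testing.assert_array_equal(s1, s2)


def test_predict_sequence_positions_and_context_reset():
    model = train_model([["a", "b", "a"]], ["a", "b"], max_order=2)
    pred = model.predict_sequence(["a", "b"])
    assert [p.position for p in pred] == [1, 2]
    # position 1 uses the empty context
    assert pred.predictions[0].probability == pytest.approx(
        model.distribution(())["a"], abs=1e-12
    )


@pytest.mark.parametrize("escape", ["A", "C", "D"])
def test_order0_ic_matches_direct_closed_form(escape):
    """For an order-0 model, every position's IC equals the order-0 escape
    closed form computed directly from the count table."""
    corpus = [["a", "b", "b", "c"], ["b", "c", "c"]]
    alphabet = ["a", "b", "c", "d"]
    model = PPM(corpus, alphabet, max_order=0, escape=escape).fit()
    bucket = model.counts[()]
    n = sum(bucket.values())
    t = len(bucket)
    k = len(alphabet)

    def order0_p(sym):
        c = bucket.get(sym, 0)
        if escape == "A":
            return c / (n + 1) + (1 / (n + 1)) / k
        if escape == "C":
            return c / (n + t) + (t / (n + t)) / k
        return (c - 0.5) / n * (c > 0) + (t / (2 * n)) / k

    seq = ["a", "b", "c", "d"]
    ics = model.predict_sequence(seq).ic_bits
    for sym, ic in zip(seq, ics):
        assert ic == pytest.approx(-math.log2(order0_p(sym)), abs=1e-9)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_json_round_trip_is_lossless(struct_model):
    restored = FittedPPM.from_json(struct_model.to_json())
    assert restored.to_json() == struct_model.to_json()
    ctx = ("Tonic/root", "Submediant/root")
    assert restored.distribution(ctx) == struct_model.distribution(ctx)


def test_json_rejects_unknown_format_version(struct_model):
    import json

    doc = json.loads(struct_model.to_json())
    doc["format_version"] = 999
    with pytest.raises(ValueError, match="format version"):
        FittedPPM.from_json(json.dumps(doc))


def test_alphabet_validation():
    with pytest.raises(ValueError):
        Alphabet([])
    with pytest.raises(ValueError):
        Alphabet(["a", "a"])
    with pytest.raises(ValueError):
        Alphabet(["a", ""])
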