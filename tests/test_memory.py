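"""Hierarchical sequence memory: entropy bookkeeping, boundary-entropy
chunking against an independent replay oracle, layer formation,
consolidation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conceptboard.fixtures import ArtificialLanguageSpec, gen_artificial_language
from conceptboard.memory import (
    ChunkerConfig,
    Distribution,
    Event,
    INFINITE_SURPRISE,
    SequenceMemory,
    TransitionMatrix,
    ViewpointSpec,
    entropy,
    information_content,
)


def feed(mem: SequenceMemory, symbols, vp="x"):
    out = []
    for t, s in enumerate(symbols):
        out.extend(mem.observe(Event(t=t, viewpoints={vp: s})))
    return out


def fresh(vp="x", **cfg) -> SequenceMemory:
    defaults = dict(max_levels=2, consolidate_every=0)
    defaults.update(cfg)
    mem = SequenceMemory(ChunkerConfig(**defaults))
    mem.register_viewpoint(ViewpointSpec(id=vp))
    return mem


# ----------------------------------------------------------------------
# independent replay oracle for the boundary-entropy decision

def oracle_boundaries(stream, tol=1e-9):
    """From-scratch replay of every entropy-change decision with plain
    dicts: add-one smoothing over the running alphabet, counts as of
    before the current observation, boundary after the arriving symbol
    when its context's predicted entropy exceeds the previous context's.
    """
    counts: dict[str, dict[str, int]] = {}
    alphabet: list[str] = []
    bounds = []

    def h(ctx, alpha):
        row = counts.get(ctx, {})
        total = sum(row.values()) + len(alpha)
        return -sum(
            (row.get(s, 0) + 1) / total * math.log2((row.get(s, 0) + 1) / total)
            for s in alpha
        )

    prev = None
    for i, sym in enumerate(stream):
        if prev is not None:
            alpha = alphabet + ([sym] if sym not in alphabet else [])
            if h(sym, alpha) - h(prev, alpha) > tol:
                bounds.append(i + 1)
            counts.setdefault(prev, {})
            counts[prev][sym] = counts[prev].get(sym, 0) + 1
        if sym not in alphabet:
            alphabet.append(sym)
        prev = sym
    return bounds


# ----------------------------------------------------------------------

class TestEntropy:
    def test_closed_forms(self):
        uniform4 = Distribution(list("abcd"), {s: 0.25 for s in "abcd"})
        assert entropy(uniform4) == pytest.approx(2.0)
        point = Distribution(["a", "b"], {"a": 1.0, "b": 0.0})
        assert entropy(point) == 0.0

    def test_matches_direct_summation(self):
        d = Distribution(["a", "b", "c"], {"a": 0.5, "b": 0.25, "c": 0.25})
        direct = 0.0
        for p in (0.5, 0.25, 0.25):
            direct -= p * math.log2(p)
        assert entropy(d) == pytest.approx(direct)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            Distribution(["a", "b"], {"a": 0.7, "b": 0.7})

    def test_information_content(self):
        d = Distribution(["a", "b", "c"], {"a": 0.25, "b": 0.75, "c": 0.0})
        assert information_content(d, "a") == pytest.approx(2.0)
        assert information_content(d, "c") == INFINITE_SURPRISE
        one = Distribution(["a"], {"a": 1.0})
        assert information_content(one, "a") == 0.0
        with pytest.raises(KeyError):
            information_content(one, "zzz")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_expected_surprise_equals_entropy(self, raw):
        z = sum(raw)
        probs = {f"s{i}": p / z for i, p in enumerate(raw)}
        d = Distribution(list(probs), probs)
        expected = sum(p * information_content(d, s) for s, p in probs.items())
        assert expected == pytest.approx(entropy(d))


class TestPredict:
    def test_row_normalization_without_smoothing(self):
        m = TransitionMatrix()
        for _ in range(3):
            m.increment("a", "b")
        m.increment("a", "c")
        d = m.predict("a", ["b", "c"], smoothing=0.0)
        assert d.probs == {"b": 0.75, "c": 0.25}

    def test_empty_row_smoothing_is_uniform(self):
        d = TransitionMatrix().predict("never-seen", list("abcde"))
        assert all(p == pytest.approx(0.2) for p in d.probs.values())

    def test_unknown_level_rejected(self):
        mem = fresh()
        feed(mem, ["a", "b"])
        with pytest.raises(ValueError):
            mem.predict("x", 5, "a")

    def test_mixture_matches_hand_computed_weights(self):
        """Entropy-weighted superposition: weights proportional to 2^-H."""
        mem = SequenceMemory(ChunkerConfig(max_levels=0))
        mem.register_viewpoint(ViewpointSpec(id="p"))
        mem.register_viewpoint(ViewpointSpec(id="q"))
        for t, (a, b) in enumerate(zip("aabab", "xyzxy")):
            mem.observe(Event(t=t, viewpoints={"p": a, "q": b}))
        dp = mem.predict("p", 0, "a")
        dq = mem.predict("q", 0, "x")
        wp, wq = 2.0 ** -entropy(dp), 2.0 ** -entropy(dq)
        mixed = mem.predict_mixture(["p", "q"], 0, {"p": "a", "q": "x"})
        for s in dp.alphabet:
            expected = (wp * dp.p(s) + wq * dq.p(s)) / (wp + wq)
            norm = sum(
                (wp * dp.p(u) + wq * dq.p(u)) / (wp + wq)
                for u in set(dp.alphabet) | set(dq.alphabet)
            )
            assert mixed[s] == pytest.approx(expected / norm)


class TestObserve:
    def test_boundaries_fall_at_word_ends(self):
        """On the designed corpus (deterministic within-word transitions,
        uniform between words) every post-burn-in boundary is a word end."""
        events, truth = gen_artificial_language(ArtificialLanguageSpec(n_tokens=600))
        mem = fresh("syl")
        for e in events:
            mem.observe(Event(t=e["t"], viewpoints=e["vp"]))
        found = [b for b in mem.boundaries("syl") if b > 100]
        assert found and set(found) <= set(truth)

    def test_constant_stream_never_chunks_after_burn_in(self):
        mem = fresh()
        closed = feed(mem, ["z"] * 200)
        assert [c for c in closed if c.end > 10] == []

    def test_largest_entropy_increase_wins_competition(self):
        """With two generators registering positive entropy changes at the
        same event, only the larger one chunks; the loser's candidate
        boundary is held and then forgotten."""
        mem = SequenceMemory(ChunkerConfig(max_levels=1, forgetting_period=3))
        mem.register_viewpoint(ViewpointSpec(id="A"))
        mem.register_viewpoint(ViewpointSpec(id="B"))
        # at the fourth event both generators see an entropy rise:
        # A jumps by ~0.19 bits (novel symbol after a trained context),
        # B by ~0.085 bits (novel symbol in a 3-symbol alphabet)
        a_stream = ["a", "a", "a", "b"]
        b_stream = ["x", "y", "x", "z"]
        closed = []
        for t, (a, b) in enumerate(zip(a_stream, b_stream)):
            closed.extend(mem.observe(Event(t=t, viewpoints={"A": a, "B": b})))
        assert closed, "the larger positive change must close a chunk"
        assert all(c.label.startswith("A") for c in closed)
        assert mem.pending_boundaries["B"]
        for t in range(4, 9):
            mem.observe(Event(t=t, viewpoints={"A": "a", "B": "x"}))
        assert not mem.pending_boundaries["B"]

    def test_incremental_equals_replay_oracle(self):
        """For corpora up to 200 events the incremental chunker's level-0
        boundaries equal the independent from-scratch replay."""
        events, _ = gen_artificial_language(
            ArtificialLanguageSpec(n_tokens=200, seed=11)
        )
        stream = [e["vp"]["syl"] for e in events]
        mem = fresh("syl")
        for e in events:
            mem.observe(Event(t=e["t"], viewpoints=e["vp"]))
        assert mem.boundaries("syl") == oracle_boundaries(stream)

    def test_missing_viewpoint_rejected(self):
        mem = fresh()
        with pytest.raises(KeyError):
            mem.observe(Event(t=0, viewpoints={"other": "a"}))


class TestPromote:
    def test_first_chunk_creates_singleton_upper_sequence(self):
        mem = fresh()
        closed = feed(mem, ["a", "a", "b"])
        assert [c.end for c in closed if c.level == 0] == [3]
        layer1 = mem.hierarchies["x"].layers[1]
        assert len(layer1.sequence) == 1
        assert layer1.matrix.counts == {}

    def test_repeated_chunk_reuses_label_and_counts_transition(self):
        """Recurring identical chunk contents share one label, and each
        recurrence increments the upper layer's transition counts so that
        they recount exactly from the upper sequence's bigrams."""
        events, _ = gen_artificial_language(
            ArtificialLanguageSpec(n_tokens=150, seed=11)
        )
        mem = fresh("syl")
        for e in events:
            mem.observe(Event(t=e["t"], viewpoints=e["vp"]))
        layer1 = mem.hierarchies["syl"].layers[1]
        repeated = [l for l in layer1.alphabet if layer1.sequence.count(l) > 1]
        assert repeated, "identical chunk contents must share a label"
        recount: dict[str, dict[str, int]] = {}
        for a, b in zip(layer1.sequence, layer1.sequence[1:]):
            recount.setdefault(a, {}).setdefault(b, 0)
            recount[a][b] += 1
        assert recount == layer1.matrix.counts

    def test_down_links_count_chunk_symbols_with_multiplicity(self):
        mem = fresh()
        closed = feed(mem, ["a", "a", "b"])
        chunk = closed[0]
        down = mem.hierarchies["x"].down[0].counts[chunk.label]
        assert down == {"a": 2, "b": 1}

    def test_max_levels_zero_disables_chunking(self):
        mem = fresh(max_levels=0)
        closed = feed(mem, ["a", "a", "b", "c", "d"])
        assert closed == []
        assert len(mem.hierarchies["x"].layers) == 1


@pytest.fixture(scope="module")
def trained():
    events, _ = gen_artificial_language(ArtificialLanguageSpec(n_tokens=400))
    mem = fresh("syl", max_levels=3)
    for e in events:
        mem.observe(Event(t=e["t"], viewpoints=e["vp"]))
    return mem


class TestInvariants:
    def test_chunk_extents_tile_each_level(self, trained):
        for layer in trained.hierarchies["syl"].layers:
            if not layer.chunks:
                continue
            assert layer.chunks[0].start == 0
            for prev, cur in zip(layer.chunks, layer.chunks[1:]):
                assert cur.start == prev.end
            assert layer.chunks[-1].end <= len(layer.sequence)

    def test_down_links_recomputable_from_extents(self, trained):
        hier = trained.hierarchies["syl"]
        for level, down in enumerate(hier.down):
            recount: dict[str, dict[str, int]] = {}
            for c in hier.layers[level].chunks:
                for s in hier.layers[level].sequence[c.start : c.end]:
                    recount.setdefault(c.label, {}).setdefault(s, 0)
                    recount[c.label][s] += 1
            assert recount == down.counts

    def test_identical_corpus_gives_identical_memory(self):
        events, _ = gen_artificial_language(ArtificialLanguageSpec(n_tokens=300))
        dumps = []
        for _ in range(2):
            mem = fresh("syl")
            for e in events:
                mem.observe(Event(t=e["t"], viewpoints=e["vp"]))
            dumps.append(mem.to_json())
        assert dumps[0] == dumps[1]


class TestCodeLength:
    def test_repeating_sequence_approaches_zero(self):
        mem = fresh(max_levels=0)
        feed(mem, ["a", "b"] * 300)
        assert mem.mean_code_length() < 0.2

    def test_iid_uniform_approaches_log2_n(self):
        rng = np.random.default_rng(1)
        mem = fresh(max_levels=0)
        feed(mem, [f"s{k}" for k in rng.integers(0, 4, 3000)])
        assert mem.mean_code_length() == pytest.approx(2.0, abs=0.15)

    def test_tiny_memory_is_finite(self):
        mem = fresh(max_levels=0)
        feed(mem, ["only"])
        assert 0.0 <= mem.mean_code_length() < math.inf
        with pytest.raises(ValueError):
            SequenceMemory().mean_code_length()


class TestConsolidate:
    def test_local_minimum_is_fixed_point(self):
        mem = fresh()
        feed(mem, ["a", "a", "b"] * 4)
        mem.consolidate()
        before = mem.to_json()
        mem.consolidate()
        assert mem.to_json() == before

    def test_redundant_labels_merge_and_code_length_drops(self):
        """Early mislabeled chunks leave labels used in the same contexts
        as the eventual word labels; consolidation merges them and the
        mean code length strictly decreases."""
        events, _ = gen_artificial_language(ArtificialLanguageSpec(n_tokens=600))
        mem = fresh("syl")
        for e in events:
            mem.observe(Event(t=e["t"], viewpoints=e["vp"]))
        layer1 = mem.hierarchies["syl"].layers[1]
        before_labels = len(layer1.alphabet)
        before = mem.mean_code_length()
        mem.consolidate()
        after = mem.mean_code_length()
        assert len(layer1.alphabet) < before_labels
        assert after < before

    def test_never_increases_code_length(self):
        rng = np.random.default_rng(9)
        for trial in range(3):
            mem = fresh()
            feed(mem, [f"s{k}" for k in rng.integers(0, 3, 80)])
            before = mem.mean_code_length()
            mem.consolidate()
            assert mem.mean_code_length() <= before + 1e-12
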