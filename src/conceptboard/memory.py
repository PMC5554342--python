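"""Incremental, entropy-driven hierarchical sequence memory.

The memory learns a layered model of one or more synchronized symbol
streams (*viewpoints*).  Each layer holds a symbol sequence and a
first-order Markov transition model over that layer's alphabet.  As each
event arrives, one generator per viewpoint measures the change in the
entropy of its next-symbol prediction; the generator with the largest
positive entropy increase wins access to the global workspace and closes
its open chunk.  The chunk is labeled with a symbol — via the conceptual
space of the layer above, so that identical chunks share a label — and the
label is appended to the next layer up, where the same boundary test
applies recursively.  The result is a tree of chunks over the raw event
stream, together with up/down link statistics between adjacent layers.

Segmentation is driven purely by boundary entropy: within a word of an
artificial language, the successor distribution is sharp; at the word's
final symbol, the successor distribution spreads over all possible next
words, the predicted entropy jumps, and the chunk closes exactly at the
word end.

The entropy comparison uses the transition counts as they stood *before*
the current observation (the model the generator was actually predicting
with), smoothed over a common alphabet.  Counts are updated afterwards.
Learning is therefore fully deterministic and order-dependent: the same
corpus in the same order always produces the same memory.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .space import GAP, ConceptualSpace, SpaceConfig, Trajectory, abstract

logger = logging.getLogger(__name__)

__all__ = [
    "Distribution",
    "TransitionMatrix",
    "LevelLinkMatrix",
    "Chunk",
    "Event",
    "MemoryLayer",
    "ViewpointSpec",
    "ChunkerConfig",
    "SequenceMemory",
    "entropy",
    "information_content",
    "INFINITE_SURPRISE",
]

#: Distinguished value returned for a zero-probability symbol.
INFINITE_SURPRISE = math.inf

#: Golden-angle increment for procedurally placed seed points of purely
#: symbolic alphabets (keeps seeds distinct and deterministic).
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class Distribution:
    """A probability distribution over an alphabet."""

    alphabet: list[str]
    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if any(p < 0 for p in self.probs.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must be >= 0 and sum to 1, got {total}")
        missing = set(self.alphabet) - set(self.probs)
        if missing:
            raise ValueError(f"distribution missing symbols {sorted(missing)}")

    def p(self, symbol: str) -> float:
        return self.probs.get(symbol, 0.0)


def entropy(d: Distribution) -> float:
    """Shannon entropy H(D) = -sum p(s) log2 p(s), in bits (0 log 0 := 0)."""
    return -sum(p * math.log2(p) for p in d.probs.values() if p > 0)


def information_content(d: Distribution, s: str) -> float:
    """Surprise h(D, s) = -log2 p(s), in bits; infinite for p(s) = 0."""
    if s not in d.probs:
        raise KeyError(f"symbol {s!r} not in the distribution's alphabet")
    p = d.probs[s]
    if p == 0:
        return INFINITE_SURPRISE
    return -math.log2(p)


class TransitionMatrix:
    """First-order transition counts for one memory layer."""

    def __init__(self) -> None:
        self.counts: dict[str, dict[str, int]] = {}

    def increment(self, context: str, nxt: str) -> None:
        self.counts.setdefault(context, {}).setdefault(nxt, 0)
        self.counts[context][nxt] += 1

    def row_total(self, context: str) -> int:
        return sum(self.counts.get(context, {}).values())

    def predict(self, context: str, alphabet: list[str], smoothing: float = 1.0) -> Distribution:
        """Row-normalized counts with add-``smoothing`` over ``alphabet``.

        An empty row with smoothing yields the uniform distribution; with
        ``smoothing=0`` an empty row is an error.
        """
        if not alphabet:
            raise ValueError("empty alphabet")
        row = self.counts.get(context, {})
        total = sum(row.values()) + smoothing * len(alphabet)
        if total == 0:
            raise ValueError(f"no observations for context {context!r} and no smoothing")
        probs = {s: (row.get(s, 0) + smoothing) / total for s in alphabet}
        return Distribution(alphabet, probs)

    def to_dict(self) -> dict:
        return {c: dict(r) for c, r in self.counts.items()}


class LevelLinkMatrix:
    """Counts linking symbols of one layer to symbols one layer away.

    A higher-level symbol connects *down* to every symbol inside its chunk
    (with multiplicity); a lower-level symbol connects *up* to every symbol
    whose chunk contains it.
    """

    def __init__(self, direction: str) -> None:
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        self.direction = direction
        self.counts: dict[str, dict[str, int]] = {}

    def increment(self, a: str, b: str, n: int = 1) -> None:
        self.counts.setdefault(a, {}).setdefault(b, 0)
        self.counts[a][b] += n

    def to_dict(self) -> dict:
        return {c: dict(r) for c, r in self.counts.items()}


@dataclass
class Chunk:
    """A labeled contiguous extent of one layer's sequence.

    ``start``/``end`` index the sequence at ``level`` (end exclusive); the
    label is a symbol of level + 1.
    """

    level: int
    label: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Event:
    """One synchronized time step of the input stream."""

    t: int
    viewpoints: dict[str, object]


@dataclass
class ViewpointSpec:
    """A basic viewpoint (raw stream) or a linked pair of basic viewpoints.

    A linked viewpoint's alphabet is the set of pairs actually observed
    from the two source alphabets.  ``dim`` is the dimensionality of a
    continuous basic viewpoint's base conceptual space (symbolic
    viewpoints get procedurally seeded 2-D spaces).  ``gap`` is the base
    space's gap parameter, and ``discriminability`` — for continuous
    viewpoints — is the distance beyond which a point classified into an
    existing region is nonetheless discriminable from its seed and mints
    a new symbol; without it a continuous stream would never grow an
    alphabet past its first symbol.
    """

    id: str
    kind: str = "basic"  # "basic" | "linked"
    sources: tuple[str, str] | None = None
    dim: int = 2
    gap: float = 0.0
    discriminability: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("basic", "linked"):
            raise ValueError(f"unknown viewpoint kind {self.kind!r}")
        if self.kind == "linked" and (self.sources is None or len(self.sources) != 2):
            raise ValueError("linked viewpoint needs exactly two source viewpoints")


@dataclass
class ChunkerConfig:
    """Global learning parameters.

    sampling_rate : nominal event rate in Hz (40 Hz preferred); metadata
        for interpreting time indices, not used in the update equations.
    max_levels : highest layer index that chunking may create (0 disables
        chunking entirely, leaving a flat first-order model).
    forgetting_period : events after which a losing generator's candidate
        boundary is discarded.
    consolidate_every : events between automatic consolidation passes
        (0 = never consolidate automatically).
    abstraction_coeffs : spectral coefficients kept per dimension when a
        chunk trajectory is abstracted into a label point.
    delta_tolerance : entropy changes at or below this (bits) do not count
        as increases; guards the boundary test against floating-point
        summation noise between distributions with identical structure.
    """

    sampling_rate: float = 40.0
    max_levels: int = 3
    forgetting_period: int = 20
    consolidate_every: int = 500
    abstraction_coeffs: int = 8
    delta_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.forgetting_period <= 0:
            raise ValueError("sampling_rate and forgetting_period must be positive")
        if self.max_levels < 0 or self.consolidate_every < 0:
            raise ValueError("max_levels and consolidate_every must be >= 0")


class MemoryLayer:
    """One level of the hierarchy: a sequence, its model, and its space."""

    def __init__(self, level: int, space: ConceptualSpace):
        self.level = level
        self.sequence: list[str] = []
        self.alphabet: list[str] = []
        self.matrix = TransitionMatrix()
        self.space = space
        self.chunks: list[Chunk] = []  # chunks over THIS layer's sequence

    def append(self, symbol: str) -> None:
        if symbol not in self.alphabet:
            self.alphabet.append(symbol)
        self.sequence.append(symbol)


class _Hierarchy:
    """Per-viewpoint stack of layers plus the generator state."""

    def __init__(self, spec: ViewpointSpec, config: ChunkerConfig):
        self.spec = spec
        base_space = ConceptualSpace(spec.dim, SpaceConfig(gap=spec.gap), prefix=f"{spec.id}:")
        self.layers: list[MemoryLayer] = [MemoryLayer(0, base_space)]
        self.pointers: list[int] = [0]  # open-chunk start per level
        self.up: list[LevelLinkMatrix] = []  # up[k]: level k -> level k+1
        self.down: list[LevelLinkMatrix] = []  # down[k]: level k+1 -> level k
        self.last_entropy: float | None = None
        self.last_distribution: Distribution | None = None
        self._symbolic_seed_count = 0
        self._config = config

    def layer(self, level: int) -> MemoryLayer:
        return self.layers[level]

    def ensure_level(self, level: int) -> MemoryLayer:
        while len(self.layers) <= level:
            below = self.layers[-1]
            k = self._config.abstraction_coeffs
            dim = below.space.dim * k
            space = ConceptualSpace(
                dim,
                SpaceConfig(seed_tolerance=1e-3),
                prefix=f"{self.spec.id}.L{len(self.layers)}:",
            )
            self.layers.append(MemoryLayer(len(self.layers), space))
            self.pointers.append(len(self.layers[-1].sequence))
            self.up.append(LevelLinkMatrix("up"))
            self.down.append(LevelLinkMatrix("down"))
        return self.layers[level]

    def symbolic_seed(self) -> np.ndarray:
        """Deterministic, mutually distinct seed for a purely symbolic token."""
        k = self._symbolic_seed_count
        self._symbolic_seed_count += 1
        angle = k * _GOLDEN_ANGLE
        point = np.zeros(self.layers[0].space.dim)
        point[0] = math.cos(angle)
        if len(point) > 1:
            point[1] = math.sin(angle)
        return point


class SequenceMemory:
    """The layered sequence memory and its incremental chunker."""

    def __init__(self, config: ChunkerConfig | None = None):
        self.config = config or ChunkerConfig()
        self.hierarchies: dict[str, _Hierarchy] = {}
        self.event_count = 0
        #: losing generators' candidate boundaries: vp -> [(event, position, dH)]
        self.pending_boundaries: dict[str, list[tuple[int, int, float]]] = {}

    # -- registration --------------------------------------------------

    def register_viewpoint(self, spec: ViewpointSpec) -> None:
        if spec.id in self.hierarchies:
            raise ValueError(f"viewpoint {spec.id!r} already registered")
        if spec.kind == "linked":
            for src in spec.sources:
                if src not in self.hierarchies:
                    raise ValueError(f"linked viewpoint source {src!r} not registered")
        self.hierarchies[spec.id] = _Hierarchy(spec, self.config)
        self.pending_boundaries[spec.id] = []

    def viewpoint_ids(self) -> list[str]:
        return list(self.hierarchies)

    # -- prediction ----------------------------------------------------

    def predict(
        self, viewpoint: str, level: int, context: str, smoothing: float = 1.0
    ) -> Distribution:
        """Smoothed next-symbol distribution at one layer, given one context."""
        hier = self._hier(viewpoint)
        if level >= len(hier.layers):
            raise ValueError(f"viewpoint {viewpoint!r} has no level {level}")
        layer = hier.layers[level]
        return layer.matrix.predict(context, layer.alphabet, smoothing)

    def predict_mixture(
        self, viewpoints: list[str], level: int, contexts: dict[str, str]
    ) -> dict[str, float]:
        """Entropy-weighted superposition of per-viewpoint predictions.

        Each viewpoint's distribution is weighted in proportion to
        ``2 ** -H`` (sharper predictions count for more) and the weighted
        distributions are summed per symbol and renormalized.  Alphabets
        need not agree; the result ranges over their union.
        """
        dists = {v: self.predict(v, level, contexts[v]) for v in viewpoints}
        weights = {v: 2.0 ** (-entropy(d)) for v, d in dists.items()}
        z = sum(weights.values())
        mixed: dict[str, float] = {}
        for v, d in dists.items():
            w = weights[v] / z
            for s, p in d.probs.items():
                mixed[s] = mixed.get(s, 0.0) + w * p
        total = sum(mixed.values())
        return {s: p / total for s, p in mixed.items()}

    # -- observation ---------------------------------------------------

    def observe(self, event: Event) -> list[Chunk]:
        """Ingest one event; returns the chunks closed this step (if any).

        Per viewpoint: symbolize the value (via the base conceptual space
        for continuous values), measure the entropy change between the
        prediction from the previous context and the prediction from the
        new one (both under the pre-observation counts), then append and
        update counts.  The single generator with the largest positive
        entropy change wins the workspace competition and closes its open
        chunk, which is promoted to the next layer; ties break in favor of
        the earliest-registered viewpoint.
        """
        self.event_count += 1
        deltas: dict[str, float] = {}
        symbols: dict[str, str] = {}
        for vp_id, hier in self.hierarchies.items():
            value = self._event_value(event, hier.spec, symbols)
            if value is None:
                continue
            sym = self._symbolize(hier, value)
            symbols[vp_id] = sym
            layer0 = hier.layers[0]
            if layer0.sequence:
                prev = layer0.sequence[-1]
                alphabet = layer0.alphabet + ([sym] if sym not in layer0.alphabet else [])
                d_prev = layer0.matrix.predict(prev, alphabet)
                d_new = layer0.matrix.predict(sym, alphabet)
                deltas[vp_id] = entropy(d_new) - entropy(d_prev)
                layer0.matrix.increment(prev, sym)
                hier.last_entropy = entropy(d_new)
                hier.last_distribution = d_new
            layer0.append(sym)

        closed: list[Chunk] = []
        tol = self.config.delta_tolerance
        positive = {v: dh for v, dh in deltas.items() if dh > tol}
        if positive:
            winner = max(positive, key=lambda v: (positive[v], -list(self.hierarchies).index(v)))
            for vp_id, dh in positive.items():
                if vp_id == winner:
                    continue
                # losing candidate boundary, kept until the forgetting period
                pos = len(self.hierarchies[vp_id].layers[0].sequence)
                self.pending_boundaries[vp_id].append((self.event_count, pos, dh))
            closed.extend(self._close_chunk(self.hierarchies[winner], level=0))
        self._forget()
        if self.config.consolidate_every and self.event_count % self.config.consolidate_every == 0:
            self.consolidate()
        return closed

    def _event_value(self, event: Event, spec: ViewpointSpec, symbols: dict[str, str]):
        if spec.kind == "basic":
            if spec.id not in event.viewpoints:
                raise KeyError(f"event {event.t} missing viewpoint {spec.id!r}")
            return event.viewpoints[spec.id]
        a, b = spec.sources
        if a in symbols and b in symbols:
            return f"{symbols[a]}&{symbols[b]}"
        return None

    def _symbolize(self, hier: _Hierarchy, value) -> str:
        """Map a raw viewpoint value to a level-0 symbol.

        Strings are symbols already (assigned a procedural seed on first
        sight).  Numeric values are classified in the base conceptual
        space under the current expectation; a point falling in a gap
        region (or an empty space) seeds a new symbol.
        """
        space = hier.layers[0].space
        if isinstance(value, str):
            if value not in hier.layers[0].alphabet and value not in space.symbols:
                space.add_seed(hier.symbolic_seed(), value)
            return value
        point = np.atleast_1d(np.asarray(value, dtype=float))
        if not space.symbols:
            return space.add_seed(point)
        dist = None
        layer0 = hier.layers[0]
        if layer0.sequence and hier.last_distribution is not None:
            d = hier.last_distribution
            if set(d.alphabet) >= set(space.symbols):
                dist = {s: d.p(s) for s in space.symbols}
                z = sum(dist.values())
                if z > 0:
                    dist = {s: p / z for s, p in dist.items()}
                else:
                    dist = None
        sym = space.classify(point, dist)
        if sym == GAP:
            sym = space.add_seed(point)
        elif (
            hier.spec.discriminability is not None
            and float(np.linalg.norm(point - space.seed(sym))) > hier.spec.discriminability
        ):
            sym = space.add_seed(point)
        return sym

    # -- chunk closure and promotion ------------------------------------

    def _close_chunk(self, hier: _Hierarchy, level: int) -> list[Chunk]:
        layer = hier.layers[level]
        start, end = hier.pointers[level], len(layer.sequence)
        if end <= start:
            return []
        hier.pointers[level] = end
        if level + 1 > self.config.max_levels:
            logger.info(
                "viewpoint %s: chunk at level %d reached max_levels, not promoted",
                hier.spec.id,
                level,
            )
            return []
        return self._promote(hier, level, start, end)

    def _promote(self, hier: _Hierarchy, level: int, start: int, end: int) -> list[Chunk]:
        """Label a closed chunk and append the label one layer up.

        The chunk's symbols trace a trajectory through the level's
        conceptual space; its spectral abstraction is the label's point in
        the space above.  Identical chunks therefore always share a label,
        while distinct contents mint distinct labels (consolidation may
        merge them later).  The boundary test then applies recursively at
        the upper layer.
        """
        layer = hier.layers[level]
        upper = hier.ensure_level(level + 1)
        content = layer.sequence[start:end]
        traj = Trajectory(np.vstack([layer.space.seed(s) for s in content]))
        point = abstract(traj, self.config.abstraction_coeffs)
        label = upper.space.add_seed(point)
        chunk = Chunk(level=level, label=label, start=start, end=end)
        layer.chunks.append(chunk)
        for s in content:
            hier.down[level].increment(label, s)
            hier.up[level].increment(s, label)

        closed = [chunk]
        delta_h = None
        if upper.sequence:
            prev = upper.sequence[-1]
            alphabet = upper.alphabet + ([label] if label not in upper.alphabet else [])
            d_prev = upper.matrix.predict(prev, alphabet)
            d_new = upper.matrix.predict(label, alphabet)
            delta_h = entropy(d_new) - entropy(d_prev)
            upper.matrix.increment(prev, label)
        upper.append(label)
        if delta_h is not None and delta_h > self.config.delta_tolerance:
            closed.extend(self._close_chunk(hier, level + 1))
        return closed

    def _forget(self) -> None:
        horizon = self.event_count - self.config.forgetting_period
        for vp_id, pending in self.pending_boundaries.items():
            self.pending_boundaries[vp_id] = [p for p in pending if p[0] > horizon]

    # -- code length and consolidation ----------------------------------

    def mean_code_length(self) -> float:
        """Mean bits per stored symbol, over every layer of every viewpoint.

        Each symbol's code length is its surprise under the smoothed
        first-order model of its layer, conditioned on its predecessor
        (the first symbol of a layer is coded against the uniform
        distribution over that layer's alphabet).
        """
        total_bits = 0.0
        n = 0
        for hier in self.hierarchies.values():
            for layer in hier.layers:
                if not layer.sequence:
                    continue
                total_bits += math.log2(len(layer.alphabet))
                n += 1
                for i in range(1, len(layer.sequence)):
                    d = layer.matrix.predict(layer.sequence[i - 1], layer.alphabet)
                    total_bits += information_content(d, layer.sequence[i])
                    n += 1
        if n == 0:
            raise ValueError("empty memory")
        return total_bits / n

    def consolidate(self) -> "SequenceMemory":
        """Greedy re-optimization of chunk-label category membership.

        Repeatedly tries merging pairs of labels at every layer above the
        base, accepting a merge only if it strictly reduces the mean code
        length; stops at a local minimum.  Merging rewrites history — the
        label's past occurrences are relabeled — so meanings can change
        retrospectively.  The mean code length never increases.
        """
        improved = True
        while improved:
            improved = False
            base = self.mean_code_length()
            for vp_id, hier in self.hierarchies.items():
                for level in range(1, len(hier.layers)):
                    alphabet = hier.layers[level].alphabet
                    for i in range(len(alphabet)):
                        for j in range(i + 1, len(alphabet)):
                            trial = copy.deepcopy(self)
                            trial._merge_labels(vp_id, level, alphabet[i], alphabet[j])
                            if trial.mean_code_length() < base - 1e-12:
                                self._merge_labels(vp_id, level, alphabet[i], alphabet[j])
                                improved = True
                                break
                        if improved:
                            break
                    if improved:
                        break
                if improved:
                    break
        return self

    def _merge_labels(self, vp_id: str, level: int, keep: str, drop: str) -> None:
        """Replace every occurrence of ``drop`` with ``keep`` at one layer."""
        hier = self._hier(vp_id)
        layer = hier.layers[level]
        layer.sequence = [keep if s == drop else s for s in layer.sequence]
        layer.alphabet = [s for s in layer.alphabet if s != drop]
        for chunk in hier.layers[level - 1].chunks:
            if chunk.label == drop:
                chunk.label = keep
        # drop's seed disappears; keep's seed stands for the merged category
        space = layer.space
        if drop in space.symbols:
            k = space.symbols.index(drop)
            del space.symbols[k]
            del space._seeds[k]
        self._rebuild_statistics(hier)

    def _rebuild_statistics(self, hier: _Hierarchy) -> None:
        """Recompute all transition and link matrices from the sequences."""
        for layer in hier.layers:
            matrix = TransitionMatrix()
            for a, b in zip(layer.sequence, layer.sequence[1:]):
                matrix.increment(a, b)
            layer.matrix = matrix
        for level in range(len(hier.up)):
            up = LevelLinkMatrix("up")
            down = LevelLinkMatrix("down")
            layer = hier.layers[level]
            for chunk in layer.chunks:
                for s in layer.sequence[chunk.start : chunk.end]:
                    down.increment(chunk.label, s)
                    up.increment(s, chunk.label)
            hier.up[level] = up
            hier.down[level] = down

    # -- introspection and IO -------------------------------------------

    def boundaries(self, viewpoint: str, level: int = 0) -> list[int]:
        """Chunk end positions (exclusive indices) at one layer."""
        hier = self._hier(viewpoint)
        return [c.end for c in hier.layers[level].chunks]

    def _hier(self, viewpoint: str) -> _Hierarchy:
        if viewpoint not in self.hierarchies:
            raise KeyError(f"unknown viewpoint {viewpoint!r}")
        return self.hierarchies[viewpoint]

    def to_json(self) -> str:
        doc = {"event_count": self.event_count, "viewpoints": {}}
        for vp_id, hier in self.hierarchies.items():
            doc["viewpoints"][vp_id] = {
                "kind": hier.spec.kind,
                "sources": hier.spec.sources,
                "layers": [
                    {
                        "level": layer.level,
                        "sequence": layer.sequence,
                        "alphabet": layer.alphabet,
                        "transitions": layer.matrix.to_dict(),
                        "chunks": [
                            {"label": c.label, "start": c.start, "end": c.end}
                            for c in layer.chunks
                        ],
                    }
                    for layer in hier.layers
                ],
                "up_links": [m.to_dict() for m in hier.up],
                "down_links": [m.to_dict() for m in hier.down],
            }
        return json.dumps(doc, indent=1)
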