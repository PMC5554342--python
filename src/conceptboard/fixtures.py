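"""Synthetic corpora and sentence fixtures.

Everything here is generated programmatically and deterministically: the
artificial segmentation language (known word inventory, hence known
ground-truth boundaries), the three reference sentences with their
category lexicons, reference binding graphs and chunk trees, and the
multi-viewpoint "John loves Mary" event stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bridge import AttachmentRule, ChunkNode, RoleMap
from .control import CATEGORY_TO_KIND, Lexicon
from .memory import ViewpointSpec

__all__ = [
    "ArtificialLanguageSpec",
    "gen_artificial_language",
    "SentenceFixture",
    "fixture",
    "FIXTURE_NAMES",
    "gen_jlm",
    "write_jsonl",
    "read_jsonl",
]


# ----------------------------------------------------------------------
# artificial segmentation language

@dataclass
class ArtificialLanguageSpec:
    """A lexicon of symbol-sequence words emitted i.i.d.

    Within-word transitions are deterministic given the lexicon; the
    successor of a word-final symbol is distributed over the word-initial
    symbols per the selection probabilities, so predictive entropy jumps
    exactly at word ends — the ground truth the chunker is scored against.
    """

    lexicon: list[tuple[str, ...]] = field(
        default_factory=lambda: [
            ("tu", "pi", "ro"),
            ("go", "la", "bu"),
            ("bi", "da", "ku"),
        ]
    )
    probabilities: list[float] | None = None  # uniform if absent
    n_tokens: int = 900
    seed: int = 7
    viewpoint: str = "syl"

    def __post_init__(self) -> None:
        if not self.lexicon or any(len(w) == 0 for w in self.lexicon):
            raise ValueError("lexicon words must be non-empty")
        symbols = [s for w in self.lexicon for s in w]
        if len(set(symbols)) != len(symbols):
            raise ValueError("word-internal symbols must be globally unique")


def gen_artificial_language(spec: ArtificialLanguageSpec):
    """Generate the token stream and its ground-truth boundaries.

    Returns ``(events, boundaries)`` where events are JSON-Lines-ready
    dicts ``{"t": k, "vp": {viewpoint: symbol}}`` and boundaries are the
    exclusive end indices of each complete word in the stream.
    """
    rng = np.random.default_rng(spec.seed)
    probs = spec.probabilities
    if probs is None:
        probs = [1.0 / len(spec.lexicon)] * len(spec.lexicon)
    events, boundaries = [], []
    t = 0
    while t < spec.n_tokens:
        word = spec.lexicon[rng.choice(len(spec.lexicon), p=probs)]
        for s in word:
            if t >= spec.n_tokens:
                break
            events.append({"t": t, "vp": {spec.viewpoint: s}})
            t += 1
        else:
            boundaries.append(t)
    return events, boundaries


def write_jsonl(events: list[dict], path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps(e, ensure_ascii=False) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ----------------------------------------------------------------------
# sentence fixtures

@dataclass
class SentenceFixture:
    name: str
    tokens: list[str]
    lexicon: Lexicon
    vocabulary: dict[str, str]  # word -> structure-assembly kind
    pool_sizes: dict[str, int]
    reference_graph: nx.Graph
    chunk_tree: ChunkNode
    role_map: RoleMap


#: shared category lexicon for all fixtures and queries
BASE_LEXICON = Lexicon(
    {
        "cat": "noun",
        "mat": "noun",
        "dog": "noun",
        "couch": "noun",
        "is": "localizer",
        "on": "prep",
        "in": "prep",
        "sees": "tverb",
        "met": "tverb",
        "has": "aux",
        "two": "num",
        "very": "adv",
        "tired": "adj",
        "dancers": "noun",
        "Bill-Gates": "noun",
        "Dallas": "noun",
        "where": "wh",
        "Where": "wh",
        "who": "wh",
        "Who": "wh",
    }
)

#: role map shared by the fixture chunk trees: chunk categories are
#: phrase-like (NP, VP, ...) but carry no theoretical commitment — they
#: are just the labels the hand-specified chunkings use.
FIXTURE_ROLE_MAP = RoleMap(
    kinds={
        "S": "S",
        "NP": "N",
        "VP": "V",
        "AUXP": "Aux",
        "ADJP": "Adj",
        "ADVP": "Adv",
        "NUMP": "Num",
        "PPP": "PP",
    },
    attachments=[
        AttachmentRule(child="NP", role="pn", target="sibling", sibling="PPP", direction="preceding"),
        AttachmentRule(child="NP", role="t", target="sibling", sibling="VP", direction="preceding"),
        AttachmentRule(child="NP", role="n", target="parent", parent="S"),
        AttachmentRule(child="NP", role="pn", target="parent", parent="PPP"),
        AttachmentRule(child="VP", role="v", target="parent", parent="S"),
        AttachmentRule(child="AUXP", role="va", target="sibling", sibling="VP", direction="following"),
        AttachmentRule(child="PPP", role="pv", target="sibling", sibling="VP", direction="preceding"),
        AttachmentRule(child="NUMP", role="nm", target="parent", parent="NP"),
        AttachmentRule(child="ADJP", role="na", target="parent", parent="NP"),
        AttachmentRule(child="ADVP", role="ad", target="parent", parent="ADJP"),
    ],
)


def _graph(edges: list[tuple[str, str, str]], words: set[str]) -> nx.Graph:
    g = nx.Graph()
    for a, role, b in edges:
        for node in (a, b):
            if node not in g:
                if node in words:
                    g.add_node(node, label=node, kind="word")
                else:
                    g.add_node(node, label=node.rstrip("0123456789"), kind="structure")
        g.add_edge(a, b, role=role)
    return g


def _np(token: str) -> ChunkNode:
    return ChunkNode("NP", [ChunkNode.leaf(token)])


def _fixture_cat_is_on_mat() -> SentenceFixture:
    tokens = ["cat", "is", "on", "mat"]
    words = set(tokens)
    edges = [
        ("cat", "word", "N1"),
        ("S1", "n", "N1"),
        ("is", "word", "V1"),
        ("S1", "v", "V1"),
        ("on", "word", "PP1"),
        ("V1", "pv", "PP1"),
        ("PP1", "pn", "N2"),
        ("mat", "word", "N2"),
    ]
    tree = ChunkNode(
        "S",
        [
            _np("cat"),
            ChunkNode("VP", [ChunkNode.leaf("is")]),
            ChunkNode("PPP", [ChunkNode.leaf("on")]),
            _np("mat"),
        ],
    )
    return SentenceFixture(
        name="cat-is-on-mat",
        tokens=tokens,
        lexicon=BASE_LEXICON,
        vocabulary={w: CATEGORY_TO_KIND[BASE_LEXICON[w]] for w in tokens},
        pool_sizes={"N": 2, "V": 1, "S": 1, "PP": 1},
        reference_graph=_graph(edges, words),
        chunk_tree=tree,
        role_map=FIXTURE_ROLE_MAP,
    )


def _fixture_cat_sees_cat() -> SentenceFixture:
    tokens = ["cat", "sees", "cat"]
    words = set(tokens)
    edges = [
        ("cat", "word", "N1"),
        ("S1", "n", "N1"),
        ("sees", "word", "V1"),
        ("S1", "v", "V1"),
        ("V1", "t", "N2"),
        ("cat", "word", "N2"),
    ]
    tree = ChunkNode(
        "S",
        [_np("cat"), ChunkNode("VP", [ChunkNode.leaf("sees")]), _np("cat")],
    )
    return SentenceFixture(
        name="cat-sees-cat",
        tokens=tokens,
        lexicon=BASE_LEXICON,
        vocabulary={w: CATEGORY_TO_KIND[BASE_LEXICON[w]] for w in set(tokens)},
        pool_sizes={"N": 2, "V": 1, "S": 1},
        reference_graph=_graph(edges, words),
        chunk_tree=tree,
        role_map=FIXTURE_ROLE_MAP,
    )


def _fixture_bill_gates() -> SentenceFixture:
    tokens = ["Bill-Gates", "has", "met", "two", "very", "tired", "dancers", "in", "Dallas"]
    words = set(tokens)
    edges = [
        ("Bill-Gates", "word", "N1"),
        ("S1", "n", "N1"),
        ("has", "word", "Aux1"),
        ("met", "word", "V1"),
        ("S1", "v", "V1"),
        ("V1", "va", "Aux1"),
        ("two", "word", "Num1"),
        ("N2", "nm", "Num1"),
        ("very", "word", "Adv1"),
        ("tired", "word", "Adj1"),
        ("N2", "na", "Adj1"),
        ("Adj1", "ad", "Adv1"),
        ("dancers", "word", "N2"),
        ("V1", "t", "N2"),
        ("in", "word", "PP1"),
        ("V1", "pv", "PP1"),
        ("PP1", "pn", "N3"),
        ("Dallas", "word", "N3"),
    ]
    tree = ChunkNode(
        "S",
        [
            _np("Bill-Gates"),
            ChunkNode("AUXP", [ChunkNode.leaf("has")]),
            ChunkNode("VP", [ChunkNode.leaf("met")]),
            ChunkNode(
                "NP",
                [
                    ChunkNode("NUMP", [ChunkNode.leaf("two")]),
                    ChunkNode("ADJP", [ChunkNode("ADVP", [ChunkNode.leaf("very")]), ChunkNode.leaf("tired")]),
                    ChunkNode.leaf("dancers"),
                ],
            ),
            ChunkNode("PPP", [ChunkNode.leaf("in"), _np("Dallas")]),
        ],
    )
    return SentenceFixture(
        name="bill-gates",
        tokens=tokens,
        lexicon=BASE_LEXICON,
        vocabulary={w: CATEGORY_TO_KIND[BASE_LEXICON[w]] for w in tokens},
        pool_sizes={"N": 3, "V": 1, "S": 1, "Aux": 1, "Adj": 1, "Adv": 1, "Num": 1, "PP": 1},
        reference_graph=_graph(edges, words),
        chunk_tree=tree,
        role_map=FIXTURE_ROLE_MAP,
    )


_FIXTURES = {
    "cat-is-on-mat": _fixture_cat_is_on_mat,
    "cat-sees-cat": _fixture_cat_sees_cat,
    "bill-gates": _fixture_bill_gates,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture(name: str) -> SentenceFixture:
    """Look up a sentence fixture by name."""
    if name not in _FIXTURES:
        raise LookupError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    return _FIXTURES[name]()


# ----------------------------------------------------------------------
# multi-viewpoint corpus

#: phoneme-level transcription of *John loves Mary* with word spans
_JLM_WORDS = [
    ("John", ["dZ", "Q", "n"], "♂"),          # ♂
    ("loves", ["l", "V", "v", "z"], "♥"),      # ♥
    ("Mary", ["m", "e@", "r", "i"], "♀"),      # ♀
]


def gen_jlm(seed: int = 0):
    """Synchronized multi-viewpoint event stream for *John loves Mary*.

    Four basic viewpoints per event: the phoneme symbol, smooth synthetic
    pitch and amplitude contours (continuous, to exercise symbolization
    through the conceptual space), and a semantic tag aligned with the
    spoken word.  Also returns the ViewpointSpec of the linked phoneme-by-semantics
    viewpoint, whose alphabet is pairs from the two source alphabets.
    """
    rng = np.random.default_rng(seed)
    n = sum(len(ph) for _, ph, _ in _JLM_WORDS)
    pitch = 120.0 + 25.0 * np.sin(np.linspace(0.0, np.pi, n))
    amplitude = 0.5 + 0.3 * np.sin(np.linspace(0.3, 2.6, n))
    pitch = pitch + rng.normal(0.0, 0.5, n)
    amplitude = np.clip(amplitude + rng.normal(0.0, 0.01, n), 0.0, 1.0)
    events = []
    t = 0
    for _, phonemes, emoji in _JLM_WORDS:
        for ph in phonemes:
            events.append(
                {
                    "t": t,
                    "vp": {
                        "phoneme": ph,
                        "pitch": round(float(pitch[t]), 4),
                        "amplitude": round(float(amplitude[t]), 4),
                        "emoji": emoji,
                    },
                }
            )
            t += 1
    linked = ViewpointSpec(id="phoneme&emoji", kind="linked", sources=("phoneme", "emoji"))
    return events, linked
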