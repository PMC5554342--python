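"""Control circuits: parsing a token stream into the blackboard and
answering questions from the bound structure.

Control is deterministic: a rule table over category sequences selects a
per-word command script, and the sequence-node reservoir presents category
n-grams in order (a chain of nodes, each firing only after its
predecessor) with an exact-association readout.  Executing a script
drives concept and structure assemblies, opens the main<->sub gates
for the constructions being built, and arms exactly the connection nodes
whose binding is expected — co-activity then ignites those nodes' WM
populations in the dynamics.

The word-presentation regime shapes the activity profile the blackboard
produces: each word's concept assembly and newly recruited structure
assemblies are driven from word onset; when the word can be bound into
the developing structure, the control circuit completes the binding and
releases the drives partway through the word interval, so total activity
drops.  A word that cannot yet bind (the sentence-initial word, or a
modifier whose head has not arrived) is held active until its binding
becomes possible, so total activity does not decline in its interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .blackboard import Blackboard, ConnectionNode
from .dynamics import ActivityTrace

__all__ = [
    "Lexicon",
    "categorize",
    "ParseError",
    "OpenQueryError",
    "TrainingError",
    "WordStep",
    "build_script",
    "execute_script",
    "parse",
    "recognize_query",
    "answer",
    "AnswerScript",
    "SequenceNode",
    "Reservoir",
    "train_readout",
    "default_reservoir",
    "CATEGORY_TO_KIND",
    "ROLE_TAGS",
]


class ParseError(Exception):
    """The category sequence is not covered by the rule table."""


class OpenQueryError(Exception):
    """A query's cued word has no binding in the blackboard."""


class TrainingError(Exception):
    """Contradictory readout training examples."""


class Lexicon(dict):
    """word -> syntactic/semantic category (e.g. is -> localizer)."""

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self), fh)


def categorize(word: str, lexicon: Lexicon) -> str:
    """Deterministic category lookup; unknown words are an error."""
    if word not in lexicon:
        raise LookupError(f"word {word!r} is not in the lexicon")
    return lexicon[word]


#: category -> structure-assembly kind a word of that category binds
CATEGORY_TO_KIND = {
    "noun": "N",
    "localizer": "V",
    "tverb": "V",
    "aux": "Aux",
    "num": "Num",
    "adv": "Adv",
    "adj": "Adj",
    "prep": "PP",
}

#: blackboard role -> thematic tag fed back to the reservoir
ROLE_TAGS = {"n": "Agent", "t": "Theme", "pn": "Location"}
_TAG_PRIORITY = ("n", "t", "pn")


@dataclass
class WordStep:
    """The control commands issued for one word interval."""

    word: str
    recruit: list[str] = field(default_factory=list)  # kinds, in order
    drive: list[str] = field(default_factory=list)  # words + assembly names
    open_gates: list[tuple[str, str]] = field(default_factory=list)
    arm: list[tuple] = field(default_factory=list)  # expected bindings
    release: list[str] = field(default_factory=list)
    # arm entries: ("word", word, assembly) | ("role", a, role_a, b, role_b)


# ----------------------------------------------------------------------
# rule table: category sequence -> command-script builder

def _loc_sentence(tokens: list[str]) -> list[WordStep]:
    """noun localizer prep noun — e.g. *cat is on mat*."""
    w1, w2, w3, w4 = tokens
    return [
        WordStep(w1, recruit=["N"], drive=[w1, "N1"], arm=[("word", w1, "N1")]),
        WordStep(
            w2,
            recruit=["V", "S"],
            drive=[w2, "V1", "S1"],
            open_gates=[("N", "n"), ("S", "n"), ("S", "v"), ("V", "v")],
            arm=[
                ("word", w2, "V1"),
                ("role", "S1", "n", "N1", "n"),
                ("role", "S1", "v", "V1", "v"),
            ],
            release=[w1, "N1", w2, "V1", "S1"],
        ),
        WordStep(
            w3,
            recruit=["PP"],
            drive=[w3, "PP1", "V1"],
            open_gates=[("V", "pv"), ("PP", "pv")],
            arm=[("word", w3, "PP1"), ("role", "V1", "pv", "PP1", "pv")],
            release=[w3, "PP1", "V1"],
        ),
        WordStep(
            w4,
            recruit=["N"],
            drive=[w4, "N2", "PP1"],
            open_gates=[("PP", "pn"), ("N", "pn")],
            arm=[("word", w4, "N2"), ("role", "PP1", "pn", "N2", "pn")],
            release=[w4, "N2", "PP1"],
        ),
    ]


def _transitive(tokens: list[str]) -> list[WordStep]:
    """noun tverb noun — e.g. *cat sees cat* (same in-situ assembly twice)."""
    w1, w2, w3 = tokens
    return [
        WordStep(w1, recruit=["N"], drive=[w1, "N1"], arm=[("word", w1, "N1")]),
        WordStep(
            w2,
            recruit=["V", "S"],
            drive=[w2, "V1", "S1"],
            open_gates=[("N", "n"), ("S", "n"), ("S", "v"), ("V", "v")],
            arm=[
                ("word", w2, "V1"),
                ("role", "S1", "n", "N1", "n"),
                ("role", "S1", "v", "V1", "v"),
            ],
            release=[w1, "N1", w2, "V1", "S1"],
        ),
        WordStep(
            w3,
            recruit=["N"],
            drive=[w3, "N2", "V1"],
            open_gates=[("V", "t"), ("N", "t")],
            arm=[("word", w3, "N2"), ("role", "V1", "t", "N2", "t")],
            release=[w3, "N2", "V1"],
        ),
    ]


def _aux_np_pp(tokens: list[str]) -> list[WordStep]:
    """noun aux tverb num adv adj noun prep noun — the nine-word sentence
    *Bill-Gates has met two very tired dancers in Dallas*.

    The first word has nothing to bind to and is held active until the
    subject binding completes at the second word.  The numerator triggers
    anticipatory recruitment of the noun assembly it modifies; the adverb
    cannot bind until its adjective arrives and is held.
    """
    bg, has, met, two, very, tired, dancers, inw, dallas = tokens
    return [
        WordStep(bg, recruit=["N"], drive=[bg, "N1"], arm=[("word", bg, "N1")]),
        WordStep(
            has,
            recruit=["S", "Aux"],
            drive=[has, "S1", "Aux1", "N1"],
            open_gates=[("N", "n"), ("S", "n")],
            arm=[("word", has, "Aux1"), ("role", "S1", "n", "N1", "n")],
            release=[bg, "N1", has, "S1", "Aux1"],
        ),
        WordStep(
            met,
            recruit=["V"],
            drive=[met, "V1", "S1", "Aux1"],
            open_gates=[("S", "v"), ("V", "v"), ("V", "va"), ("Aux", "va")],
            arm=[
                ("word", met, "V1"),
                ("role", "S1", "v", "V1", "v"),
                ("role", "V1", "va", "Aux1", "va"),
            ],
            release=[met, "V1", "S1", "Aux1"],
        ),
        WordStep(
            two,
            recruit=["Num", "N"],
            drive=[two, "Num1", "N2"],
            open_gates=[("N", "nm"), ("Num", "nm")],
            arm=[("word", two, "Num1"), ("role", "N2", "nm", "Num1", "nm")],
            release=[two, "Num1", "N2"],
        ),
        WordStep(very, recruit=["Adv"], drive=[very, "Adv1"], arm=[("word", very, "Adv1")]),
        WordStep(
            tired,
            recruit=["Adj"],
            drive=[tired, "Adj1", "N2", "Adv1"],
            open_gates=[("Adj", "na"), ("N", "na"), ("Adj", "ad"), ("Adv", "ad")],
            arm=[
                ("word", tired, "Adj1"),
                ("role", "N2", "na", "Adj1", "na"),
                ("role", "Adj1", "ad", "Adv1", "ad"),
            ],
            release=[tired, "Adj1", "N2", "Adv1", very],
        ),
        WordStep(
            dancers,
            drive=[dancers, "N2", "V1"],
            open_gates=[("V", "t"), ("N", "t")],
            arm=[("word", dancers, "N2"), ("role", "V1", "t", "N2", "t")],
            release=[dancers, "N2", "V1"],
        ),
        WordStep(
            inw,
            recruit=["PP"],
            drive=[inw, "PP1", "V1"],
            open_gates=[("V", "pv"), ("PP", "pv")],
            arm=[("word", inw, "PP1"), ("role", "V1", "pv", "PP1", "pv")],
            release=[inw, "PP1", "V1"],
        ),
        WordStep(
            dallas,
            recruit=["N"],
            drive=[dallas, "N3", "PP1"],
            open_gates=[("PP", "pn"), ("N", "pn")],
            arm=[("word", dallas, "N3"), ("role", "PP1", "pn", "N3", "pn")],
            release=[dallas, "N3", "PP1"],
        ),
    ]


RULE_TABLE = {
    ("noun", "localizer", "prep", "noun"): _loc_sentence,
    ("noun", "tverb", "noun"): _transitive,
    ("noun", "aux", "tverb", "num", "adv", "adj", "noun", "prep", "noun"): _aux_np_pp,
}


def build_script(tokens: list[str], lexicon: Lexicon) -> list[WordStep]:
    """Pure function from the category sequence to the command script."""
    if not tokens:
        raise ParseError("empty token stream")
    categories = tuple(categorize(w, lexicon) for w in tokens)
    if categories not in RULE_TABLE:
        raise ParseError(f"category sequence {categories} not covered by the rule table")
    return RULE_TABLE[categories](tokens)


def execute_script(
    blackboard: Blackboard,
    script: list[WordStep],
    word_ms: float = 200.0,
    drive_ms: float = 140.0,
    dt: float = 1.0,
    tail_ms: float = 100.0,
    record: bool = False,
) -> tuple[ActivityTrace | None, list[float]]:
    """Run a command script against the blackboard dynamics.

    Each word owns a ``word_ms`` interval: drives and gates are applied at
    onset, armed bindings may ignite while the drives last (``drive_ms``),
    then the step's releases are cleared and activity decays until the
    next word.  Returns the recorded trace (if requested) and word onsets.
    """
    onsets: list[float] = []
    frames: list[np.ndarray] = []
    times: list[float] = []
    t = 0.0

    def advance(ms: float, nodes: list[ConnectionNode] | None, scan: bool) -> None:
        nonlocal t
        for _ in range(int(round(ms / dt))):
            blackboard.step(dt, scan=scan, nodes=nodes)
            t += dt
            if record:
                times.append(t)
                frames.append(np.fromiter(blackboard.net.activities().values(), dtype=float))

    blackboard.settle(60.0, dt)
    t = 0.0
    for step in script:
        onsets.append(t)
        for kind in step.recruit:
            blackboard.recruit(kind)
        for name in step.drive:
            if name in blackboard.concepts:
                blackboard.drive_word(name, 1.0)
            else:
                blackboard.drive(blackboard.assembly_by_name(name).main, 1.0)
        for kind, role in step.open_gates:
            blackboard.open_role_gates(kind, role, on=True)
        armed = [_resolve_node(blackboard, ref) for ref in step.arm]
        advance(drive_ms, armed, scan=True)
        for name in step.release:
            if name in blackboard.concepts:
                blackboard.drive_word(name, 0.0)
            else:
                blackboard.drive(blackboard.assembly_by_name(name).main, 0.0)
        for kind, role in step.open_gates:
            blackboard.open_role_gates(kind, role, on=False)
        advance(word_ms - drive_ms, None, scan=False)
    advance(tail_ms, None, scan=False)

    trace = None
    if record:
        ids = list(blackboard.net.activities())
        trace = ActivityTrace(np.array(times), ids, np.vstack(frames))
    return trace, onsets


def _resolve_node(bb: Blackboard, ref: tuple) -> ConnectionNode:
    if ref[0] == "word":
        return bb.word_node(ref[1], ref[2])
    return bb.role_node(ref[1], ref[2], ref[3], ref[4])


def parse(
    tokens: list[str],
    lexicon: Lexicon,
    blackboard: Blackboard,
    record: bool = False,
    **run_kw,
) -> tuple[list[WordStep], ActivityTrace | None, list[float]]:
    """Build the command script for a token stream and execute it stepwise.

    After execution the blackboard's bound structure is the sentence's
    connection path.  Permuted or uncovered category sequences raise
    :class:`ParseError` before anything is driven.
    """
    script = build_script(tokens, lexicon)
    trace, onsets = execute_script(blackboard, script, record=record, **run_kw)
    return script, trace, onsets


# ----------------------------------------------------------------------
# questions

@dataclass(frozen=True)
class AnswerScript:
    """Retrieval recipe associated with one query pattern."""

    cue_role: str  # "noun" | "verb": which query token supplies the cue
    gates: tuple[tuple[str, str], ...]
    answer_kind: str = "N"


def role_tag(blackboard: Blackboard, word: str) -> str:
    """Thematic tag of a word, read from its active blackboard bindings.

    The word's in-situ assembly reaches its bound structure fragment;
    the tag is taken from the role its main assembly is bound through
    (Agent for a subject noun, Theme for an object, Location for a
    preposition's noun), preferring Agent when several bindings exist.
    """
    triples = blackboard.bound_structure()
    mains = {b for a, role, b in triples if a == word and role == "word"}
    mains |= {a for a, role, b in triples if b == word and role == "word"}
    if not mains:
        raise OpenQueryError(f"{word!r} has no binding in the blackboard")
    roles = set()
    for a, role, b in triples:
        if role == "word":
            continue
        if a in mains or b in mains:
            roles.add(role)
    for role in _TAG_PRIORITY:
        if role in roles:
            return ROLE_TAGS[role]
    raise OpenQueryError(f"{word!r} is bound but fills no tagged role")


def recognize_query(
    tokens: list[str], lexicon: Lexicon, blackboard: Blackboard
) -> tuple[str, ...]:
    """Generalize a question into ``(wh, categories..., tag)``.

    The trailing tag is not in the token stream: it is blackboard
    feedback, read from the role the cued noun's assembly is bound
    through in the stored sentence.
    """
    if not tokens:
        raise ParseError("empty query")
    categories = [categorize(w.rstrip("?"), lexicon) for w in tokens]
    if categories[0] != "wh":
        raise ParseError(f"query must start with a wh-word, got {tokens[0]!r}")
    nouns = [w.rstrip("?") for w, c in zip(tokens, categories) if c == "noun"]
    if not nouns:
        raise ParseError("query contains no noun to cue with")
    tag = role_tag(blackboard, nouns[-1])
    return (tokens[0].rstrip("?").lower(), *categories[1:], tag)


# ----------------------------------------------------------------------
# sequence-node reservoir

@dataclass
class SequenceNode:
    """One node of the reservoir's chain.

    Its gating column lets it fire only when its predecessor has fired
    (sequential order), an external token of its category arrives, and —
    for the final node — the blackboard feedback tag is present.
    """

    id: int
    category: str
    previous: int | None


class Reservoir:
    """A chain of sequence nodes with an exact-association readout."""

    def __init__(self) -> None:
        self.nodes: list[SequenceNode] = []
        self.readout: dict[tuple, AnswerScript] = {}

    def present(self, pattern: tuple) -> tuple:
        """Walk/extend the chain for a pattern; returns the pattern key."""
        prev = None
        for element in pattern:
            node = next(
                (n for n in self.nodes if n.category == element and n.previous == prev),
                None,
            )
            if node is None:
                node = SequenceNode(len(self.nodes), element, prev)
                self.nodes.append(node)
            prev = node.id
        return tuple(pattern)

    def lookup(self, pattern: tuple) -> AnswerScript:
        key = self.present(pattern)
        if key not in self.readout:
            raise ParseError(f"no readout for pattern {key}")
        return self.readout[key]


def train_readout(
    reservoir: Reservoir, examples: list[tuple[tuple, AnswerScript]]
) -> dict[tuple, AnswerScript]:
    """Exact association training: every pair is reproduced verbatim;
    contradictory pairs are an error; unseen patterns stay unanswerable."""
    for pattern, script in examples:
        key = reservoir.present(pattern)
        if key in reservoir.readout and reservoir.readout[key] != script:
            raise TrainingError(f"contradictory scripts for pattern {key}")
        reservoir.readout[key] = script
    return reservoir.readout


def default_reservoir() -> Reservoir:
    """Reservoir trained on the wh-query constructions over the fixtures."""
    where_script = AnswerScript(
        cue_role="noun",
        gates=(
            ("N", "n"), ("S", "n"), ("S", "v"), ("V", "v"),
            ("V", "pv"), ("PP", "pv"), ("PP", "pn"), ("N", "pn"),
        ),
    )
    who_script = AnswerScript(
        cue_role="verb",
        gates=(("V", "v"), ("S", "v"), ("S", "n"), ("N", "n")),
    )
    r = Reservoir()
    train_readout(
        r,
        [
            (("where", "localizer", "noun", "Agent"), where_script),
            (("who", "tverb", "noun", "Agent"), who_script),
            (("who", "tverb", "noun", "Theme"), who_script),
        ],
    )
    return r


def answer(
    tokens: list[str],
    lexicon: Lexicon,
    blackboard: Blackboard,
    reservoir: Reservoir | None = None,
) -> str | None:
    """Answer a wh-question from the bound blackboard.

    Returns the retrieved word, or None (the no-answer signal) when the
    query is open — nothing bound, or retrieval comes back empty.
    """
    reservoir = reservoir or default_reservoir()
    try:
        pattern = recognize_query(tokens, lexicon, blackboard)
    except OpenQueryError:
        return None
    script = reservoir.lookup(pattern)
    clean = [w.rstrip("?") for w in tokens]
    categories = [categorize(w, lexicon) for w in clean]
    if script.cue_role == "noun":
        cue = [w for w, c in zip(clean, categories) if c == "noun"][-1]
    else:
        cue = [w for w, c in zip(clean, categories) if c in ("tverb", "localizer")][-1]
    words, _ = blackboard.retrieve(cue, list(script.gates), script.answer_kind)
    if not words:
        return None
    return sorted(words)[0]
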