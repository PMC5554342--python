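"""The sentence neural blackboard.

Concepts are *in situ* assemblies: one population per word, never copied.
Sentence structure is carried by pools of structure assemblies (a main
population plus role-labeled sub-assembly populations) and by connection
matrices of connection nodes, each of which can bind one particular pair
of sub-assemblies (or a word to a main assembly) through a bistable
working-memory population.

Conditional connections are realized as three-population gating circuits
(relay ``X``, tonically active inhibitor ``i``, disinhibitor ``di``):
activity flows from source to target only while ``di`` silences ``i``.
Main-to-sub gates are disinhibited by control input (syntactic
operations); the directional gates inside a connection node are
disinhibited by the node's WM population, so an ignited WM *is* the
binding — activation then flows between the bound assemblies in either
direction for as long as the WM population reverberates.

Every circuit is made of plain excitatory/inhibitory links on the
underlying Wilson-Cowan network; nothing here bypasses the dynamics
except WM ignition itself, which is performed by a supervisory co-activity
scan (:meth:`Blackboard.bind_if_coactive`) standing in for the entry
gating circuit's threshold behavior.  The entry circuit's populations are
instantiated and wired (they contribute to the population count and to
sub-threshold WM priming) but the discrete ignition decision is taken by
the scan, which is robust and auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .dynamics import Link, Network, Population, WM_PARAMS

__all__ = [
    "KIND_ROLES",
    "DEFAULT_ROLE_PAIRS",
    "GatingCircuit",
    "ConnectionNode",
    "ConnectionMatrix",
    "ConceptAssembly",
    "StructureAssembly",
    "Blackboard",
    "make_blackboard",
    "PoolExhaustedError",
]

#: Role sub-assemblies owned by each structure-assembly kind:
#: S (sentence) has subject and verb slots; N (noun) can be a subject,
#: a theme, and can take adjective, numerator and preposition modifiers;
#: V (verb) fills the sentence verb slot, takes an auxiliary, a theme and
#: a preposition; Aux/Adj/Adv/Num/PP carry their single attachment roles
#: (adverbs attach to adjectives through the shared ``ad`` role,
#: prepositions link a verb via ``pv`` and a noun via ``pn``).
KIND_ROLES: dict[str, tuple[str, ...]] = {
    "S": ("n", "v"),
    "N": ("n", "t", "na", "nm", "pn"),
    "V": ("v", "va", "t", "pv"),
    "Aux": ("va",),
    "Adj": ("na", "ad"),
    "Adv": ("ad",),
    "Num": ("nm",),
    "PP": ("pv", "pn"),
}

#: Bindable role pairs: each entry ((kindA, role), (kindB, role)) gets a
#: connection matrix between all assemblies of the two kinds.
DEFAULT_ROLE_PAIRS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("S", "n"), ("N", "n")),
    (("S", "v"), ("V", "v")),
    (("V", "va"), ("Aux", "va")),
    (("V", "t"), ("N", "t")),
    (("N", "nm"), ("Num", "nm")),
    (("N", "na"), ("Adj", "na")),
    (("Adj", "ad"), ("Adv", "ad")),
    (("V", "pv"), ("PP", "pv")),
    (("PP", "pn"), ("N", "pn")),
)

# wiring weights for all circuits
W_EXC = 2.0  # excitatory cascade weight
W_INH = -4.0  # inhibition (i -> X, di -> i)
W_ENTRY = 1.0  # each sub-assembly into the entry relay
W_PRIME = 0.6  # entry relay into WM: primes but cannot ignite alone
GATE_OPEN = 1.0  # control drive that opens a di population
GATE_SUPPRESS = -2.0  # control drive that holds a word gate shut


class PoolExhaustedError(Exception):
    """More simultaneous assemblies of a kind requested than the pool holds."""


@dataclass
class GatingCircuit:
    """One conditional connection: source -> (X, gated by i, di) -> target."""

    source: str
    target: str
    x: str
    i: str
    di: str

    @property
    def population_ids(self) -> tuple[str, str, str]:
        return (self.x, self.i, self.di)


@dataclass
class ConnectionNode:
    """Binding machinery for one specific assembly pair.

    One WM population, an entry gating circuit (co-activity primes WM),
    and two directional gating circuits disinhibited by WM.
    """

    a: str  # population id of the first bindable assembly
    b: str
    wm: str
    entry: GatingCircuit
    ab: GatingCircuit
    ba: GatingCircuit

    def population_ids(self) -> list[str]:
        return [
            self.wm,
            *self.entry.population_ids,
            *self.ab.population_ids,
            *self.ba.population_ids,
        ]


#: populations per connection node: 1 WM + 3 gating circuits of 3 each
POPULATIONS_PER_NODE = 10


@dataclass
class ConnectionMatrix:
    """Grid of connection nodes for one bindable pair of assembly sets."""

    key: str
    nodes: dict[tuple[str, str], ConnectionNode] = field(default_factory=dict)


@dataclass
class ConceptAssembly:
    word: str
    kind: str
    pop: str


@dataclass
class StructureAssembly:
    kind: str
    index: int
    main: str
    subs: dict[str, str]  # role -> population id
    gates: dict[str, tuple[GatingCircuit, GatingCircuit]]  # role -> (main->sub, sub->main)

    @property
    def name(self) -> str:
        return f"{self.kind}{self.index}"


class Blackboard:
    """A sentence blackboard compiled onto a Wilson-Cowan network."""

    def __init__(
        self,
        ignition_threshold: float = 0.3,
        ignition_ms: float = 10.0,
        wm_read_level: float = 0.25,
    ):
        self.net = Network()
        self.concepts: dict[str, ConceptAssembly] = {}
        self.pools: dict[str, list[StructureAssembly]] = {}
        self.word_matrices: dict[str, ConnectionMatrix] = {}
        self.role_matrices: dict[tuple, ConnectionMatrix] = {}
        self.ignition_threshold = ignition_threshold
        self.ignition_ms = ignition_ms
        self.wm_read_level = wm_read_level
        self._timers: dict[str, float] = {}  # wm id -> co-activity ms
        self._node_by_wm: dict[str, tuple[str, ConnectionNode]] = {}
        self._recruited: dict[str, list[int]] = {}

    # ------------------------------------------------------------------
    # construction helpers

    def _add_pop(self, pid: str, **kw) -> str:
        self.net.add_population(Population(pid, **kw))
        return pid

    def _add_gating(self, source: str, target: str, name: str) -> GatingCircuit:
        x = self._add_pop(f"{name}.X")
        i = self._add_pop(f"{name}.i", drive=GATE_OPEN)  # tonically active
        di = self._add_pop(f"{name}.di")
        self.net.add_link(Link(source, x, W_EXC))
        self.net.add_link(Link(i, x, W_INH))
        self.net.add_link(Link(di, i, W_INH))
        self.net.add_link(Link(x, target, W_EXC))
        return GatingCircuit(source, target, x, i, di)

    def _add_node(self, key: str, a: str, b: str, word_node: bool) -> ConnectionNode:
        wm = self._add_pop(f"{key}.WM", **WM_PARAMS)
        entry = self._add_gating_entry(key, a, b, wm)
        ab = self._add_gating(a, b, f"{key}.ab")
        ba = self._add_gating(b, a, f"{key}.ba")
        # WM disinhibits both directional gates: the binding opens the flow
        self.net.add_link(Link(wm, ab.di, W_EXC))
        self.net.add_link(Link(wm, ba.di, W_EXC))
        node = ConnectionNode(a, b, wm, entry, ab, ba)
        self._node_by_wm[wm] = (key, node)
        if word_node:
            # word gates are additionally held shut by default; the control
            # circuits release them selectively (parse input, retrieval cue
            # and answer kinds), standing in for the phonological blackboard
            for circuit in (ab, ba):
                self.net.set_control(circuit.di, GATE_SUPPRESS)
        return node

    def _add_gating_entry(self, key: str, a: str, b: str, wm: str) -> GatingCircuit:
        x = self._add_pop(f"{key}.entry.X", threshold=0.6)
        i = self._add_pop(f"{key}.entry.i", drive=GATE_OPEN)
        di = self._add_pop(f"{key}.entry.di")
        self.net.add_link(Link(a, x, W_ENTRY))
        self.net.add_link(Link(b, x, W_ENTRY))
        self.net.add_link(Link(i, x, W_INH))
        self.net.add_link(Link(di, i, W_INH))
        self.net.add_link(Link(x, wm, W_PRIME))
        return GatingCircuit(a, wm, x, i, di)

    # ------------------------------------------------------------------
    # inventory

    def assembly(self, kind: str, index: int) -> StructureAssembly:
        return self.pools[kind][index]

    def assembly_by_name(self, name: str) -> StructureAssembly:
        for pool in self.pools.values():
            for sa in pool:
                if sa.name == name:
                    return sa
        raise KeyError(name)

    def population_count(self) -> int:
        return len(self.net)

    def expected_population_count(self) -> int:
        """Closed-form population count implied by the element inventory:
        1 per concept, 1 + |roles| per structure assembly plus 2 gating
        circuits (3 populations each) per main-sub pair, and 10 per
        connection node."""
        n = len(self.concepts)
        for pool in self.pools.values():
            for sa in pool:
                n += 1 + len(sa.subs) + 2 * 3 * len(sa.subs)
        for matrix in list(self.word_matrices.values()) + list(self.role_matrices.values()):
            n += POPULATIONS_PER_NODE * len(matrix.nodes)
        return n

    # ------------------------------------------------------------------
    # gates and drives

    def open_role_gates(self, kind: str, role: str, on: bool = True) -> None:
        """Drive (or release) the di populations of every main<->sub gating
        circuit for one (kind, role) across the whole pool."""
        if kind not in self.pools or role not in KIND_ROLES.get(kind, ()):
            raise ValueError(f"no role {role!r} on kind {kind!r}")
        value = GATE_OPEN if on else 0.0
        for sa in self.pools[kind]:
            for circuit in sa.gates[role]:
                self.net.set_control(circuit.di, value)

    def open_word_gates(self, kind: str, on: bool = True) -> None:
        """Release (or re-suppress) the word<->main directional gates of one
        kind's word connection matrix."""
        if kind not in self.word_matrices:
            raise ValueError(f"no word matrix for kind {kind!r}")
        value = 0.0 if on else GATE_SUPPRESS
        for node in self.word_matrices[kind].nodes.values():
            self.net.set_control(node.ab.di, value)
            self.net.set_control(node.ba.di, value)

    def drive(self, pid: str, amplitude: float) -> None:
        """Set a persistent external drive on one population (0 clears)."""
        self.net.set_control(pid, amplitude)

    def drive_word(self, word: str, amplitude: float = 1.0) -> None:
        self.net.set_control(self.concepts[word].pop, amplitude)

    # ------------------------------------------------------------------
    # recruitment

    def recruit(self, kind: str) -> StructureAssembly:
        """Return the lowest-index not-yet-recruited assembly of a kind."""
        used = self._recruited.setdefault(kind, [])
        pool = self.pools.get(kind, [])
        for sa in pool:
            if sa.index not in used:
                used.append(sa.index)
                return sa
        raise PoolExhaustedError(
            f"all {len(pool)} assemblies of kind {kind!r} are already in use"
        )

    # ------------------------------------------------------------------
    # dynamics and binding

    def word_node(self, word: str, assembly: str) -> ConnectionNode:
        kind = self.concepts[word].kind
        return self.word_matrices[kind].nodes[(word, assembly)]

    def role_node(self, a: str, role_a: str, b: str, role_b: str) -> ConnectionNode:
        """Connection node binding assembly ``a``'s ``role_a`` sub-assembly
        to ``b``'s ``role_b`` sub-assembly, in either matrix orientation."""
        ka = self.assembly_by_name(a).kind
        kb = self.assembly_by_name(b).kind
        if (ka, role_a, kb, role_b) in self.role_matrices:
            return self.role_matrices[(ka, role_a, kb, role_b)].nodes[(a, b)]
        if (kb, role_b, ka, role_a) in self.role_matrices:
            return self.role_matrices[(kb, role_b, ka, role_a)].nodes[(b, a)]
        raise KeyError(f"no connection matrix for {ka}.{role_a} ~ {kb}.{role_b}")

    def step(self, dt: float = 1.0, scan: bool = True, nodes=None) -> list[tuple[str, str]]:
        """Advance the network one step; optionally run the ignition scan
        (over all nodes, or only over ``nodes`` if given)."""
        self.net.step(None, dt)
        if scan:
            return self.bind_if_coactive(dt, nodes)
        return []

    def bind_if_coactive(self, dt: float = 1.0, nodes=None) -> list[tuple[str, str]]:
        """Ignite the WM population of every connection node whose two
        endpoint assemblies have been concurrently above the ignition
        threshold for the configured hold time.  Returns newly bound pairs.

        ``nodes``, if given, restricts the scan to those connection nodes
        (the control circuits arm exactly the bindings they expect).
        """
        if nodes is None:
            scanned = self._node_by_wm.items()
        else:
            scanned = [(n.wm, (None, n)) for n in nodes]
        new: list[tuple[str, str]] = []
        for wm, (key, node) in scanned:
            if self.net.activity(wm) >= self.wm_read_level:
                continue
            a, b = self.net.activity(node.a), self.net.activity(node.b)
            if a >= self.ignition_threshold and b >= self.ignition_threshold:
                t = self._timers.get(wm, 0.0) + dt
                if t >= self.ignition_ms:
                    self.ignite(node)
                    new.append((node.a, node.b))
                    t = 0.0
                self._timers[wm] = t
            else:
                self._timers[wm] = 0.0
        return new

    def ignite(self, node: ConnectionNode) -> None:
        """Kick a WM population into its persistent reverberating state."""
        self.net.set_activity(node.wm, 0.55)

    def active_bindings(self) -> list[tuple[str, str, str]]:
        """(matrix key, a, b) for every node whose WM is currently active."""
        out = []
        for wm, (key, node) in self._node_by_wm.items():
            if self.net.activity(wm) >= self.wm_read_level:
                out.append((key, node.a, node.b))
        return out

    def settle(self, ms: float = 50.0, dt: float = 1.0) -> None:
        """Step without the ignition scan so tonic populations (the gating
        inhibitors) reach their fixed points before anything is driven."""
        for _ in range(int(round(ms / dt))):
            self.step(dt, scan=False)

    def quiesce(self) -> None:
        """Zero all transient activity, preserving active WM bindings."""
        wm_levels = {
            wm: self.net.activity(wm)
            for wm in self._node_by_wm
            if self.net.activity(wm) >= self.wm_read_level
        }
        for pid in self.net.populations:
            self.net.set_activity(pid, self.net.populations[pid].baseline)
        for wm, level in wm_levels.items():
            self.net.set_activity(wm, level)

    def reset(self) -> None:
        """Clear all activity including WM bindings and recruitment state."""
        self.net.reset()
        self._timers.clear()
        self._recruited.clear()
        for kind in self.word_matrices:
            self.open_word_gates(kind, on=False)

    # ------------------------------------------------------------------
    # structure readout

    def bound_structure(self) -> list[tuple[str, str, str]]:
        """The sentence's connection path: one (element, role, element)
        triple per active WM population.  Words appear under their own
        label; structure assemblies under kind+index (N1, S1, ...)."""
        triples = []
        pop_owner = self._population_owner_map()
        for key, a, b in self.active_bindings():
            owner_a, role_a = pop_owner[a]
            owner_b, role_b = pop_owner[b]
            role = role_a if role_a is not None else "word"
            triples.append((owner_a, role, owner_b))
        return triples

    def structure_graph(self) -> nx.Graph:
        """bound_structure as a labeled graph: node label is the word
        itself for concepts and the kind for structure assemblies."""
        g = nx.Graph()
        for a, role, b in self.bound_structure():
            for node in (a, b):
                if node not in g:
                    if node in self.concepts:
                        g.add_node(node, label=node, kind="word")
                    else:
                        sa = self.assembly_by_name(node)
                        g.add_node(node, label=sa.kind, kind="structure")
            g.add_edge(a, b, role=role)
        return g

    def _population_owner_map(self) -> dict[str, tuple[str, str | None]]:
        owners: dict[str, tuple[str, str | None]] = {}
        for concept in self.concepts.values():
            owners[concept.pop] = (concept.word, None)
        for pool in self.pools.values():
            for sa in pool:
                owners[sa.main] = (sa.name, None)
                for role, pid in sa.subs.items():
                    owners[pid] = (sa.name, role)
        return owners

    # ------------------------------------------------------------------
    # retrieval

    def retrieve(
        self,
        cue: str,
        role_gates: list[tuple[str, str]],
        answer_kind: str,
        settle_ms: float = 300.0,
        dt: float = 1.0,
        readout_threshold: float = 0.3,
    ) -> tuple[set[str], set[str]]:
        """Content-addressable retrieval.

        Activates the cue's in-situ assembly, opens the word gates of the
        cue's and the answer's kinds plus the main<->sub gates named by
        ``role_gates``, lets activation flow along the WM-bound connection
        path, and returns the words (other than the cue) whose concept
        assemblies become active, together with the active structure
        assemblies.
        """
        if cue not in self.concepts:
            raise KeyError(f"cue {cue!r} is not in the vocabulary")
        self.quiesce()
        self.settle(50.0, dt)
        cue_kind = self.concepts[cue].kind
        opened_words = {cue_kind, answer_kind} & set(self.word_matrices)
        for kind in opened_words:
            self.open_word_gates(kind, on=True)
        for kind, role in role_gates:
            self.open_role_gates(kind, role, on=True)
        self.drive_word(cue, 1.0)
        for _ in range(int(round(settle_ms / dt))):
            self.step(dt, scan=False)
        words = {
            w
            for w, c in self.concepts.items()
            if w != cue
            and c.kind == answer_kind
            and self.net.activity(c.pop) >= readout_threshold
        }
        assemblies = {
            sa.name
            for pool in self.pools.values()
            for sa in pool
            if self.net.activity(sa.main) >= readout_threshold
        }
        # restore the resting configuration
        self.drive_word(cue, 0.0)
        for kind, role in role_gates:
            self.open_role_gates(kind, role, on=False)
        for kind in opened_words:
            self.open_word_gates(kind, on=False)
        self.quiesce()
        return words, assemblies

    # ------------------------------------------------------------------
    # serialization

    def to_json(self) -> str:
        return json.dumps(
            {
                "concepts": {w: c.kind for w, c in self.concepts.items()},
                "pools": {k: [sa.name for sa in pool] for k, pool in self.pools.items()},
                "population_count": self.population_count(),
                "bindings": self.bound_structure(),
            },
            indent=1,
        )

    def export_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("element_a,role,element_b\n")
            for a, role, b in self.bound_structure():
                fh.write(f"{a},{role},{b}\n")


def make_blackboard(
    vocabulary: dict[str, str],
    pool_sizes: dict[str, int],
    role_pairs=DEFAULT_ROLE_PAIRS,
    word_matrices: bool = True,
    **config,
) -> Blackboard:
    """Instantiate all assemblies, gating circuits and connection matrices.

    ``vocabulary`` maps each word to the structure-assembly kind it can
    bind (e.g. ``{"cat": "N", "is": "V"}``); ``pool_sizes`` gives the
    number of structure assemblies per kind.  Connection matrices are
    created for every word kind and for every role pair whose two kinds
    both have pools.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    for kind, size in pool_sizes.items():
        if kind not in KIND_ROLES:
            raise ValueError(f"unknown structure-assembly kind {kind!r}")
        if size < 1:
            raise ValueError(f"pool size for {kind!r} must be >= 1")
    bb = Blackboard(**config)

    for word, kind in vocabulary.items():
        if kind not in KIND_ROLES:
            raise ValueError(f"word {word!r} has unknown kind {kind!r}")
        pop = bb._add_pop(f"w:{word}")
        bb.concepts[word] = ConceptAssembly(word, kind, pop)

    for kind, size in pool_sizes.items():
        pool = []
        for idx in range(1, size + 1):
            main = bb._add_pop(f"{kind}{idx}")
            subs, gates = {}, {}
            for role in KIND_ROLES[kind]:
                sub = bb._add_pop(f"{kind}{idx}.{role}")
                subs[role] = sub
                m2s = bb._add_gating(main, sub, f"{kind}{idx}.{role}.m2s")
                s2m = bb._add_gating(sub, main, f"{kind}{idx}.{role}.s2m")
                gates[role] = (m2s, s2m)
            pool.append(StructureAssembly(kind, idx, main, subs, gates))
        bb.pools[kind] = pool

    # word <-> main connection matrices, one per kind that has words
    word_kinds = sorted({k for k in vocabulary.values() if k in bb.pools}) if word_matrices else []
    for kind in word_kinds:
        matrix = ConnectionMatrix(f"word-{kind}")
        for word, wkind in vocabulary.items():
            if wkind != kind:
                continue
            for sa in bb.pools[kind]:
                key = f"w:{word}~{sa.name}"
                matrix.nodes[(word, sa.name)] = bb._add_node(
                    key, bb.concepts[word].pop, sa.main, word_node=True
                )
        bb.word_matrices[kind] = matrix

    # sub <-> sub connection matrices per bindable role pair
    for (kind_a, role_a), (kind_b, role_b) in role_pairs:
        if kind_a not in bb.pools or kind_b not in bb.pools:
            continue
        mkey = (kind_a, role_a, kind_b, role_b)
        matrix = ConnectionMatrix(f"{kind_a}-{role_a}~{kind_b}-{role_b}")
        for sa in bb.pools[kind_a]:
            for sb in bb.pools[kind_b]:
                key = f"{sa.name}.{role_a}~{sb.name}.{role_b}"
                matrix.nodes[(sa.name, sb.name)] = bb._add_node(
                    key, sa.subs[role_a], sb.subs[role_b], word_node=False
                )
        bb.role_matrices[mkey] = matrix
    return bb
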