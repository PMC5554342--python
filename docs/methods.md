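# Methods

This note records the models implemented, the parameters that matter, the
choices made where the design was genuinely open, and what the synthetic
corpora do and do not establish.

## Population dynamics

Every blackboard element is a single Wilson–Cowan rate unit

    τ dA/dt = −(A − baseline) + (1 − A) · F(w_self·A + Σ inputs + drive),
    F(x) = σ(g·(x − θ)) − σ(−g·θ),

with the transfer function shifted so `F(0) = 0`: a population with no
input decays monotonically to its baseline, and the rest state is an
exact fixed point. `F` is negative for net-inhibitory input, which pulls
activity toward zero; activity is clamped to [0, 1] after every step.
Defaults: τ = 10 ms, g = 4, θ = 0.5, baseline = 0, dt = 1 ms, all
overridable per population.

Note a structural consequence of the `(1 − A)·F` saturation: steady-state
activity cannot exceed `F_max/(1 + F_max) ≈ 0.47` at the default gain.
Driven assemblies therefore plateau near 0.40–0.46, and all thresholds in
the package (ignition, readout) are calibrated to that scale, not to 1.

**Integration.** Explicit Euler. The error is O(dt): the step-halving
difference is ≈7·10⁻³ sup-norm at dt = 1 ms and ≤10⁻³ at dt = 0.1 ms (the
regression test pins the latter). At these time constants nothing is
stiff; dt = 1 ms is used for the sentence simulations because the
qualitative profile — not the third decimal of a trajectory — carries the
scientific content.

**Working-memory populations** use a steeper, higher-threshold transfer
(g = 8, θ = 0.7) with recurrent weight 2.0. This makes the unit cleanly
bistable: the rest state is stable (loop gain at zero ≈ 0.06), a
persistent state sits at ≈ 0.458 sustained purely by reverberating
recurrent excitation, and the ignition basin boundary lies near A ≈ 0.2.
A sustained external input of ≈ 0.2 (one active partner) leaves the unit
in the low state; ≈ 0.4 (both partners) destroys the low fixed point and
ignites it. Ignition in the package sets the unit to 0.55, just above its
persistent state, from where it relaxes onto the attractor.

## Blackboard wiring

A gating circuit is three populations: relay X (excited by the source,
weight 2), inhibitor i (tonic drive 1.0, so it rests near 0.43 and holds
X silent with weight −4), and disinhibitor di (silences i with weight −4
when driven). Gates open in two ways: main↔sub gates by control drive on
di (syntactic operations), directional gates inside a connection node by
the node's WM population (weight 2 onto di), so a binding is an open
bidirectional connection for as long as WM reverberates.

A connection node is 10 populations: one WM, one entry gating circuit,
and two directional gating circuits. The entry circuit is wired (both
endpoints excite its relay, which primes WM at weight 0.6 — deliberately
below the ignition basin) but the discrete ignition decision is taken by
a supervisory co-activity scan: a node ignites when both endpoints have
stayed above the ignition threshold (default 0.3, i.e. ≈75% of a driven
assembly's plateau) for 10 ms. The scan makes ignition auditable and
exactly reproducible; the analog entry circuit contributes priming and
the population count but not the decision.

Word↔main directional gates carry one extra control bias: they are held
shut by default and released selectively (for the parsed word's kind, and
for the cue and answer kinds during retrieval). This stands in for the
phonological blackboard, which this package elides — words bind directly
to structure assemblies — and prevents every bound word from lighting up
during unrelated retrievals.

**Kinds and roles.** Structure assemblies come in kinds S, N, V, Aux,
Adj, Adv, Num, PP with role sub-assemblies S:{n,v}, N:{n,t,na,nm,pn},
V:{v,va,t,pv}, Aux:{va}, Adj:{na,ad}, Adv:{ad}, Num:{nm}, PP:{pv,pn}, and
connection matrices for the nine role pairs these support (subject S-n~N-n,
verb S-v~V-v, auxiliary V-va~Aux-va, theme V-t~N-t, numerator N-nm~Num-nm,
adjective N-na~Adj-na, adverb Adj-ad~Adv-ad, and the preposition's two
attachments V-pv~PP-pv and PP-pn~N-pn). The preposition in *cat is on
mat* is encoded with the same pv/pn roles as the nine-word sentence, so
one convention covers all fixtures. Population accounting is closed-form:
1 per concept, 1 + |roles| + 6·|roles| per structure assembly, 10 per
connection node; an audit method recomputes it from the inventory and the
suite checks it against the instantiated network. The nine-word sentence
blackboard comes to 555 populations.

## Parsing and the activity profile

Control is a deterministic rule table over category sequences — exactly
the constructions the three fixture sentences and wh-queries need;
anything else raises a parse error rather than guessing. The sequence-node
reservoir is the chaining mechanism that presents category n-grams in
order, with an exact-association readout (no gradient learning): training
pairs are reproduced verbatim, contradictions are an error, unseen
patterns are rejected.

Words are presented at 200 ms intervals (the interval is a package
choice; only the qualitative profile is claimed). Each word's concept
assembly and newly recruited structure assemblies are driven for 140 ms;
gates for the step's expected bindings are opened and exactly those
connection nodes are armed for ignition. When the word binds, drives are
released at 140 ms and the transient activity decays before the next
onset, so total activity falls below its local peak. A word that cannot
yet bind — the sentence-initial word, and a modifier whose head has not
arrived — is held active into the following interval, so its interval
shows no decline. In the nine-word sentence these are *Bill-Gates* and
*very*; the numerator *two* does bind in its own interval because the
control circuit recruits the upcoming noun assembly anticipatorily.
"Decline" is operationalized as a drop of more than 0.5 summed activity
units (roughly one population's worth) from the interval's peak; the
held words stay within ≈0.1 units of flat while binding words drop by
2–6 units, so the margin is wide.

Retrieval settles the network for 50 ms (letting tonic inhibitors reach
their fixed points), drives the cue's in-situ assembly for 300 ms with the
named gate path open, and reads out concept assemblies above 0.3. The
answer-kind restriction on word gates makes the example queries return
exactly their answer word.

## Sequence memory

Per viewpoint, layer 0 holds the symbolized stream; each layer has a
first-order transition matrix with add-one smoothing over its running
alphabet (so predictions exist for unseen contexts, at the price of
early entropies being dominated by the smoothing mass — hence burn-in).

**Boundary decision.** On arrival of symbol `s_{t+1}` after `s_t`, each
generator compares `H(D(context = s_{t+1}))` with `H(D(context = s_t))`,
both computed from the counts as they stood *before* this observation and
smoothed over a common alphabet; the counts are updated afterwards. This
pre-update convention matters: with post-update counts, the in-progress
word's own increments make mid-word comparisons spuriously positive. An
entropy rise means the stream has entered a high-uncertainty context —
the signature of a unit ending — so the winning generator closes its
chunk *including* the arriving symbol, which places boundaries exactly at
word ends on corpora with deterministic within-word and uniform
between-word transitions. A rise must exceed 10⁻⁹ bits: distributions
with identical count structure but different alphabet insertion order can
differ by one ulp in floating-point summation, and such noise must not
win a competition. One global winner per event (largest rise; ties break
toward the earliest-registered viewpoint); losing generators' candidate
boundaries are retained for a forgetting period (default 20 events) and
then dropped. After a win, the winner's hierarchy re-anchors its open
chunk at the boundary — an interpretation, since the treatment of losing
pointers is genuinely open.

**Layer formation.** A closed chunk's symbols trace a trajectory through
their layer's conceptual space; the trajectory is resampled to 32 points
(respecting durations), DCT-transformed per dimension, and the first 8
coefficient magnitudes per dimension form the chunk's point in the space
one level up. Identical contents map to identical points and reuse their
label (seed tolerance 10⁻³ in the upper spaces); distinct contents mint
distinct labels, deliberately leaving merging to consolidation. The label
is appended to the upper layer, up/down link counts are updated with
multiplicity, and the same boundary test applies recursively up to
`max_levels` (default 3).

**Symbolization.** String-valued viewpoints are symbols already; their
seeds are placed deterministically at golden-angle positions on the unit
circle, which keeps them distinct without an embedding claim. Continuous
viewpoints are classified in their base space under the current
prediction (so expectation genuinely modulates perception, and errors are
committed to memory as if correct); gap regions mint new symbols, and a
`discriminability` radius lets a continuous stream grow an alphabet even
while only one seed exists — without it, a single seed owns the whole
space and no second symbol could ever form. Linked viewpoints pair the
two source symbols of the same event.

**Code length and consolidation.** The memory's quality measure is the
mean, over every stored symbol at every layer, of its smoothed surprise
given its predecessor (first symbols are coded against the uniform
distribution over their layer's alphabet). Consolidation greedily merges
label pairs at layers above the base, accepting only strict decreases of
this mean, until a local minimum; merges rewrite the label's history
(sequences, chunk labels, link counts are rebuilt), so meanings change
retrospectively. By construction the mean code length never increases.
The scheduled trigger is every 500 events (a schedule, not a sleep
model).

## Conceptual spaces

Classification is nearest-seed with two modifications applied pairwise to
the separating hyperplanes: an expectation offset
`α·(p(s)−p(s′))/(p(s)+p(s′))·‖s−s′‖/2` toward the less likely symbol
(our concretization of "in proportion to relative likelihood"; α default
0.5, optionally scaled by `1 − H(D)/log₂|A|` so sharper distributions
move boundaries more), and a symmetric `g/2` withdrawal creating an
explicit GAP zone. A point must lie in all of a symbol's modulated,
gapped half-spaces to be classified; ties at exact boundaries go to the
earliest symbol. Distance is Euclidean. Modulation is transient — seeds
never move. With α = g = 0 the classifier provably reduces to nearest
neighbor, and the suite checks it against a brute-force scan.

## Synthetic corpora: what they show and what they do not

The artificial language (three trisyllabic words over nine globally
unique syllables, uniform i.i.d. word selection, 900 tokens, seed 7)
realizes the cleanest possible segmentation setting: within-word
transitions are deterministic, so predicted entropy is flat inside words
and jumps only at word ends. Perfect boundary F1 here shows the
boundary-entropy machinery is implemented correctly — not that the
chunker segments natural speech, where transitions are merely skewed,
units repeat with unequal frequency, and symbols are shared across words.
Likewise the *John loves Mary* stream exercises synchronized multi-modal
viewpoints, continuous-value symbolization and linked alphabets with
smooth synthetic pitch/amplitude contours; it makes no claim about real
prosody. The sentence fixtures pin one syntactic reading each (e.g.
*Bill-Gates* as a single noun, the preposition attached to the verb);
ambiguity competition is out of scope.

## Known limitations

- The blackboard's control rule table covers exactly the fixture
  constructions; there is no broad-coverage parsing and no probabilistic
  disambiguation.
- WM bindings persist until explicitly reset; nothing decays them at
  sentence end.
- Chunk labels from different early segmentations of the same word are
  only unified by consolidation; before a consolidation pass the upper
  layers can carry redundant labels.
- The bridge compiles post hoc from a given chunk tree and role map; it
  does not co-simulate chunking and binding, and the role map is supplied,
  not learned.
- `predict` is strictly first-order per layer; longer-range context
  enters only through the layer hierarchy, and the optional up/down-link
  mixture is not part of the boundary decision.
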