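# conceptboard

Two cognitive architectures for representing and processing sentence-like
conceptual structures, implemented as one Python package:

* a **sentence neural blackboard** — in-situ concept assemblies bound into
  compositional structures by working-memory populations and gated
  disinhibition circuits, simulated with Wilson–Cowan population
  dynamics; and
* an **entropy-driven hierarchical sequence memory** — an incremental
  learner that chunks symbol streams where the entropy of its next-symbol
  prediction rises, labels chunks through Voronoi-tessellated conceptual
  spaces, and stacks layers of abstraction with first-order Markov models
  at every layer;

together with a **bridge** that compiles a learned chunk hierarchy into
blackboard bindings, making the structural correspondence between the two
architectures operational.

The package is aimed at computational cognitive scientists who want an
executable, testable account of (a) how temporary neural bindings can
implement compositional sentence structure without copying concept
representations, and (b) how the structural elements such a blackboard
needs could be discovered from sequence statistics rather than engineered.

## The models

**Blackboard dynamics.** Every element is a neural population with
activity `A ∈ [0, 1]` obeying

```
τ dA/dt = −(A − baseline) + (1 − A) · F(input),
F(x) = σ(g·(x − θ)) − σ(−g·θ)
```

with `σ` the logistic function, integrated by explicit Euler (default
`τ = 10 ms`, `g = 4`, `θ = 0.5`, `dt = 1 ms`). Inhibition is carried on
negative link weights. A *conditional connection* is a three-population
gating circuit (relay X, tonically active inhibitor i, disinhibitor di):
activation flows only while di silences i. Two assemblies bind when their
co-activity ignites the bistable *working-memory* population of their
connection node (gain 8, threshold 0.7, recurrent weight 2.0, persistent
state ≈ 0.46); the active WM population disinhibits both directional
gates, so the binding *is* the open connection, and it outlives the
stimuli by reverberation alone.

**Sequence memory.** Per viewpoint `v` and layer, the memory keeps a
symbol sequence and transition counts. Predictions are distributions
`D` over the alphabet `ℵ(v)` (add-one smoothing); their entropy is
`H(D) = −Σ p log₂ p` and a symbol's code length is `h(D, s) = −log₂ p(s)`.
When a new symbol makes the predicted entropy rise, the generator with the
largest rise closes its open chunk (boundary competition for workspace
access); the chunk's trajectory through its layer's conceptual space is
spectrally abstracted (DCT) into a point one space up, which names the
chunk — identical chunks share a label, and periodic *consolidation*
greedily merges labels whenever that reduces the mean bits per stored
symbol.

## Worked example

Parse *cat sees cat* into a blackboard and inspect the bound structure:

```
$ conceptboard simulate --fixture cat-sees-cat
populations: 198
S1 -[n]- N1
S1 -[v]- V1
V1 -[t]- N2
cat -[word]- N1
cat -[word]- N2
sees -[word]- V1
```

198 neural populations implement this small blackboard. The single
in-situ assembly for *cat* is bound to two different structure assemblies
— subject `N1` and theme `N2` — which is how the architecture represents
a repeated word without duplicating its concept (the "problem of two").

Question answering is content-addressable retrieval over the bound
structure:

```
$ conceptboard ask --question "Where is cat?" --after "cat is on mat"
mat
```

The question is generalized to *Where–localizer–noun–Agent* (the final
tag is fed back from the blackboard, where *cat* is bound as subject),
the trained readout opens the subject→verb→preposition→noun gate path,
and activation flowing from the cue's in-situ assembly reactivates
exactly *mat*.

Learning and segmentation:

```
$ conceptboard genlang --out corpus.jsonl --n-tokens 900 --seed 7
$ conceptboard learn --corpus corpus.jsonl --max-levels 2
```

feeds an artificial language of three trisyllabic words through the
chunker; after a short burn-in, every chunk boundary falls at a word end
(boundary F1 = 1.0 against ground truth on this corpus).

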