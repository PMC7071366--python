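# cinet

Context-integrating convolutional classification of ambiguous visual
stimuli.

When people read T[?]E where [?] is a shape halfway between A and H, they
see THE; in C[?]T they see CAT. `cinet` is a small, self-contained
modelling package for studying this *context effect* in a machine
classifier: it stacks a target stimulus together with weighted flanking
context stimuli into a single multi-channel input cuboid,

    R = ∇_{i=-S1..S2} R_{j+i},     R_{j+i} = α_{j+i} C_{j+i} + N_{j+i},

and classifies the stack with a compact CNN whose first-layer filters
span the full stack depth, so every feature couples target and context
pixels. Varying the context weights `α`, the per-slot Gaussian noise
variances, and the ordering of the context slots simulates congruent,
attenuated, impaired and flipped context environments; sweeping the
center-letter noise variance controls the degradation level. The package
is aimed at computational cognitive-science experiments on
context-shift-decrement and context-reinstatement effects, and ships
everything it needs: hand-designed 32×32 letter bitmaps, three ambiguous
hybrid letters ([A/H], [O/U], [P/R]) that are Hamming-equidistant from
their parents, a from-scratch NumPy CNN with a literal-equation reference
implementation, and a six-set experimental protocol.

See `docs/methods.md` for the model, its assumptions, and what the
synthetic stimulus world does and does not emulate.

## Worked example

Train a span-2 classifier on the six words {BAG, THE, MOW, FUN, SPY,
IRK} and ask it to resolve the ambiguous letter [A/H] in two different
contexts:

```python
import numpy as np
from cinet import (IntegrationConfig, TrainConfig, make_ambiguous,
                   make_word_inputs, TARGET_LETTERS)
from cinet.experiments import train_pool, TRAIN_WORDS_3

net = train_pool(1, 1, TRAIN_WORDS_3, n_networks=1,
                 train_config=TrainConfig(samples_per_class=30),
                 global_seed=42)[0].network

hybrid = make_ambiguous("A", "H")
cfg = IntegrationConfig.uniform(1, 1)          # unity weights, no noise
for word in ("BAG", "THE"):
    x = make_word_inputs(word, hybrid, cfg)    # replace the center letter
    p = net.predict(x)
    print(word, "->", TARGET_LETTERS[p.decided_class],
          np.round(p.posteriors, 3))
```

```
BAG -> A [0.999 0.001 0.    0.    0.    0.   ]
THE -> H [0.001 0.999 0.    0.    0.    0.   ]
```

The same hybrid bitmap is read as an A between B and G but as an H
between T and E: the posteriors (one per class A, H, O, U, P, R) move
almost entirely to the parent implied by the word.

The full protocol — three classifier pools, seven experiment sets per
center type, a nine-point noise sweep with two-stage averaging — runs
from the CLI and writes a tidy CSV, a JSON manifest and optional plots:

```bash
cinet run --profile ci --seed 1 --out results/      # desk scale, ~20 min
cinet render all --out glyphs/                      # export bitmaps as PNGs
```

`--profile full` restores the published 30-networks × 100-samples
protocol (hours on one CPU).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline classification probabilities from scratch at the
desk-scale profile: it trains the three classifier pools, then evaluates
congruent span-2 and span-4 context with ambiguous centers, flipped
context, the context-free baseline on plain letters, and
matched-context-noise conditions at their respective noise levels,
writing one `{"value": ..., "n": ...}` entry per condition.
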