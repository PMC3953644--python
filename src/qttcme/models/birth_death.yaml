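# Independent birth-death process, per-species template.
# One species X with spontaneous creation at rate b and first-order
# destruction at rate delta; d-species fixtures replicate this block.
# Started at zero copies the marginal is Poisson(lambda(t)) with
# lambda' = b - delta * lambda.
name: birth-death
species: [X]
window: [4096]
initial: [0]
rates:
  b: 1.0
  delta: 0.1
reactions:
  - stoich: [1]
    factors: {X: {poly: [1.0]}}
  - stoich: [-1]
    factors: {X: {poly: [0.0, 0.1]}}
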