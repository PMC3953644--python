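# Genetic toggle switch: two repressors U and V in a double-negative
# feedback loop.  Production of each is repressed by the other through
# a Hill function, degradation is first order.  The parameters below
# are bistable: deterministic fixed points near (18, 0.2) and
# (0.4, 14), giving a bimodal stationary distribution from the (0, 0)
# start as sample paths commit to one basin or the other.
name: toggle-switch
species: [U, V]
window: [64, 64]
initial: [0, 0]
reactions:
  - stoich: [1, 0]
    factors: {V: {hill: {vmax: 18.0, K: 4.0, n: 3.0}}}
  - stoich: [-1, 0]
    factors: {U: {poly: [0.0, 1.0]}}
  - stoich: [0, 1]
    factors: {U: {hill: {vmax: 14.0, K: 4.0, n: 3.0}}}
  - stoich: [0, -1]
    factors: {V: {poly: [0.0, 1.0]}}
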