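# Enzymatic futile cycle: substrate S is converted to product P by
# enzyme E1 through the complex SE1, and P back to S by enzyme E2
# through PE2.  The system is closed; along every path
#   S + P + SE1 + PE2 = S_total,  E1 + SE1 = E1_total,
#   E2 + PE2 = E2_total.
# With one copy of each enzyme, S and P are strongly anti-correlated
# (S + P is nearly conserved), which is the structure the transposed
# virtual-index ordering compresses well.  All rate constants are of
# unit order.
name: futile-cycle
species: [S, P, SE1, PE2, E1, E2]
window: [128, 128, 2, 2, 2, 2]
initial: [127, 0, 0, 0, 1, 1]
reactions:
  # S + E1 -> SE1
  - stoich: [-1, 0, 1, 0, -1, 0]
    factors: {S: {poly: [0.0, 1.0]}, E1: {poly: [0.0, 1.0]}}
  # SE1 -> S + E1
  - stoich: [1, 0, -1, 0, 1, 0]
    factors: {SE1: {poly: [0.0, 1.0]}}
  # SE1 -> P + E1
  - stoich: [0, 1, -1, 0, 1, 0]
    factors: {SE1: {poly: [0.0, 1.0]}}
  # P + E2 -> PE2
  - stoich: [0, -1, 0, 1, 0, -1]
    factors: {P: {poly: [0.0, 1.0]}, E2: {poly: [0.0, 1.0]}}
  # PE2 -> P + E2
  - stoich: [0, 1, 0, -1, 0, 1]
    factors: {PE2: {poly: [0.0, 1.0]}}
  # PE2 -> S + E2
  - stoich: [1, 0, 0, -1, 0, 1]
    factors: {PE2: {poly: [0.0, 1.0]}}
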