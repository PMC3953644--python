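"""Built-in case-study networks at configurable scale.

The three fixtures -- independent birth-death processes, the genetic
toggle switch, and the enzymatic futile cycle -- are defined in the
versioned YAML files under ``qttcme/models/``; the functions here load
them and apply scale overrides (window sizes, species count, total
substrate) so that the same model runs both at full window sizes and
at the reduced scales used for dense-oracle comparisons.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .network import FSPWindow, PropensityFactor, Reaction, ReactionNetwork

__all__ = ["birth_death", "toggle_switch", "futile_cycle", "load_model_file"]


def _load_yaml(name: str) -> dict:
    text = resources.files("qttcme").joinpath(f"models/{name}.yaml").read_text()
    return yaml.safe_load(text)


def load_model_file(name: str):
    """Load a built-in model by name; returns (network, window)."""
    doc = _load_yaml(name)
    net = ReactionNetwork.from_dict(doc)
    return net, FSPWindow(tuple(doc["window"]))


def birth_death(d: int = 1, n: int = None, b: float = None, delta: float = None):
    """``d`` independent birth-death species on a window of ``n`` states
    each (defaults from the model file: n = 4096, b = 1, delta = 0.1).

    Returns (network, window)."""
    doc = _load_yaml("birth_death")
    b = float(doc["rates"]["b"]) if b is None else float(b)
    delta = float(doc["rates"]["delta"]) if delta is None else float(delta)
    n = int(doc["window"][0]) if n is None else int(n)
    species = [f"X{k + 1}" for k in range(d)]
    reactions = []
    for k in range(d):
        z = [0] * d
        z[k] = 1
        reactions.append(
            Reaction(tuple(z), {k: PropensityFactor("poly", {"coeffs": [b]})})
        )
        z = [0] * d
        z[k] = -1
        reactions.append(
            Reaction(tuple(z), {k: PropensityFactor("poly", {"coeffs": [0.0, delta]})})
        )
    net = ReactionNetwork(species, reactions, name=f"birth-death-d{d}", initial=(0,) * d)
    return net, FSPWindow((n,) * d)


def toggle_switch(n: int = None):
    """Bistable two-repressor toggle switch; ``n`` overrides the
    per-species window size (default 64)."""
    doc = _load_yaml("toggle_switch")
    if n is not None:
        doc["window"] = [int(n), int(n)]
    net = ReactionNetwork.from_dict(doc)
    return net, FSPWindow(tuple(doc["window"]))


def futile_cycle(s_total: int = None):
    """Closed enzymatic futile cycle with one copy of each enzyme.

    ``s_total`` overrides the total substrate (default 127); the S and
    P windows become the next power of two above it and the initial
    state places all substrate in S."""
    doc = _load_yaml("futile_cycle")
    if s_total is not None:
        s_total = int(s_total)
        nsp = 1 << s_total.bit_length()  # smallest power of two > s_total
        doc["window"][0] = doc["window"][1] = nsp
        doc["initial"][0] = s_total
    net = ReactionNetwork.from_dict(doc)
    return net, FSPWindow(tuple(doc["window"]))


def futile_cycle_invariants(net: ReactionNetwork, x0) -> list:
    """The three conserved quantities of the futile cycle as index
    weight vectors, evaluated at ``x0`` for the conserved values."""
    import numpy as np

    idx = {s: k for k, s in enumerate(net.species)}
    w_sub = np.zeros(net.d)
    for s in ("S", "P", "SE1", "PE2"):
        w_sub[idx[s]] = 1.0
    w_e1 = np.zeros(net.d)
    for s in ("E1", "SE1"):
        w_e1[idx[s]] = 1.0
    w_e2 = np.zeros(net.d)
    for s in ("E2", "PE2"):
        w_e2[idx[s]] = 1.0
    x0 = np.asarray(x0, dtype=float)
    return [(w, float(w @ x0)) for w in (w_sub, w_e1, w_e2)]
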