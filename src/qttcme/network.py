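"""Reaction-network model types and the model-file schema.

A network is a list of species and a list of reactions.  Each reaction
carries a stoichiometric vector (net copy-number change) and a
rank-one separable propensity: ``a_j(x) = prod_k w_j^(k)(x_k)`` with
nonnegative per-species factors.  Factors are given as polynomial
coefficients, a repressing Hill function, or a tabulated vector; rate
constants are folded into the factors.  Non-separable propensities are
rejected by construction: the schema only admits per-species factors.

Model files are YAML::

    name: birth-death
    species: [X]
    window: [256]
    initial: [0]
    reactions:
      - stoich: [1]
        factors: {X: {poly: [1.0]}}
      - stoich: [-1]
        factors: {X: {poly: [0.0, 0.1]}}
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "PropensityFactor",
    "Reaction",
    "ReactionNetwork",
    "FSPWindow",
    "SchemaError",
]


class SchemaError(ValueError):
    """Malformed model definition."""


@dataclass(frozen=True)
class PropensityFactor:
    """Single-species propensity factor ``w(x) >= 0``.

    kind 'poly':  params['coeffs'] = [c0, c1, ...], w(x) = sum c_i x^i
    kind 'hill':  params = {vmax, K, n}, w(x) = vmax / (1 + (x/K)^n)
    kind 'table': params['values'] tabulated on {0..len-1}
    """

    kind: str
    params: dict

    def __post_init__(self):
        if self.kind not in ("poly", "hill", "table"):
            raise SchemaError(f"unknown factor kind {self.kind!r}")
        if self.kind == "poly" and not len(self.params.get("coeffs", [])):
            raise SchemaError("poly factor needs nonempty 'coeffs'")
        if self.kind == "hill":
            for key in ("vmax", "K", "n"):
                if key not in self.params:
                    raise SchemaError(f"hill factor needs {key!r}")
        if self.kind == "table" and not len(self.params.get("values", [])):
            raise SchemaError("table factor needs nonempty 'values'")

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        if self.kind == "poly":
            c = np.asarray(self.params["coeffs"], dtype=np.float64)
            return np.polyval(c[::-1], x)
        if self.kind == "hill":
            vmax = float(self.params["vmax"])
            K = float(self.params["K"])
            n = float(self.params["n"])
            return vmax / (1.0 + (x / K) ** n)
        vals = np.asarray(self.params["values"], dtype=np.float64)
        xi = np.clip(x.astype(np.int64), 0, len(vals) - 1)
        return vals[xi]

    def values(self, n: int) -> np.ndarray:
        """Evaluate on the window {0..n-1}."""
        v = self(np.arange(n))
        if np.any(v < -1e-13 * max(1.0, np.max(np.abs(v)))):
            raise ValueError("negative propensity factor on the window")
        return np.maximum(v, 0.0)

    @property
    def poly_degree(self):
        """Polynomial degree if polynomial, else None (used for the
        degree+1 rank bound)."""
        if self.kind != "poly":
            return None
        c = np.asarray(self.params["coeffs"], dtype=np.float64)
        nz = np.nonzero(c)[0]
        return int(nz[-1]) if nz.size else 0

    def to_dict(self):
        if self.kind == "poly":
            return {"poly": [float(c) for c in self.params["coeffs"]]}
        if self.kind == "hill":
            return {"hill": {k: float(self.params[k]) for k in ("vmax", "K", "n")}}
        return {"table": [float(v) for v in self.params["values"]]}

    @staticmethod
    def from_dict(spec) -> "PropensityFactor":
        if not isinstance(spec, dict) or len(spec) != 1:
            raise SchemaError(f"factor spec must be a single-key mapping, got {spec!r}")
        kind, val = next(iter(spec.items()))
        if kind == "poly":
            return PropensityFactor("poly", {"coeffs": list(val)})
        if kind == "hill":
            return PropensityFactor("hill", dict(val))
        if kind == "table":
            return PropensityFactor("table", {"values": list(val)})
        raise SchemaError(f"unknown factor kind {kind!r}")


_ONE = PropensityFactor("poly", {"coeffs": [1.0]})


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: net change ``stoich`` and per-species
    factors (missing species contribute the constant factor 1)."""

    stoich: tuple
    factors: dict  # species index -> PropensityFactor

    def factor(self, k: int) -> PropensityFactor:
        return self.factors.get(k, _ONE)

    def propensity(self, X: np.ndarray) -> np.ndarray:
        """Vectorized propensity at states ``X`` of shape (..., d)."""
        X = np.asarray(X)
        a = np.ones(X.shape[:-1], dtype=np.float64)
        for k, f in self.factors.items():
            a = a * f(X[..., k])
        return a


@dataclass
class ReactionNetwork:
    species: list
    reactions: list
    name: str = "network"
    initial: tuple = None  # deterministic point-mass initial state

    def __post_init__(self):
        if len(self.species) < 1:
            raise SchemaError("need at least one species")
        if len(self.reactions) < 1:
            raise SchemaError("need at least one reaction")
        d = len(self.species)
        for r in self.reactions:
            if len(r.stoich) != d:
                raise SchemaError("stoichiometric vector length != species count")
            for k in r.factors:
                if not 0 <= k < d:
                    raise SchemaError("factor refers to unknown species")
        if self.initial is None:
            self.initial = (0,) * d
        self.initial = tuple(int(x) for x in self.initial)

    @property
    def d(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def propensities(self, X: np.ndarray) -> np.ndarray:
        """All reaction propensities at states ``X`` (..., d) ->
        (..., M)."""
        return np.stack([r.propensity(X) for r in self.reactions], axis=-1)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species),
            "initial": list(self.initial),
            "reactions": [
                {
                    "stoich": [int(z) for z in r.stoich],
                    "factors": {
                        self.species[k]: f.to_dict() for k, f in sorted(r.factors.items())
                    },
                }
                for r in self.reactions
            ],
        }

    @staticmethod
    def from_dict(doc: dict) -> "ReactionNetwork":
        try:
            species = list(doc["species"])
        except (KeyError, TypeError):
            raise SchemaError("model must define 'species'") from None
        if "reactions" not in doc or not doc["reactions"]:
            raise SchemaError("model must define a nonempty 'reactions' list")
        index = {s: k for k, s in enumerate(species)}
        reactions = []
        for i, r in enumerate(doc["reactions"]):
            if "stoich" not in r:
                raise SchemaError(f"reaction {i}: missing 'stoich'")
            factors = {}
            for sname, spec in (r.get("factors") or {}).items():
                if sname not in index:
                    raise SchemaError(f"reaction {i}: unknown species {sname!r}")
                factors[index[sname]] = PropensityFactor.from_dict(spec)
            reactions.append(Reaction(tuple(int(z) for z in r["stoich"]), factors))
        return ReactionNetwork(
            species=species,
            reactions=reactions,
            name=str(doc.get("name", "network")),
            initial=tuple(doc.get("initial", [0] * len(species))),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_yaml(source) -> "ReactionNetwork":
        """Load from a YAML string or file path."""
        text = source
        try:
            import os

            if os.path.exists(str(source)):
                with open(source) as fh:
                    text = fh.read()
        except (OSError, ValueError):
            pass
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise SchemaError("model file must contain a mapping")
        return ReactionNetwork.from_dict(doc)


@dataclass(frozen=True)
class FSPWindow:
    """Rectangular truncation {0..n_1-1} x ... x {0..n_d-1}; sizes are
    powers of two so each species quantizes to binary virtual levels."""

    sizes: tuple

    def __post_init__(self):
        sizes = tuple(int(n) for n in self.sizes)
        for n in sizes:
            if n < 2:
                raise ValueError("window sizes must be >= 2")
            if n & (n - 1):
                raise ValueError(
                    f"window size {n} is not a power of two; "
                    "round up (padding adds states, never removes them)"
                )
        object.__setattr__(self, "sizes", sizes)

    @property
    def d(self) -> int:
        return len(self.sizes)

    @property
    def n_states(self) -> int:
        return int(np.prod([int(n) for n in self.sizes]))

    @property
    def levels(self) -> tuple:
        return tuple(int(n).bit_length() - 1 for n in self.sizes)

    def contains(self, X) -> np.ndarray:
        X = np.asarray(X)
        lo = np.all(X >= 0, axis=-1)
        hi = np.all(X < np.asarray(self.sizes), axis=-1)
        return lo & hi

    @staticmethod
    def for_sizes(requested) -> "FSPWindow":
        """Round requested per-species sizes up to powers of two."""
        out = []
        for n in requested:
            n = max(int(n), 2)
            out.append(1 << (n - 1).bit_length())
        return FSPWindow(tuple(out))
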