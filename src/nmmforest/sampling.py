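"""Parameter-space definition and Latin hypercube designs.

The default :class:`ParameterSpace` covers the 11 model parameters over wide,
experimentally motivated ranges (gains A, B, G; input P; inverse time
constants a, b, g; connectivity scale C; sigmoid v0, e0, r).  Designs are
plain randomised Latin hypercubes: each dimension is cut into n equal-width
strata, each stratum receives exactly one uniformly jittered sample, and the
strata are assigned to rows by an independent random permutation per
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import PARAM_NAMES

__all__ = [
    "DEFAULT_RANGES",
    "RATIO_NAMES",
    "ParameterSpace",
    "latin_hypercube",
    "add_ratio_features",
]

# name -> (nominal, min, max); canonical order
DEFAULT_RANGES = {
    "A": (5.0, 0.0, 10.0),
    "B": (22.0, 0.0, 50.0),
    "G": (20.0, 0.0, 50.0),
    "P": (90.0, 0.0, 2000.0),
    "a": (100.0, 25.0, 140.0),
    "b": (50.0, 6.5, 110.0),
    "g": (500.0, 350.0, 650.0),
    "C": (135.0, 0.0, 1350.0),
    "v0": (6.0, 2.0, 9.0),
    "e0": (2.5, 0.5, 7.5),
    "r": (0.56, 0.3, 0.8),
}

RATIO_NAMES = ("r_A/B", "r_a/b")


@dataclass(frozen=True)
class ParameterSpace:
    """An ordered box of named parameter ranges.

    ``dimensions`` is a tuple of (name, min, max) triples; ``nominal`` maps
    names to nominal values where known.  The default space is the standard
    11-parameter box in canonical order.
    """

    dimensions: tuple = field(
        default_factory=lambda: tuple(
            (name, DEFAULT_RANGES[name][1], DEFAULT_RANGES[name][2])
            for name in PARAM_NAMES
        )
    )
    nominal: dict = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_RANGES.items()}
    )

    def __post_init__(self):
        names = [d[0] for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")
        for name, lo, hi in self.dimensions:
            if not lo < hi:
                raise ValueError(f"dimension {name}: need min < max, got [{lo}, {hi}]")

    @property
    def names(self):
        return tuple(d[0] for d in self.dimensions)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d[1] for d in self.dimensions], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([d[2] for d in self.dimensions], dtype=float)

    def bounds(self, name: str):
        for dname, lo, hi in self.dimensions:
            if dname == name:
                return lo, hi
        raise KeyError(name)

    def nominal_vector(self) -> np.ndarray:
        return np.array([self.nominal[n] for n in self.names], dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSpace":
        """Read ranges from a YAML list of {name, min, max[, nominal]} records."""
        with open(path) as fh:
            records = yaml.safe_load(fh)
        dims, nominal = [], {}
        for rec in records:
            dims.append((str(rec["name"]), float(rec["min"]), float(rec["max"])))
            if "nominal" in rec:
                nominal[str(rec["name"])] = float(rec["nominal"])
        return cls(dimensions=tuple(dims), nominal=nominal)

    def to_yaml(self, path) -> None:
        records = []
        for name, lo, hi in self.dimensions:
            rec = {"name": name, "min": lo, "max": hi}
            if name in self.nominal:
                rec["nominal"] = self.nominal[name]
            records.append(rec)
        with open(path, "w") as fh:
            yaml.safe_dump(records, fh, sort_keys=False)


def latin_hypercube(n: int, space: ParameterSpace = None, seed=0) -> pd.DataFrame:
    """Randomised Latin hypercube design of ``n`` points over ``space``.

    For every dimension, exactly one sample falls in each of the n
    equal-width strata of [min, max]; positions within strata are uniform.
    Reproducible: the same seed yields the same design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if space is None:
        space = ParameterSpace()
    rng = np.random.default_rng(seed)
    p = len(space.dimensions)
    lo, hi = space.lower, space.upper
    cols = np.empty((n, p))
    for j in range(p):
        perm = rng.permutation(n)
        jitter = rng.random(n)
        u = (perm + jitter) / n
        cols[:, j] = lo[j] + u * (hi[j] - lo[j])
    df = pd.DataFrame(cols, columns=list(space.names))
    df.attrs["seed"] = seed
    return df


def add_ratio_features(design: pd.DataFrame) -> pd.DataFrame:
    """Append the ratio features r_A/B = A/B and r_a/b = a/b.

    A zero denominator yields a +infinity sentinel (finite tree thresholds
    route such rows right), never an exception.  Original columns are
    unchanged.
    """
    for col in ("A", "B", "a", "b"):
        if col not in design.columns:
            raise KeyError(f"column {col!r} required for ratio features")
    out = design.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for (num, den), name in zip((("A", "B"), ("a", "b")), RATIO_NAMES):
            ratio = np.where(
                design[den].to_numpy() != 0.0,
                design[num].to_numpy() / design[den].to_numpy(),
                np.inf,
            )
            out[name] = ratio
    return out
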