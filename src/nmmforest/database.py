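"""Building and persisting simulation databases.

``build_database`` runs the full pipeline — Latin hypercube design →
batched integration → feature extraction → class labels — and keeps the
provenance (seed, ranges, solver settings, version) needed to regenerate
the database bit-identically.  Chunking is fixed independently of the
worker count, so the result does not depend on parallelism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .features import BAND_LABELS, SEIZURE_LABELS, extract_features
from .model import PARAM_NAMES
from .sampling import ParameterSpace, RATIO_NAMES, add_ratio_features, latin_hypercube

__all__ = [
    "SimulationDatabase",
    "build_database",
    "save_database",
    "load_database",
    "target_labels",
    "fit_target_forest",
    "TARGETS",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["amplitude_mV", "frequency_Hz", "peaks_per_cycle", "label"]

#: forest targets mirroring the four dynamic characteristics of interest
TARGETS = ("steady_state", "amplitude", "frequency", "seizure")

_CHUNK = 512  # rows per integration chunk, fixed for reproducibility


@dataclass
class SimulationDatabase:
    """Design matrix + extracted features + provenance."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in FEATURE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def parameter_names(self) -> list:
        return [c for c in self.df.columns if c not in FEATURE_COLUMNS]

    @property
    def n_divergent(self) -> int:
        return int((self.df["label"] == "divergent").sum())

    def class_fractions(self, include_divergent: bool = False) -> pd.Series:
        """Fraction of rows per class label (divergent rows excluded from
        the denominator by default, but always reported in provenance)."""
        labels = self.df["label"]
        if not include_divergent:
            labels = labels[labels != "divergent"]
        return labels.value_counts(normalize=True).reindex(
            feat.CLASS_LABELS, fill_value=0.0
        )

    def seizure_fraction(self) -> float:
        frac = self.class_fractions()
        return float(sum(frac[lbl] for lbl in SEIZURE_LABELS))

    def with_ratios(self) -> "SimulationDatabase":
        """Return a copy with the ratio columns r_A/B and r_a/b appended."""
        if all(r in self.df.columns for r in RATIO_NAMES):
            return self
        params = self.df[self.parameter_names]
        out = add_ratio_features(params)
        for c in FEATURE_COLUMNS:
            out[c] = self.df[c].to_numpy()
        prov = dict(self.provenance, ratios=True)
        return SimulationDatabase(out, prov)


def _simulate_chunk(chunk: np.ndarray, sim_config: dict) -> pd.DataFrame:
    from .model import simulate_batch

    _, outputs, divergent = simulate_batch(chunk, **sim_config)
    fs = sim_config.get("sample_rate", 512.0)
    return extract_features(outputs, fs, divergent)


def build_database(
    space: ParameterSpace = None,
    n: int = 2000,
    seed=0,
    sim_config: dict = None,
    workers: int = 1,
) -> SimulationDatabase:
    """Design, simulate and classify ``n`` parameter sets.

    ``sim_config`` is forwarded to :func:`~nmmforest.model.simulate_batch`
    (duration, burn_in, sample_rate, dt, initial_state).  The result is
    independent of ``workers``: rows are always processed in fixed chunks
    whose outcome depends only on the design.
    """
    if space is None:
        space = ParameterSpace()
    sim_config = dict(sim_config or {})
    design = latin_hypercube(n, space, seed=seed)
    X = design.to_numpy()
    chunks = [X[i:i + _CHUNK] for i in range(0, n, _CHUNK)]

    if workers > 1:
        try:
            from joblib import Parallel, delayed
            parts = Parallel(n_jobs=workers)(
                delayed(_simulate_chunk)(c, sim_config) for c in chunks
            )
        except ImportError:  # pragma: no cover - joblib is optional
            log.warning("joblib unavailable; running single-threaded")
            parts = [_simulate_chunk(c, sim_config) for c in chunks]
    else:
        parts = [_simulate_chunk(c, sim_config) for c in chunks]
    features = pd.concat(parts, ignore_index=True)

    df = design.copy()
    for c in FEATURE_COLUMNS:
        df[c] = features[c].to_numpy()
    n_div = int((df["label"] == "divergent").sum())
    if n_div:
        log.info("%d / %d simulations diverged", n_div, n)

    from . import __version__

    provenance = {
        "seed": int(seed) if np.isscalar(seed) else seed,
        "n": int(n),
        "ranges": [list(d) for d in space.dimensions],
        "sim_config": {
            k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
            for k, v in sim_config.items()
        },
        "n_divergent": n_div,
        "version": __version__,
    }
    return SimulationDatabase(df, provenance)


def save_database(db: SimulationDatabase, path) -> None:
    """Persist as CSV or Parquet (by suffix) plus a JSON provenance sidecar."""
    path = Path(path)
    if path.suffix == ".parquet":
        db.df.to_parquet(path, index=False)
    elif path.suffix == ".csv":
        db.df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported database format {path.suffix!r}")
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(db.provenance, fh, indent=1)


def load_database(path) -> SimulationDatabase:
    """Load a saved database; missing provenance or schema is an error."""
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not path.exists():
        raise FileNotFoundError(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing provenance sidecar {meta_path}")
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unsupported database format {path.suffix!r}")
    with open(meta_path) as fh:
        provenance = json.load(fh)
    db = SimulationDatabase(df, provenance)
    if provenance.get("n") is not None and db.n != provenance["n"]:
        raise ValueError(
            f"database has {db.n} rows but provenance records {provenance['n']}"
        )
    return db


def target_labels(df: pd.DataFrame, target: str):
    """Build (labels, row_mask) for one of the four forest targets.

    * ``steady_state``: binary steady vs cycle, divergent rows dropped.
    * ``amplitude``: oscillatory rows only; amplitude split into quartile
      classes q1..q4.
    * ``frequency``: single-peak oscillatory rows; label = clinical band.
    * ``seizure``: binary (poly)spike-wave vs everything else.
    """
    labels = df["label"]
    valid = labels != "divergent"
    if target == "steady_state":
        y = np.where(labels == "steady_state", "steady", "cycle")
        return y[valid.to_numpy()], valid.to_numpy()
    if target == "seizure":
        y = np.where(labels.isin(SEIZURE_LABELS), "seizure", "rest")
        return y[valid.to_numpy()], valid.to_numpy()
    if target == "frequency":
        mask = labels.isin(BAND_LABELS).to_numpy()
        return labels.to_numpy()[mask], mask
    if target == "amplitude":
        mask = (valid & (labels != "steady_state")).to_numpy()
        amp = df.loc[mask, "amplitude_mV"].to_numpy()
        edges = np.quantile(amp, [0.25, 0.5, 0.75])
        y = np.array(["q1", "q2", "q3", "q4"])[np.searchsorted(edges, amp)]
        return y, mask
    raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")


def fit_target_forest(
    db: SimulationDatabase,
    target: str,
    ratios: bool = False,
    B: int = 100,
    mtry=None,
    min_leaf: int = 50,
    seed=0,
    **fit_kwargs,
):
    """Fit a random forest for one dynamic characteristic of the database.

    With ``ratios=True`` the feature space is augmented with r_A/B and
    r_a/b (13 features).  Returns a fitted
    :class:`~nmmforest.forest.ForestResults`.
    """
    from .forest import RandomForest

    if ratios:
        db = db.with_ratios()
    y, mask = target_labels(db.df, target)
    X = db.df.loc[mask, db.parameter_names]
    forest = RandomForest(X, y, feature_names=db.parameter_names, target=target)
    return forest.fit(B=B, mtry=mtry, min_leaf=min_leaf, seed=seed, **fit_kwargs)
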