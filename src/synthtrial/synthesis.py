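"""Sequential tree-based synthesis of patient-level trial tables.

Variables are synthesized one at a time in a fixed visit sequence
(covariates first, then the endpoint variables with each event flag before
its time).  The first visited variable is drawn by bootstrap from its
empirical donor pool; every later variable is modelled by a decision tree
(CART) or a bootstrap ensemble of trees (RF) fitted on the variables
visited before it, with each leaf retaining the indices of its training
donors.  A synthetic value is produced by routing the partially
synthesized record to a leaf and drawing uniformly from that leaf's
donors, so synthetic values are always a subset of observed training
values.

Records that violate the survival-ordering constraints
(``pfs > 0``, ``os > 0``, ``pfs <= os``) are discarded wholesale and
regenerated with fresh randomness until the requested record count is
reached, matching the reject-and-regenerate protocol of constraint-aware
synthesis.  All sampling uses a Mersenne-Twister generator so that a run
is exactly reproducible from its integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data import TrialTable, VariableSchema

__all__ = [
    "SynthesisError",
    "Hyperparameters",
    "SynthModel",
    "make_seed_set",
    "fit_synthesizer",
    "synthesize",
    "check_constraints",
    "TreeSynthesizer",
    "BootstrapResampler",
    "TimeScaledGenerator",
    "register_generator",
    "get_generator",
    "GENERATORS",
]

CONSTRAINT_RULES = ("pfs_time > 0", "os_time > 0", "pfs_time <= os_time")


class SynthesisError(RuntimeError):
    """Constraint-satisfying records could not be produced in time."""


def make_seed_set(master_seed: int, count: int) -> list[int]:
    """Deterministic list of ``count`` distinct 31-bit replicate seeds.

    Seeds are drawn with the Mersenne-Twister algorithm from the master
    seed; the same master seed always yields the same list, and the same
    list is shared by every generation method in a study.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rs = np.random.RandomState(master_seed)  # MT19937
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < count:
        for v in rs.randint(0, 2**31 - 1, size=count):
            v = int(v)
            if v not in seen:
                seen.add(v)
                out.append(v)
                if len(out) == count:
                    break
    return out


@dataclass(frozen=True)
class Hyperparameters:
    """Tree-growing controls shared by the CART and RF variants."""

    min_leaf: int = 5
    max_depth: int | None = None
    n_trees: int = 10  # RF only
    max_features: float | str | None = "sqrt"  # RF feature subsetting
    fit_seed: int = 0  # makes RF bootstraps and tie-breaks reproducible


@dataclass(frozen=True)
class _Encoder:
    """Maps one variable's raw values to the numeric codes trees consume."""

    name: str
    kind: Literal["numeric", "categorical"]
    levels: tuple = ()  # observed categorical levels, stable sorted order

    def encode(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "numeric":
            return np.asarray(values, dtype=float)
        lookup = {lvl: i for i, lvl in enumerate(self.levels)}
        return np.array([lookup[_as_level(v)] for v in values], dtype=float)


def _as_level(v) -> str:
    return str(v)


@dataclass(frozen=True)
class _DonorLeaves:
    """One fitted tree plus the raw training-donor values per leaf."""

    tree: DecisionTreeRegressor | DecisionTreeClassifier
    donors: dict[int, np.ndarray]  # leaf id -> raw donor values (non-empty)

    def leaf_for(self, x: np.ndarray) -> np.ndarray:
        return self.tree.apply(np.asarray(x, dtype=np.float32))


@dataclass(frozen=True)
class _Component:
    """Fitted synthesis component for one variable.

    ``pool`` alone: donor-pool bootstrap (first variable, or a variable
    with a single observed value).  Otherwise one ``_DonorLeaves`` for
    CART or several for RF.
    """

    name: str
    pool: np.ndarray | None = None
    leaves: tuple[_DonorLeaves, ...] = ()


@dataclass(frozen=True)
class SynthModel:
    """A fitted sequential synthesizer: one component per visited variable."""

    schema: VariableSchema
    method: Literal["cart", "rf"]
    hyper: Hyperparameters
    visit_sequence: tuple[str, ...]
    components: tuple[_Component, ...]
    encoders: dict[str, _Encoder]
    n_train: int


def _variable_kind(schema: VariableSchema, name: str) -> str:
    """Modelling kind: event flags are treated as categorical, times as numeric."""
    v = schema.variable(name)
    if v.role in ("pfs_event", "os_event") or v.vartype == "categorical":
        return "categorical"
    return "numeric"


def _make_encoder(schema: VariableSchema, name: str, values: np.ndarray) -> _Encoder:
    if _variable_kind(schema, name) == "categorical":
        levels = tuple(sorted({_as_level(v) for v in values}))
        return _Encoder(name, "categorical", levels)
    return _Encoder(name, "numeric")


def _fit_tree(
    x: np.ndarray,
    y_enc: np.ndarray,
    y_raw: np.ndarray,
    categorical: bool,
    hyper: Hyperparameters,
    max_features,
    random_state: int,
) -> _DonorLeaves:
    cls = DecisionTreeClassifier if categorical else DecisionTreeRegressor
    tree = cls(
        min_samples_leaf=hyper.min_leaf,
        max_depth=hyper.max_depth,
        max_features=max_features,
        random_state=random_state,
    )
    x32 = np.asarray(x, dtype=np.float32)
    tree.fit(x32, y_enc)
    leaf_ids = tree.apply(x32)
    donors = {int(l): y_raw[leaf_ids == l] for l in np.unique(leaf_ids)}
    return _DonorLeaves(tree, donors)


def fit_synthesizer(
    table: TrialTable,
    method: Literal["cart", "rf"] = "cart",
    hyper: Hyperparameters = Hyperparameters(),
) -> SynthModel:
    """Fit the per-variable synthesis components in visit order.

    The first visited variable keeps its empirical donor pool.  Each later
    variable gets a regression tree (numeric) or classification tree
    (categorical) on all previously visited variables; the RF variant
    grows ``n_trees`` trees, each on a bootstrap resample with random
    feature subsetting, and each leaf keeps its in-bag donors.  A variable
    with a single observed value is fitted as a constant donor pool, with
    a warning.
    """
    if method not in ("cart", "rf"):
        raise ValueError(f"unknown method {method!r}")
    if table.n < 2 * hyper.min_leaf:
        raise ValueError(f"need at least 2*min_leaf={2 * hyper.min_leaf} training rows")
    schema = table.schema
    seq = tuple(schema.synthesis_order())
    df = table.df
    encoders = {name: _make_encoder(schema, name, df[name].to_numpy()) for name in seq}
    fit_rng = np.random.RandomState(hyper.fit_seed)

    components: list[_Component] = []
    x_cols: list[np.ndarray] = []
    for j, name in enumerate(seq):
        y_raw = df[name].to_numpy()
        y_enc = encoders[name].encode(y_raw)
        if j == 0 or len(np.unique(y_enc)) < 2:
            if j > 0:
                warnings.warn(
                    f"variable {name!r} has a single observed value; fitted as constant",
                    stacklevel=2,
                )
            components.append(_Component(name, pool=y_raw.copy()))
        else:
            x = np.column_stack(x_cols)
            categorical = _variable_kind(schema, name) == "categorical"
            if method == "cart":
                leaves = (
                    _fit_tree(x, y_enc, y_raw, categorical, hyper, None, hyper.fit_seed),
                )
            else:
                n = table.n
                grown = []
                for _ in range(hyper.n_trees):
                    boot = fit_rng.randint(0, n, size=n)
                    grown.append(
                        _fit_tree(
                            x[boot],
                            y_enc[boot],
                            y_raw[boot],
                            categorical,
                            hyper,
                            hyper.max_features if x.shape[1] > 1 else None,
                            int(fit_rng.randint(0, 2**31 - 1)),
                        )
                    )
                leaves = tuple(grown)
            components.append(_Component(name, leaves=leaves))
        x_cols.append(y_enc)
    return SynthModel(schema, method, hyper, seq, tuple(components), encoders, table.n)


def _sample_from_leaves(
    dl: _DonorLeaves, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Route rows of ``x`` to leaves and draw one donor per row."""
    leaf_ids = dl.leaf_for(x)
    out = np.empty(len(x), dtype=object)
    for leaf in np.unique(leaf_ids):
        idx = np.flatnonzero(leaf_ids == leaf)
        pool = dl.donors[int(leaf)]
        out[idx] = pool[rng.integers(0, len(pool), size=len(idx))]
    return out


def _generate_batch(model: SynthModel, m: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    x_cols: list[np.ndarray] = []
    for comp in model.components:
        if comp.pool is not None:
            vals = comp.pool[rng.integers(0, len(comp.pool), size=m)]
        else:
            x = np.column_stack(x_cols)
            if model.method == "cart":
                vals = _sample_from_leaves(comp.leaves[0], x, rng)
            else:
                which = rng.integers(0, len(comp.leaves), size=m)
                vals = np.empty(m, dtype=object)
                for t in range(len(comp.leaves)):
                    idx = np.flatnonzero(which == t)
                    if len(idx):
                        vals[idx] = _sample_from_leaves(comp.leaves[t], x[idx], rng)
        cols[comp.name] = vals
        x_cols.append(model.encoders[comp.name].encode(vals))
    return pd.DataFrame(cols)


def check_constraints(row) -> tuple[bool, list[str]]:
    """Evaluate the survival-ordering rules on one record (mapping-like)."""
    pfs, os_ = float(row["pfs_time"]), float(row["os_time"])
    violated = []
    if not pfs > 0:
        violated.append("pfs_time > 0")
    if not os_ > 0:
        violated.append("os_time > 0")
    if not pfs <= os_:
        violated.append("pfs_time <= os_time")
    return (not violated), violated


def _constraint_mask(model: SynthModel, batch: pd.DataFrame) -> np.ndarray:
    sch = model.schema
    pt = batch[sch.endpoint_name("pfs_time")].to_numpy(float)
    ot = batch[sch.endpoint_name("os_time")].to_numpy(float)
    return (pt > 0) & (ot > 0) & (pt <= ot)


def synthesize(model: SynthModel, n: int, seed: int, max_rounds: int = 1000) -> TrialTable:
    """Draw exactly ``n`` constraint-satisfying synthetic records.

    Violating records are discarded wholesale and regenerated with fresh
    randomness from the same models.  Deterministic given
    ``(model, n, seed)``.  Raises :class:`SynthesisError` if ``max_rounds``
    regeneration rounds cannot fill the table, reporting the rejection
    rate per violated rule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.Generator(np.random.MT19937(seed))
    kept: list[pd.DataFrame] = []
    n_kept = 0
    n_drawn = 0
    rule_rejections = dict.fromkeys(CONSTRAINT_RULES, 0)
    for _ in range(max_rounds + 1):
        need = n - n_kept
        batch = _generate_batch(model, need, rng)
        mask = _constraint_mask(model, batch)
        if not mask.all():
            sch = model.schema
            pt = batch[sch.endpoint_name("pfs_time")].to_numpy(float)
            ot = batch[sch.endpoint_name("os_time")].to_numpy(float)
            rule_rejections["pfs_time > 0"] += int((~(pt > 0)).sum())
            rule_rejections["os_time > 0"] += int((~(ot > 0)).sum())
            rule_rejections["pfs_time <= os_time"] += int((pt > ot).sum())
        n_drawn += need
        good = batch.loc[mask]
        if len(good):
            kept.append(good)
            n_kept += len(good)
        if n_kept == n:
            df = pd.concat(kept, ignore_index=True) if len(kept) > 1 else kept[0]
            df = df.reset_index(drop=True)
            for name in model.visit_sequence:
                if model.encoders[name].kind == "numeric":
                    df[name] = df[name].astype(float)
            return TrialTable(model.schema, df.loc[:, model.schema.names])
    worst = max(rule_rejections, key=rule_rejections.get)
    raise SynthesisError(
        f"could not produce {n} constraint-satisfying records in {max_rounds} "
        f"regeneration rounds; dominant violated rule {worst!r} "
        f"(overall rejection rate {1 - n_kept / max(n_drawn, 1):.3f})"
    )


# ---------------------------------------------------------------------------
# Pluggable generator interface for the study runner


class TreeSynthesizer:
    """The package's sequential tree synthesizer behind the generator contract.

    Any object exposing ``fit(table)`` and ``sample(n, seed) -> TrialTable``
    can be registered for a study; this is the built-in implementation for
    the ``cart`` and ``rf`` methods.
    """

    def __init__(self, method: Literal["cart", "rf"] = "cart",
                 hyper: Hyperparameters = Hyperparameters(), max_rounds: int = 1000):
        self.method = method
        self.hyper = hyper
        self.max_rounds = max_rounds
        self.model: SynthModel | None = None

    def fit(self, table: TrialTable) -> "TreeSynthesizer":
        self.model = fit_synthesizer(table, self.method, self.hyper)
        return self

    def sample(self, n: int, seed: int) -> TrialTable:
        if self.model is None:
            raise RuntimeError("fit() must be called before sample()")
        return synthesize(self.model, n, seed, self.max_rounds)


class BootstrapResampler:
    """Baseline generator: resample whole training rows with replacement.

    Constraint-satisfying by construction; useful as a calibration
    reference because its medians behave like bootstrap medians.
    """

    def __init__(self) -> None:
        self.table: TrialTable | None = None

    def fit(self, table: TrialTable) -> "BootstrapResampler":
        self.table = table
        return self

    def sample(self, n: int, seed: int) -> TrialTable:
        if self.table is None:
            raise RuntimeError("fit() must be called before sample()")
        rng = np.random.Generator(np.random.MT19937(seed))
        idx = rng.integers(0, self.table.n, size=n)
        return TrialTable(self.table.schema, self.table.df.iloc[idx].reset_index(drop=True))


class TimeScaledGenerator:
    """Deliberately misspecified generator: base output with times scaled.

    Wraps another generator and multiplies both endpoint times by a
    constant factor.  Serves as a negative control: a sound evaluation
    battery must rank it below a faithful generator.
    """

    def __init__(self, base=None, factor: float = 3.0):
        self.base = base if base is not None else TreeSynthesizer("cart")
        self.factor = factor

    def fit(self, table: TrialTable) -> "TimeScaledGenerator":
        self.base.fit(table)
        return self

    def sample(self, n: int, seed: int) -> TrialTable:
        t = self.base.sample(n, seed)
        df = t.df.copy()
        for role in ("pfs_time", "os_time"):
            col = t.schema.endpoint_name(role)
            df[col] = df[col].astype(float) * self.factor
        return TrialTable(t.schema, df)


GENERATORS: dict[str, type | object] = {}


def register_generator(name: str, factory) -> None:
    """Register a generator factory (callable returning fit/sample objects)."""
    GENERATORS[name] = factory


def get_generator(name: str):
    try:
        return GENERATORS[name]()
    except KeyError:
        raise KeyError(
            f"unknown generator {name!r}; registered: {sorted(GENERATORS)}"
        ) from None


register_generator("cart", lambda: TreeSynthesizer("cart"))
register_generator("rf", lambda: TreeSynthesizer("rf"))
register_generator("resample", BootstrapResampler)
register_generator("scaled", TimeScaledGenerator)
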