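"""Typed DAG containers, topology generators, and the factorized joint density.

A Bayesian network over variables ``X1..Xp`` is a directed acyclic graph (DAG)
whose joint density factorizes node-by-node::

    P(X1, ..., Xp) = prod_i P(Xi | parents(Xi))

Nodes are *typed*: each variable is either continuous or discrete (with a
declared number of levels).  Mixed networks obey the constraint that a
discrete child may only have discrete parents; continuous children may have
parents of any kind.  The containers here hold structure
(:class:`TypedDag`) and, optionally, the per-node conditional distributions
(:class:`ParameterizedNetwork`) used by the simulator and by
:func:`log_joint`.

Two ground-truth topology generators are provided:

* :func:`generate_random_dag` — fix a uniformly random topological order and
  include each forward pair independently, with the inclusion probability set
  so the expected in-degree equals ``mean_parents``.
* :func:`generate_scale_free_dag` — preferential attachment, with every edge
  oriented from an older node to a newer one, which guarantees acyclicity by
  construction.  Scale-free topology is restricted to all-continuous
  networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import networkx as nx
import numpy as np

from .exceptions import (
    CyclicStructureError,
    InvalidArgumentError,
    InvalidValueError,
    MixedConstraintError,
    UnsupportedCombinationError,
)

CONTINUOUS = "continuous"
DISCRETE = "discrete"

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class VariableSpec:
    """One node: a name, a kind, and (for discrete nodes) a level count."""

    name: str
    kind: str = CONTINUOUS
    levels: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, DISCRETE):
            raise InvalidArgumentError(f"unknown variable kind {self.kind!r}")
        if self.kind == DISCRETE:
            if self.levels is None or int(self.levels) < 2:
                raise InvalidArgumentError(
                    f"discrete variable {self.name!r} needs levels >= 2, got {self.levels!r}"
                )
            object.__setattr__(self, "levels", int(self.levels))
        elif self.levels is not None:
            raise InvalidArgumentError(
                f"continuous variable {self.name!r} must not declare levels"
            )

    @property
    def is_discrete(self) -> bool:
        return self.kind == DISCRETE


@dataclass(frozen=True)
class TypedDag:
    """A typed directed acyclic graph: the structure container.

    ``variables`` is the ordered node list; ``edges`` is a set of
    ``(parent, child)`` name pairs.  Validation enforces unique names, known
    endpoints, no self-edges, the discrete-parents-only rule for discrete
    children, and acyclicity.
    """

    variables: tuple[VariableSpec, ...]
    edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(
            self, "edges", frozenset((str(u), str(v)) for u, v in self.edges)
        )
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("duplicate variable names")
        known = set(names)
        kind = {v.name: v.kind for v in self.variables}
        for u, v in self.edges:
            if u not in known or v not in known:
                raise InvalidArgumentError(f"edge ({u}, {v}) references unknown node")
            if u == v:
                raise InvalidArgumentError(f"self-edge on {u}")
            if kind[v] == DISCRETE and kind[u] == CONTINUOUS:
                raise MixedConstraintError(
                    f"continuous parent {u} of discrete child {v}"
                )
        topological_order(self)  # raises CyclicStructureError on a cycle

    # -- basic accessors -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def p(self) -> int:
        return len(self.variables)

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def parents(self, name: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == name))

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(sorted(v for u, v in self.edges if u == name))

    def in_degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.names}
        for _, v in self.edges:
            deg[v] += 1
        return deg

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.names))
        g.add_edges_from(sorted(self.edges))
        return g


def topological_order(dag: TypedDag) -> list[str]:
    """Topological order of ``dag``, deterministic via name-order tie-breaks.

    Raises :class:`CyclicStructureError` if the edge set contains a directed
    cycle; this doubles as the acyclicity check used by the validators.
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(n for n in (v.name for v in dag.variables)))
    g.add_edges_from(sorted(dag.edges))
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise CyclicStructureError("graph contains a directed cycle") from exc


# ---------------------------------------------------------------------------
# topology generators
# ---------------------------------------------------------------------------

def _node_names(p: int) -> list[str]:
    width = max(2, len(str(p)))
    return [f"X{i + 1:0{width}d}" for i in range(p)]


def _draw_kinds(
    p: int,
    types: str,
    discrete_fraction: float,
    levels_choices: Sequence[int],
    rng: np.random.Generator,
) -> list[VariableSpec]:
    names = _node_names(p)
    if types == CONTINUOUS:
        return [VariableSpec(n, CONTINUOUS) for n in names]
    if types == DISCRETE:
        levels = rng.choice(list(levels_choices), size=p)
        return [VariableSpec(n, DISCRETE, int(l)) for n, l in zip(names, levels)]
    if types == "mixed":
        disc = rng.random(p) < discrete_fraction
        # a mixed network should actually mix: force at least one of each kind
        if disc.all():
            disc[int(rng.integers(p))] = False
        if not disc.any():
            disc[int(rng.integers(p))] = True
        levels = rng.choice(list(levels_choices), size=p)
        return [
            VariableSpec(n, DISCRETE, int(l)) if d else VariableSpec(n, CONTINUOUS)
            for n, d, l in zip(names, disc, levels)
        ]
    raise InvalidArgumentError(f"unknown type scheme {types!r}")


def generate_random_dag(
    p: int,
    mean_parents: float,
    types: str = CONTINUOUS,
    seed: SeedLike = 0,
    *,
    discrete_fraction: float = 0.5,
    max_discrete_parents: int = 3,
    levels_choices: Sequence[int] = (2, 3),
) -> TypedDag:
    """Random DAG with expected in-degree ``mean_parents``.

    A uniformly random topological order is fixed, then each forward pair is
    included independently with probability ``2 * mean_parents / (p - 1)``
    (clamped to 1), which makes the expected number of edges
    ``p * mean_parents``.  Under mixed typing, continuous->discrete pairs are
    never included, and discrete children are capped at
    ``max_discrete_parents`` parents so their conditional tables stay small.
    """
    if p < 1:
        raise InvalidArgumentError("p must be >= 1")
    if mean_parents < 0:
        raise InvalidArgumentError("mean_parents must be >= 0")
    if mean_parents >= p:
        raise InvalidArgumentError("mean_parents must be < p")
    rng = as_rng(seed)
    specs = _draw_kinds(p, types, discrete_fraction, levels_choices, rng)
    order = rng.permutation(p)
    q = 0.0 if p == 1 else min(1.0, 2.0 * mean_parents / (p - 1))
    u = rng.random((p, p))  # one draw per ordered position pair; upper triangle used
    is_disc = np.array([specs[order[j]].is_discrete for j in range(p)])
    include = u < q
    include[np.tril_indices(p)] = False
    # mixed constraint: no continuous parent for a discrete child
    if is_disc.any():
        cont_rows = ~is_disc
        include[np.ix_(cont_rows, is_disc)] = False
    edges: set[tuple[str, str]] = set()
    for j in range(p):
        incoming = np.nonzero(include[:, j])[0]
        if is_disc[j] and len(incoming) > max_discrete_parents:
            keep = rng.choice(len(incoming), size=max_discrete_parents, replace=False)
            incoming = incoming[np.sort(keep)]
        child = specs[order[j]].name
        edges.update((specs[order[i]].name, child) for i in incoming)
    return TypedDag(tuple(specs), frozenset(edges))


def generate_scale_free_dag(
    p: int, attachment_edges: int, seed: SeedLike = 0, types: str = CONTINUOUS
) -> TypedDag:
    """Scale-free DAG by preferential attachment, all nodes continuous.

    Each new node attaches to ``attachment_edges`` existing nodes with
    probability proportional to their current degree; edges point old -> new,
    so the arrival order is a topological order and the graph is acyclic with
    a heavy-tailed out-degree distribution.
    """
    if types != CONTINUOUS:
        raise UnsupportedCombinationError(
            "scale-free topology is only supported for all-continuous networks"
        )
    if p < 2:
        raise InvalidArgumentError("p must be >= 2 for preferential attachment")
    if attachment_edges < 1:
        raise InvalidArgumentError("attachment_edges must be >= 1")
    rng = as_rng(seed)
    g = nx.barabasi_albert_graph(p, attachment_edges, seed=rng)
    names = _node_names(p)
    specs = tuple(VariableSpec(n, CONTINUOUS) for n in names)
    # nx adds nodes in index order; orient each undirected edge old -> new
    edges = frozenset(
        (names[min(u, v)], names[max(u, v)]) for u, v in g.edges()
    )
    return TypedDag(specs, edges)


# ---------------------------------------------------------------------------
# conditional distributions and the parameterized network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearGaussianCpd:
    """X_child ~ Normal(intercept + sum_j beta_j * x_j, sigma2)."""

    betas: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", dict(self.betas))
        if self.sigma2 <= 0:
            raise InvalidArgumentError("sigma2 must be positive")

    @property
    def parent_names(self) -> frozenset[str]:
        return frozenset(self.betas)


@dataclass(frozen=True)
class MultinomialCpd:
    """CPT for a discrete child: one probability row per parent configuration.

    ``parents`` is the (sorted) parent name tuple; ``table`` maps a tuple of
    parent levels (aligned with ``parents``) to a probability vector over the
    child's levels.
    """

    parents: tuple[str, ...]
    table: Mapping[tuple[int, ...], tuple[float, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        tbl = {
            tuple(int(x) for x in key): tuple(float(v) for v in row)
            for key, row in self.table.items()
        }
        object.__setattr__(self, "table", tbl)
        for key, row in tbl.items():
            if len(key) != len(self.parents):
                raise InvalidArgumentError("CPT key arity != number of parents")
            if any(v < 0 for v in row):
                raise InvalidArgumentError("CPT entries must be >= 0")
            if abs(sum(row) - 1.0) > 1e-9:
                raise InvalidArgumentError("CPT row must sum to 1 within 1e-9")

    @property
    def parent_names(self) -> frozenset[str]:
        return frozenset(self.parents)


@dataclass(frozen=True)
class CgComponent:
    """Regression for one discrete-parent configuration of a CG node."""

    betas: tuple[float, ...]
    intercept: float
    sigma2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if self.sigma2 <= 0:
            raise InvalidArgumentError("sigma2 must be positive")


@dataclass(frozen=True)
class ConditionalGaussianCpd:
    """Continuous child with discrete (and possibly continuous) parents.

    For each configuration of the discrete parents there is a linear-Gaussian
    regression on the continuous parents; marginally the child follows a
    Gaussian mixture.
    """

    discrete_parents: tuple[str, ...]
    continuous_parents: tuple[str, ...]
    components: Mapping[tuple[int, ...], CgComponent]

    def __post_init__(self) -> None:
        object.__setattr__(self, "discrete_parents", tuple(self.discrete_parents))
        object.__setattr__(self, "continuous_parents", tuple(self.continuous_parents))
        comps = {
            tuple(int(x) for x in key): c for key, c in self.components.items()
        }
        object.__setattr__(self, "components", comps)
        for key, comp in comps.items():
            if len(key) != len(self.discrete_parents):
                raise InvalidArgumentError("component key arity != #discrete parents")
            if len(comp.betas) != len(self.continuous_parents):
                raise InvalidArgumentError("component betas arity != #continuous parents")

    @property
    def parent_names(self) -> frozenset[str]:
        return frozenset(self.discrete_parents) | frozenset(self.continuous_parents)


Cpd = Union[LinearGaussianCpd, MultinomialCpd, ConditionalGaussianCpd]


@dataclass(frozen=True)
class ParameterizedNetwork:
    """A TypedDag plus one conditional distribution per node."""

    dag: TypedDag
    cpds: Mapping[str, Cpd]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpds", dict(self.cpds))
        names = set(self.dag.names)
        if set(self.cpds) != names:
            raise InvalidArgumentError("cpds must cover exactly the dag's nodes")
        for name, cpd in self.cpds.items():
            want = frozenset(self.dag.parents(name))
            if cpd.parent_names != want:
                raise InvalidArgumentError(
                    f"cpd parents of {name} = {sorted(cpd.parent_names)} "
                    f"!= dag parents {sorted(want)}"
                )
            spec = self.dag.spec(name)
            if spec.is_discrete and not isinstance(cpd, MultinomialCpd):
                raise InvalidArgumentError(f"discrete node {name} needs a MultinomialCpd")
            if not spec.is_discrete and isinstance(cpd, MultinomialCpd):
                raise InvalidArgumentError(f"continuous node {name} cannot use a CPT")


_LOG_2PI = math.log(2.0 * math.pi)


def _normal_logpdf(x: float, mean: float, sigma2: float) -> float:
    return -0.5 * (_LOG_2PI + math.log(sigma2) + (x - mean) ** 2 / sigma2)


def log_joint(network: ParameterizedNetwork, sample: Mapping[str, float]) -> float:
    """log P(sample) = sum_i log P(x_i | parents(x_i)) under the node CPDs."""
    total = 0.0
    for spec in network.dag.variables:
        name = spec.name
        cpd = network.cpds[name]
        if spec.is_discrete:
            value = int(sample[name])
            if not 0 <= value < spec.levels:
                raise InvalidValueError(
                    f"value {value} outside levels [0, {spec.levels}) for {name}"
                )
            assert isinstance(cpd, MultinomialCpd)
            key = tuple(int(sample[p]) for p in cpd.parents)
            row = cpd.table[key]
            prob = row[value]
            total += -math.inf if prob == 0 else math.log(prob)
        elif isinstance(cpd, LinearGaussianCpd):
            mean = cpd.intercept + sum(
                b * float(sample[p]) for p, b in cpd.betas.items()
            )
            total += _normal_logpdf(float(sample[name]), mean, cpd.sigma2)
        else:
            assert isinstance(cpd, ConditionalGaussianCpd)
            key = tuple(int(sample[p]) for p in cpd.discrete_parents)
            comp = cpd.components[key]
            mean = comp.intercept + sum(
                b * float(sample[p])
                for p, b in zip(cpd.continuous_parents, comp.betas)
            )
            total += _normal_logpdf(float(sample[name]), mean, comp.sigma2)
    return total
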