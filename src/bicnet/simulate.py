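"""Linear structural-equation-model (SEM) simulator for benchmark networks.

Ground-truth networks are drawn by the topology generators, parameterized by
the generalized linear SEM scheme, and sampled ancestrally:

* continuous child, continuous parents::

      X_i ~ Normal( sum_{j in parents(i)} beta_ji * X_j , sigma_i^2 )

  with ``beta_ji = s * |b|``, ``b ~ Normal(2, 0.8)``, the sign ``s`` positive
  with probability 0.5 (positive vs. negative regulation), and
  ``sigma_i^2 ~ Normal(1, 0.01)`` truncated below at 1e-3;

* discrete child: multinomial draw from a conditional probability table whose
  rows are Dirichlet(1, ..., 1) samples, rejection-sampled until every pair
  of rows that differ in a single parent level is at total-variation distance
  >= 0.1 — this is what "the child actually depends on each parent" means
  operationally here;

* continuous child with discrete (or mixed) parents: a conditional-Gaussian
  regression — shared slopes on the continuous parents, a separately drawn
  intercept per discrete-parent configuration — so the child is marginally a
  Gaussian mixture.

Column order of the emitted dataset is shuffled (seeded) by default so that
learners cannot exploit the generative variable order; the permutation is
recorded and invertible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset
from .exceptions import (
    InvalidArgumentError,
    SimulationError,
    UnsupportedCombinationError,
)
from .network import (
    CONTINUOUS,
    DISCRETE,
    CgComponent,
    ConditionalGaussianCpd,
    LinearGaussianCpd,
    MultinomialCpd,
    ParameterizedNetwork,
    SeedLike,
    TypedDag,
    as_rng,
    generate_random_dag,
    generate_scale_free_dag,
    topological_order,
)

_SIGMA2_FLOOR = 1e-3
_CPT_TV_MIN = 0.1
_CPT_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """One benchmark setting: network kind, topology, sizes, and SEM knobs.

    ``beta_sd`` / ``sigma2_sd`` are standard deviations by default; set
    ``scale_as_variance=True`` to read them as variances instead.
    """

    network_kind: str = CONTINUOUS  # continuous | discrete | mixed
    topology: str = "random"  # random | scale_free
    p: int = 20
    n: int = 1000
    seed: int = 0
    mean_parents: float = 1.5
    attachment_edges: int = 1
    discrete_fraction: float = 0.5
    max_discrete_parents: int = 3
    levels_choices: tuple[int, ...] = (2, 3)
    beta_mean: float = 2.0
    beta_sd: float = 0.8
    sign_prob: float = 0.5
    sigma2_mean: float = 1.0
    sigma2_sd: float = 0.01
    scale_as_variance: bool = False
    shuffle_columns: bool = True

    def __post_init__(self) -> None:
        if self.network_kind not in (CONTINUOUS, DISCRETE, "mixed"):
            raise InvalidArgumentError(f"unknown network kind {self.network_kind!r}")
        if self.topology not in ("random", "scale_free"):
            raise InvalidArgumentError(f"unknown topology {self.topology!r}")
        if self.topology == "scale_free" and self.network_kind != CONTINUOUS:
            raise UnsupportedCombinationError(
                "scale-free topology is only supported for continuous networks"
            )
        if self.p < 1 or self.n < 1:
            raise InvalidArgumentError("p and n must be >= 1")
        if not (0.0 <= self.sign_prob <= 1.0):
            raise InvalidArgumentError("sign_prob must be in [0, 1]")
        if not (0.0 <= self.discrete_fraction <= 1.0):
            raise InvalidArgumentError("discrete_fraction must be in [0, 1]")
        if self.beta_sd <= 0 or self.sigma2_sd <= 0:
            raise InvalidArgumentError("beta_sd and sigma2_sd must be positive")

    @property
    def beta_scale(self) -> float:
        return float(np.sqrt(self.beta_sd)) if self.scale_as_variance else self.beta_sd

    @property
    def sigma2_scale(self) -> float:
        return (
            float(np.sqrt(self.sigma2_sd)) if self.scale_as_variance else self.sigma2_sd
        )


@dataclass(frozen=True)
class SimulatedInstance:
    """Ground truth + sampled data + the column shuffle that was applied."""

    truth: ParameterizedNetwork
    data: Dataset
    column_permutation: tuple[int, ...]
    config: SimulationConfig

    def unshuffled(self) -> Dataset:
        """The dataset with columns restored to the truth's variable order."""
        return self.data.select_columns(self.truth.dag.names)


# ---------------------------------------------------------------------------
# parameter drawing
# ---------------------------------------------------------------------------

def _draw_signed_magnitude(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    b = rng.normal(cfg.beta_mean, cfg.beta_scale)
    s = 1.0 if rng.random() < cfg.sign_prob else -1.0
    return s * abs(b)


def _draw_sigma2(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    for _ in range(100):
        v = rng.normal(cfg.sigma2_mean, cfg.sigma2_scale)
        if v >= _SIGMA2_FLOOR:
            return float(v)
    return _SIGMA2_FLOOR


def _tv(a: np.ndarray, b: np.ndarray) -> float:
    return 0.5 * float(np.abs(a - b).sum())


def _draw_cpt(
    child_levels: int,
    parent_levels: Sequence[int],
    rng: np.random.Generator,
) -> dict[tuple[int, ...], tuple[float, ...]]:
    """Dirichlet(1,..,1) CPT rows, rejected until neighbouring rows differ.

    Two rows are neighbours when their parent configurations differ in
    exactly one coordinate; requiring TV >= 0.1 between neighbours makes the
    child conditionally dependent on every single parent.
    """
    configs = list(itertools.product(*[range(l) for l in parent_levels]))
    for _ in range(_CPT_MAX_ATTEMPTS):
        rows = {c: rng.dirichlet(np.ones(child_levels)) for c in configs}
        ok = True
        for a, b in itertools.combinations(configs, 2):
            if sum(x != y for x, y in zip(a, b)) == 1 and _tv(rows[a], rows[b]) < _CPT_TV_MIN:
                ok = False
                break
        if ok:
            return {c: tuple(map(float, r)) for c, r in rows.items()}
    raise SimulationError(
        f"could not draw a CPT with neighbour TV >= {_CPT_TV_MIN} "
        f"in {_CPT_MAX_ATTEMPTS} attempts"
    )


def draw_parameters(
    dag: TypedDag, config: SimulationConfig, seed: SeedLike | None = None
) -> ParameterizedNetwork:
    """Attach SEM parameters to every node of ``dag`` per the scheme above."""
    rng = as_rng(config.seed if seed is None else seed)
    cpds: dict[str, object] = {}
    for spec in dag.variables:
        parents = dag.parents(spec.name)
        p_disc = tuple(q for q in parents if dag.spec(q).is_discrete)
        p_cont = tuple(q for q in parents if not dag.spec(q).is_discrete)
        if spec.is_discrete:
            if p_cont:
                raise InvalidArgumentError(
                    f"discrete child {spec.name} has continuous parents"
                )
            table = _draw_cpt(
                spec.levels, [dag.spec(q).levels for q in p_disc], rng
            )
            cpds[spec.name] = MultinomialCpd(p_disc, table)
        elif not p_disc:
            betas = {q: _draw_signed_magnitude(config, rng) for q in p_cont}
            cpds[spec.name] = LinearGaussianCpd(
                betas, intercept=0.0, sigma2=_draw_sigma2(config, rng)
            )
        else:
            shared = tuple(_draw_signed_magnitude(config, rng) for _ in p_cont)
            components = {}
            for key in itertools.product(*[range(dag.spec(q).levels) for q in p_disc]):
                components[key] = CgComponent(
                    betas=shared,
                    intercept=_draw_signed_magnitude(config, rng),
                    sigma2=_draw_sigma2(config, rng),
                )
            cpds[spec.name] = ConditionalGaussianCpd(p_disc, p_cont, components)
    return ParameterizedNetwork(dag, cpds)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_dataset(
    network: ParameterizedNetwork, n: int, seed: SeedLike = 0
) -> Dataset:
    """Ancestral sampling in topological order; returns an N x p Dataset."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = as_rng(seed)
    dag = network.dag
    values: dict[str, np.ndarray] = {}
    for name in topological_order(dag):
        spec = dag.spec(name)
        cpd = network.cpds[name]
        if spec.is_discrete:
            assert isinstance(cpd, MultinomialCpd)
            if cpd.parents:
                keys = np.stack([values[q] for q in cpd.parents], axis=1)
                out = np.empty(n, dtype=np.int64)
                u = rng.random(n)
                for cfg, row in cpd.table.items():
                    mask = np.all(keys == np.asarray(cfg), axis=1)
                    if mask.any():
                        cum = np.cumsum(row)
                        out[mask] = np.searchsorted(cum, u[mask], side="right")
                out = np.clip(out, 0, spec.levels - 1)
            else:
                row = cpd.table[()]
                cum = np.cumsum(row)
                out = np.clip(
                    np.searchsorted(cum, rng.random(n), side="right"),
                    0,
                    spec.levels - 1,
                )
            values[name] = out
        elif isinstance(cpd, LinearGaussianCpd):
            mean = np.full(n, cpd.intercept, dtype=np.float64)
            for q, b in cpd.betas.items():
                mean += b * values[q]
            values[name] = mean + rng.normal(0.0, np.sqrt(cpd.sigma2), size=n)
        else:
            assert isinstance(cpd, ConditionalGaussianCpd)
            keys = np.stack([values[q] for q in cpd.discrete_parents], axis=1)
            mean = np.zeros(n, dtype=np.float64)
            sigma = np.ones(n, dtype=np.float64)
            for cfg, comp in cpd.components.items():
                mask = np.all(keys == np.asarray(cfg), axis=1)
                if not mask.any():
                    continue
                m = np.full(mask.sum(), comp.intercept)
                for q, b in zip(cpd.continuous_parents, comp.betas):
                    m += b * values[q][mask]
                mean[mask] = m
                sigma[mask] = np.sqrt(comp.sigma2)
            values[name] = mean + sigma * rng.normal(size=n)
    frame = pd.DataFrame({name: values[name] for name in dag.names})
    return Dataset(frame, dag.variables)


def simulate(config: SimulationConfig) -> SimulatedInstance:
    """Topology -> parameters -> samples -> (optional) column shuffle."""
    ss = np.random.SeedSequence(config.seed)
    s_topo, s_par, s_samp, s_shuf = ss.spawn(4)
    if config.topology == "scale_free":
        dag = generate_scale_free_dag(config.p, config.attachment_edges, seed=s_topo)
    else:
        dag = generate_random_dag(
            config.p,
            config.mean_parents,
            types=config.network_kind,
            seed=s_topo,
            discrete_fraction=config.discrete_fraction,
            max_discrete_parents=config.max_discrete_parents,
            levels_choices=config.levels_choices,
        )
    truth = draw_parameters(dag, config, seed=s_par)
    data = sample_dataset(truth, config.n, seed=s_samp)
    if config.shuffle_columns and config.p > 1:
        perm = tuple(int(i) for i in as_rng(s_shuf).permutation(config.p))
        data = data.select_columns([dag.names[i] for i in perm])
    else:
        perm = tuple(range(config.p))
    return SimulatedInstance(truth, data, perm, config)


# ---------------------------------------------------------------------------
# benchmark grid
# ---------------------------------------------------------------------------

def derive_seed(base_seed: int, index: int) -> int:
    """Distinct, reproducible per-run seeds below 2**31."""
    return int((base_seed * 1_000_003 + 7_919 * (index + 1)) % (2**31 - 1))


def benchmark_grid(
    kinds: Sequence[str],
    topologies: Sequence[str],
    node_sizes: Sequence[int],
    sample_sizes: Sequence[int],
    replicates: int = 1,
    base_seed: int = 0,
    **overrides,
) -> list[SimulationConfig]:
    """Cross-product of valid setting combinations x replicates.

    Invalid kind x topology pairs (scale-free with non-continuous nodes) are
    skipped, so the canonical grid {continuous, discrete, mixed} x
    {random, scale_free} x {10, 20, 50} x {50, 200, 1000} yields 4 x 3 x 3 =
    36 configurations at one replicate each.  Every (combination, replicate)
    gets a distinct derived seed.
    """
    if not (kinds and topologies and node_sizes and sample_sizes):
        raise InvalidArgumentError("all grid axes must be nonempty")
    configs: list[SimulationConfig] = []
    index = 0
    for kind in kinds:
        for topo in topologies:
            if topo == "scale_free" and kind != CONTINUOUS:
                continue
            for p in node_sizes:
                for n in sample_sizes:
                    for _ in range(replicates):
                        configs.append(
                            SimulationConfig(
                                network_kind=kind,
                                topology=topo,
                                p=p,
                                n=n,
                                seed=derive_seed(base_seed, index),
                                **overrides,
                            )
                        )
                        index += 1
    return configs
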