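"""Structure-recovery metrics, paired testing, and benchmark orchestration.

A learned edge counts as a true positive only when it matches a true edge in
both endpoints *and* direction; a reversed true edge is a false positive
(and the missed true edge a false negative).  The false-positive rate is
taken over ordered non-true pairs::

    TPR  = TP / (TP + FN)           (recall of true directed edges)
    prec = TP / (TP + FP)           (true discovery rate; 0 + flag if no edges)
    FPR  = FP / (p * (p - 1) - |E_true|)

A secondary skeleton (undirected-adjacency) panel is available for
direction-agnostic comparisons.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset
from .exceptions import InvalidArgumentError
from .network import TypedDag
from .search import LearnResult, SearchConfig, hill_climb_baseline, learn
from .simulate import SimulationConfig, derive_seed, simulate


@dataclass(frozen=True)
class StructureMetrics:
    """Directed-edge confusion counts and the three recovery rates."""

    tp: int
    fp: int
    fn: int
    tpr: float
    precision: float
    fpr: float
    precision_defined: bool = True


def _names_edges(graph) -> tuple[set, set]:
    """Accept a TypedDag or any directed graph-like (e.g. nx.DiGraph).

    The learned side need not be acyclic: a learner that emits a cyclic
    tangle still gets scored edge by edge.
    """
    if isinstance(graph, TypedDag):
        return set(graph.names), set(graph.edges)
    if hasattr(graph, "nodes") and hasattr(graph, "edges"):
        return set(graph.nodes), {(u, v) for u, v in graph.edges}
    raise InvalidArgumentError(f"cannot interpret {type(graph).__name__} as a graph")


def compare_structures(truth: TypedDag, learned) -> StructureMetrics:
    """Strict-direction comparison of a learned graph against the truth."""
    truth_names, true_edges = _names_edges(truth)
    learned_names, got = _names_edges(learned)
    if truth_names != learned_names:
        raise InvalidArgumentError("truth and learned node sets differ")
    tp = len(true_edges & got)
    fp = len(got - true_edges)
    fn = len(true_edges - got)
    p = len(truth_names)
    tpr = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    defined = (tp + fp) > 0
    precision = tp / (tp + fp) if defined else 0.0
    denom = p * (p - 1) - len(true_edges)
    fpr = fp / denom if denom > 0 else 0.0
    return StructureMetrics(tp, fp, fn, tpr, precision, fpr, defined)


def compare_skeletons(truth: TypedDag, learned) -> StructureMetrics:
    """Direction-agnostic panel: edges compared as unordered adjacencies."""
    truth_names, true_edges = _names_edges(truth)
    learned_names, got = _names_edges(learned)
    if truth_names != learned_names:
        raise InvalidArgumentError("truth and learned node sets differ")
    true_adj = {frozenset(e) for e in true_edges}
    got_adj = {frozenset(e) for e in got}
    tp = len(true_adj & got_adj)
    fp = len(got_adj - true_adj)
    fn = len(true_adj - got_adj)
    p = len(truth_names)
    tpr = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    defined = (tp + fp) > 0
    precision = tp / (tp + fp) if defined else 0.0
    denom = p * (p - 1) // 2 - len(true_adj)
    fpr = fp / denom if denom > 0 else 0.0
    return StructureMetrics(tp, fp, fn, tpr, precision, fpr, defined)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    zero_variance: bool = False


def paired_t_test(metric_a: Sequence[float], metric_b: Sequence[float]) -> TTestResult:
    """Two-sided paired-sample t test on replicate-matched metric vectors."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidArgumentError("need two equal-length vectors of length >= 2")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        mean = float(np.mean(d))
        if mean == 0.0:
            return TTestResult(0.0, 1.0, True)
        return TTestResult(math.copysign(math.inf, mean), 0.0, True)
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue), False)


# ---------------------------------------------------------------------------
# benchmark orchestration
# ---------------------------------------------------------------------------

LearnerFn = Callable[[Dataset, SearchConfig], LearnResult]

DEFAULT_LEARNERS: dict[str, LearnerFn] = {
    "two_phase": learn,
    "hill_climb": hill_climb_baseline,
}

_METRICS = ("tpr", "precision", "fpr")


@dataclass(frozen=True)
class BenchmarkResult:
    """Tidy per-run records, per-setting aggregates, and the t-test matrix."""

    records: pd.DataFrame
    aggregates: pd.DataFrame
    ttests: pd.DataFrame


def _config_label(cfg: SimulationConfig) -> str:
    return f"{cfg.network_kind}-{cfg.topology}-p{cfg.p}-n{cfg.n}"


def _holm(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a p-value family."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[i]))
        adj[i] = running
    return adj


def run_benchmark(
    grid: Sequence[SimulationConfig],
    learners: Mapping[str, LearnerFn] | None = None,
    search: SearchConfig | None = None,
    replicates: int = 20,
    base_seed: int = 0,
) -> BenchmarkResult:
    """Simulate -> learn -> score every (setting, replicate, learner).

    ``grid`` holds one config per benchmark setting; each is re-seeded per
    replicate with a distinct derived seed.  A learner failure on one
    replicate is recorded as missing, not fatal.  Aggregates are medians and
    interquartile ranges per setting x learner; the paired t-test matrix
    compares every learner pair per setting and metric, with a
    Holm-adjusted column alongside the raw p-values.
    """
    learners = dict(learners) if learners is not None else dict(DEFAULT_LEARNERS)
    search = search or SearchConfig()
    rows: list[dict] = []
    idx = 0
    for ci, cfg in enumerate(grid):
        for rep in range(replicates):
            run_cfg = replace(cfg, seed=derive_seed(base_seed, idx))
            idx += 1
            inst = simulate(run_cfg)
            for name in sorted(learners):
                t0 = time.perf_counter()
                row = {
                    "config": _config_label(cfg),
                    "network_kind": cfg.network_kind,
                    "topology": cfg.topology,
                    "p": cfg.p,
                    "n": cfg.n,
                    "replicate": rep,
                    "seed": run_cfg.seed,
                    "learner": name,
                }
                try:
                    result = learners[name](inst.data, search)
                    metrics = compare_structures(inst.truth.dag, result.dag)
                    row.update(
                        tp=metrics.tp, fp=metrics.fp, fn=metrics.fn,
                        tpr=metrics.tpr, precision=metrics.precision,
                        fpr=metrics.fpr, ok=True,
                    )
                except Exception as exc:  # recorded as missing, not fatal
                    row.update(
                        tp=np.nan, fp=np.nan, fn=np.nan, tpr=np.nan,
                        precision=np.nan, fpr=np.nan, ok=False,
                        error=f"{type(exc).__name__}: {exc}",
                    )
                row["elapsed_s"] = time.perf_counter() - t0
                rows.append(row)
    records = pd.DataFrame(rows)

    agg_rows = []
    for (config, learner), grp in records.groupby(["config", "learner"], sort=True):
        entry = {"config": config, "learner": learner, "replicates": len(grp)}
        for m in _METRICS:
            vals = grp[m].dropna()
            entry[f"{m}_median"] = float(vals.median()) if len(vals) else np.nan
            entry[f"{m}_iqr"] = (
                float(vals.quantile(0.75) - vals.quantile(0.25)) if len(vals) else np.nan
            )
        entry["elapsed_median_s"] = float(grp["elapsed_s"].median())
        agg_rows.append(entry)
    aggregates = pd.DataFrame(agg_rows)

    tt_rows = []
    names = sorted(learners)
    for config, grp in records.groupby("config", sort=True):
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                va = grp[grp.learner == a].sort_values("replicate")
                vb = grp[grp.learner == b].sort_values("replicate")
                for m in _METRICS:
                    xa, xb = va[m].to_numpy(), vb[m].to_numpy()
                    keep = ~(np.isnan(xa) | np.isnan(xb))
                    if keep.sum() < 2:
                        continue
                    res = paired_t_test(xa[keep], xb[keep])
                    tt_rows.append({
                        "config": config, "metric": m,
                        "learner_a": a, "learner_b": b,
                        "t": res.t, "p": res.p,
                        "zero_variance": res.zero_variance,
                    })
    ttests = pd.DataFrame(tt_rows)
    if len(ttests):
        ttests["p_holm"] = np.nan
        for (config, m), grp in ttests.groupby(["config", "metric"]):
            ttests.loc[grp.index, "p_holm"] = _holm(grp["p"].tolist())
    return BenchmarkResult(records, aggregates, ttests)
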