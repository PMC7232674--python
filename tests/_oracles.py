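"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive (enumeration, direct formulas) and
shares no code with the package's implementation paths.
"""

import itertools
import math

import networkx as nx
import numpy as np


def all_labeled_dags(names, max_in_degree=None):
    """Every labeled DAG on ``names`` as a frozenset of edges (543 for p=4)."""
    pairs = list(itertools.permutations(names, 2))
    out = []
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if (mask >> i) & 1]
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            continue
        if max_in_degree is not None and any(
            d > max_in_degree for _, d in g.in_degree()
        ):
            continue
        out.append(frozenset(edges))
    return out


def brute_force_metrics(names, true_edges, learned_edges):
    """Classify every ordered pair independently and tally the rates."""
    tp = fp = fn = 0
    for u, v in itertools.permutations(names, 2):
        in_true = (u, v) in true_edges
        in_learned = (u, v) in learned_edges
        if in_true and in_learned:
            tp += 1
        elif in_learned:
            fp += 1
        elif in_true:
            fn += 1
    p = len(names)
    non_true = p * (p - 1) - len(true_edges)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tpr": tp / (tp + fn) if tp + fn else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "fpr": fp / non_true if non_true else 0.0,
    }


def ols_gaussian_bic(x_columns, y):
    """Closed-form OLS + Gaussian BIC, coded independently of the package.

    Returns (bic, loglik, k) under the maximized convention
    bic = loglik - (k/2) ln n with k = #slopes + intercept + variance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [np.asarray(c, float) for c in x_columns])
    beta = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = len(x_columns) + 2
    return loglik - 0.5 * k * math.log(n), loglik, k


def textbook_paired_t(a, b):
    """Paired t statistic and two-sided p from the direct formula."""
    from scipy.stats import t as t_dist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    mean = d.mean()
    sd = math.sqrt(((d - mean) ** 2).sum() / (n - 1))
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), n - 1)
    return t, p
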