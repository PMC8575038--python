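"""Independent brute-force oracles used by the test suite.

These are deliberately naive (loops, direct formulas) and share no code
with the implementation they check.
"""

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def brute_force_es(scores: pd.Series, members, exponent=1.0):
    """Weighted KS-like running-sum enrichment score, plain loop."""
    genes = list(scores.index)
    order = sorted(genes, key=lambda g: (-scores[g], g))
    member_set = set(members)
    n, m = len(genes), len(member_set)
    total = sum(abs(scores[g]) ** exponent for g in member_set)
    running, best_pos, best_neg = 0.0, 0.0, 0.0
    for g in order:
        if g in member_set:
            running += (abs(scores[g]) ** exponent) / total if total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    # positive deviation wins exact ties; tolerance absorbs float error
    return best_pos if best_pos >= -best_neg - 1e-12 else best_neg


def brute_force_silhouette(d, labels):
    labels = np.asarray(labels)
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            out[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == lab].mean() for lab in set(labels) if lab != labels[i]
        )
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out.mean()


def brute_force_nmi(a, b):
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy().astype(float)
    n = ct.sum()
    pij = ct / n
    pi, pj = pij.sum(1), pij.sum(0)
    mi = sum(
        pij[i, j] * np.log(pij[i, j] / (pi[i] * pj[j]))
        for i in range(ct.shape[0])
        for j in range(ct.shape[1])
        if pij[i, j] > 0
    )
    hi = -sum(p * np.log(p) for p in pi if p > 0)
    hj = -sum(p * np.log(p) for p in pj if p > 0)
    return 0.0 if hi == 0 or hj == 0 else mi / np.sqrt(hi * hj)


def brute_force_ari(a, b):
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2

    sum_ij = comb2(ct).sum()
    sum_i = comb2(ct.sum(1)).sum()
    sum_j = comb2(ct.sum(0)).sum()
    n = ct.sum()
    expected = sum_i * sum_j / comb2(n)
    max_index = (sum_i + sum_j) / 2
    return (sum_ij - expected) / (max_index - expected)


def brute_force_jaccard(a, b):
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    both = either = 0
    for i in range(n):
        for j in range(i + 1, n):
            ca = a[i] == a[j]
            cb = b[i] == b[j]
            both += ca and cb
            either += ca or cb
    return 1.0 if either == 0 else both / either


def brute_force_module_score(eigengenes: pd.DataFrame, labels, alpha, beta):
    """Direct module x cluster loop with a manual Spearman (ranks +
    Pearson product-moment on ranks)."""
    labels = np.asarray(labels)
    vals = []
    for col in eigengenes.columns:
        e = eigengenes[col].to_numpy()
        s_pos = s_neg = 0
        for lab in np.unique(labels):
            c = (labels == lab).astype(float)
            re, rc = rankdata(e), rankdata(c)
            re, rc = re - re.mean(), rc - rc.mean()
            rho = (re @ rc) / np.sqrt((re @ re) * (rc @ rc))
            if rho >= alpha:
                s_pos += 1
            elif rho <= -alpha:
                s_neg += 1
        total = s_pos + s_neg
        vals.append(beta if total == 0 else (min(1, s_pos) + min(1, s_neg)) / total)
    return float(np.mean(vals))


def random_connected_graph(rng, max_nodes=50, edge_prob=0.2):
    """Random undirected graph kept connected by a backbone path."""
    n = int(rng.integers(4, max_nodes + 1))
    a = np.triu((rng.random((n, n)) < edge_prob).astype(float), 1)
    a = a + a.T
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return a
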