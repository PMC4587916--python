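"""Independent brute-force reference implementations used only by the
tests.

Everything here is written as plain loops straight from the defining
formulas, deliberately sharing no code with the package, so agreement is
meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_average_ranks_desc(values: np.ndarray) -> np.ndarray:
    """Ranks of values in decreasing order, 1 = largest, ties by average."""
    n = len(values)
    ranks = np.empty(n)
    for i in range(n):
        smaller = sum(1 for j in range(n) if values[j] > values[i])
        equal = sum(1 for j in range(n) if values[j] == values[i])
        ranks[i] = smaller + (equal + 1) / 2.0
    return ranks


def naive_clr(m: np.ndarray) -> np.ndarray:
    g = m.shape[0]
    out = np.zeros((g, g))
    mu = [sum(m[i, l] for l in range(g)) / g for i in range(g)]
    sd = [
        math.sqrt(sum((m[i, l] - mu[i]) ** 2 for l in range(g)) / (g - 1))
        for i in range(g)
    ]
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            ci = max(0.0, (m[i, j] - mu[i]) / sd[i]) if sd[i] > 0 else 0.0
            cj = max(0.0, (m[j, i] - mu[j]) / sd[j]) if sd[j] > 0 else 0.0
            out[i, j] = math.sqrt(ci * ci + cj * cj)
    return out


def naive_aracne(m: np.ndarray, eps: float = 0.0) -> np.ndarray:
    g = m.shape[0]
    out = m.copy()
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            for k in range(g):
                if k in (i, j):
                    continue
                if m[i, j] < min(m[i, k], m[j, k]) - eps:
                    out[i, j] = 0.0
                    break
    np.fill_diagonal(out, 0.0)
    return out


def naive_mutrank(corr: np.ndarray) -> np.ndarray:
    g = corr.shape[0]
    r = np.zeros((g, g))
    for i in range(g):
        others = [l for l in range(g) if l != i]
        ranks = naive_average_ranks_desc(np.abs(corr[i, others]))
        for pos, l in enumerate(others):
            r[i, l] = ranks[pos]
    s = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            if i != j:
                s[i, j] = r[i, j] * r[j, i] / 2.0
    return -s


def naive_zscore(values: np.ndarray) -> np.ndarray:
    n, g = values.shape
    mu = [sum(values[k, j] for k in range(n)) / n for j in range(g)]
    sd = [
        math.sqrt(sum((values[k, j] - mu[j]) ** 2 for k in range(n)) / n)
        for j in range(g)
    ]
    rows: dict[int, list[np.ndarray]] = {}
    for k in range(n):
        i = min(range(g), key=lambda l: (values[k, l], l))
        row = np.zeros(g)
        for j in range(g):
            row[j] = abs(values[k, j] - mu[j]) / sd[j] if sd[j] > 0 else 0.0
        rows.setdefault(i, []).append(row)
    z = np.zeros((g, g))
    for i, rs in rows.items():
        z[i] = np.mean(rs, axis=0)
    np.fill_diagonal(z, 0.0)
    return z


def naive_mrnet(m: np.ndarray) -> np.ndarray:
    g = m.shape[0]
    directed = np.zeros((g, g))
    for t in range(g):
        selected: list[int] = []
        candidates = [j for j in range(g) if j != t]
        while candidates:
            best_j, best_u = None, -np.inf
            for j in candidates:
                red = (
                    sum(m[j, s] for s in selected) / len(selected)
                    if selected
                    else 0.0
                )
                u = m[j, t] - red
                if u > best_u:
                    best_j, best_u = j, u
            if best_u <= 0:
                break
            directed[best_j, t] = best_u
            selected.append(best_j)
            candidates.remove(best_j)
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            out[i, j] = max(directed[i, j], directed[j, i])
    return out


def naive_partial_corr(corr: np.ndarray, i: int, j: int, k: int) -> float:
    num = corr[i, j] - corr[i, k] * corr[j, k]
    den = math.sqrt((1 - corr[i, k] ** 2) * (1 - corr[j, k] ** 2))
    return num / den


def naive_pcit(corr: np.ndarray) -> np.ndarray:
    g = corr.shape[0]
    c = np.clip(corr, -1 + 1e-12, 1 - 1e-12)
    np.fill_diagonal(c, 1 - 1e-12)

    def ratio(i, j, k):
        if abs(c[i, j]) < 1e-300:
            return 1.0
        r = abs(naive_partial_corr(c, i, j, k)) / abs(c[i, j])
        return r if math.isfinite(r) else 1.0

    out = np.abs(corr).copy()
    for i in range(g):
        for j in range(g):
            if i == j:
                out[i, j] = 0.0
                continue
            for k in range(g):
                if k in (i, j):
                    continue
                eps = (ratio(i, j, k) + ratio(j, k, i) + ratio(i, k, j)) / 3.0
                if abs(c[i, j]) <= eps * abs(c[i, k]) and abs(c[i, j]) <= eps * abs(
                    c[j, k]
                ):
                    out[i, j] = 0.0
                    break
    return out


def naive_evaluate(
    scores: np.ndarray,
    adjacency: np.ndarray,
    top_fraction: float,
    directed: bool,
):
    """Confusion table plus the three metrics by direct enumeration."""
    g = scores.shape[0]
    pairs = []
    if directed:
        for i in range(g):
            for j in range(g):
                if i != j:
                    pairs.append((scores[i, j], (i, j), adjacency[i, j] != 0))
        possible = g * g - g
    else:
        for i in range(g):
            for j in range(i + 1, g):
                s = max(scores[i, j], scores[j, i])
                truth = adjacency[i, j] != 0 or adjacency[j, i] != 0
                pairs.append((s, (i, j), truth))
        possible = (g * g - g) // 2
    t = max(1, int(math.floor(top_fraction * possible + 0.5)))
    t = min(t, len(pairs))
    pairs.sort(key=lambda p: (-p[0], p[1]))
    n_true = sum(1 for p in pairs if p[2])
    tp = fp = 0
    precision, recall, fpr = [], [], []
    for rank in range(t):
        if pairs[rank][2]:
            tp += 1
        else:
            fp += 1
        precision.append(tp / (rank + 1))
        recall.append(tp / n_true)
        fpr.append(fp / (len(pairs) - n_true))

    def trapz(ys, xs):
        area = 0.0
        for a in range(1, len(xs)):
            area += (xs[a] - xs[a - 1]) * (ys[a] + ys[a - 1]) / 2.0
        return area

    if recall[-1] > 0:
        aupr = trapz([precision[0]] + precision, [0.0] + recall) / recall[-1]
    else:
        aupr = 0.0
    if fpr[-1] > 0:
        auroc = trapz([0.0] + recall, [0.0] + fpr) / fpr[-1]
    else:
        auroc = 1.0 if recall[-1] > 0 else 0.5
    mean_prec = sum(precision) / len(precision)
    return {
        "t": t,
        "precision": precision,
        "recall": recall,
        "aupr": aupr,
        "auroc": auroc,
        "mean_precision": mean_prec,
    }


def naive_ranksum_pvalue(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration (midranks,
    symmetric tail count)."""
    import itertools

    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(ranks[:n1])
    mu = n1 * (n + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total
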