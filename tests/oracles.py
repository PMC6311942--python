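"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, set algebra, textbook DP) and never calls the code paths it checks.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def gotoh_global_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -0.5,
    gap_extend: float = -0.1,
) -> float:
    """Exhaustive three-state affine-gap global alignment DP.

    ``gap_open`` is the score of the first residue of a gap and
    ``gap_extend`` of each further residue.  Adjacent insertion/deletion
    runs are permitted (each opens its own gap).
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends in (mis)match
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends consuming a (gap in b)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends consuming b (gap in a)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    for j in range(1, m + 1):
        X[0][j] = NEG_INF
    return max(M[n][m], X[n][m], Y[n][m])


def overlap_indices(edges: set[tuple[int, int]], n_rna: int, n_gene: int) -> dict[str, np.ndarray]:
    """CN/AA/JA/SA matrices computed from the adjacency matrix with loops."""
    adj = np.zeros((n_rna, n_gene), dtype=bool)
    for r, g in edges:
        adj[r, g] = True
    gene_deg = adj.sum(axis=0)
    out = {name: np.zeros((n_rna, n_rna)) for name in ("CN", "AA", "JA", "SA")}
    for i in range(n_rna):
        for j in range(n_rna):
            gi, gj = adj[i], adj[j]
            if not gi.any() or not gj.any():
                continue
            inter = gi & gj
            union = gi | gj
            out["CN"][i, j] = inter.sum()
            aa = 0.0
            for z in np.flatnonzero(inter):
                if gene_deg[z] > 1:
                    aa += 1.0 / np.log(gene_deg[z])
            out["AA"][i, j] = aa
            out["JA"][i, j] = inter.sum() / union.sum()
            out["SA"][i, j] = inter.sum() / np.sqrt(gi.sum() * gj.sum())
    return out


def concordance_auc(pos, neg) -> float:
    """All-pairs concordance count with half credit for ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bpr_reference_updates(U, V, b, triples, gamma, alpha_m, alpha_l, beta_l):
    """Plain pairwise Bayesian personalized ranking SGD, coded independently.

    Updates (U, V, b) in place for each (i, j, k) triple; no group
    machinery anywhere.
    """
    for i, j, k in triples:
        s = (U[i] @ V[j] + b[j]) - (U[i] @ V[k] + b[k])
        c = 1.0 / (1.0 + np.exp(s)) if s > -30 else 1.0
        gU = -c * (1.0 * V[j] - V[k]) + alpha_m * U[i]
        gVj = -c * U[i] + alpha_l * V[j]
        gVk = -c * (-U[i]) + alpha_l * V[k]
        gbj = -c * 1.0 + beta_l * b[j]
        gbk = -c * (-1.0) + beta_l * b[k]
        U[i] = U[i] - gamma * gU
        V[j] = V[j] - gamma * gVj
        V[k] = V[k] - gamma * gVk
        b[j] = b[j] - gamma * gbj
        b[k] = b[k] - gamma * gbk
    return U, V, b


def finite_difference_check(model, triple, h: float = 1e-6) -> float:
    """Worst mixed relative/absolute error of analytic vs central-FD grads.

    The scale floor of 1e-2 turns the comparison into an absolute one for
    near-zero gradient entries, where central differences bottom out around
    1e-10.
    """
    from mirlnc.model import RankingModel, triple_gradients, triple_loss

    loss, grads = triple_gradients(model, triple)

    def loss_with(field, idx, delta):
        m2 = RankingModel(model.U.copy(), model.V.copy(), model.b.copy(),
                          model.hyper, model.mirna_ids, model.lncrna_ids)
        getattr(m2, field)[idx] += delta
        return triple_loss(m2, triple)

    worst = 0.0

    def compare(analytic, field, idx):
        nonlocal worst
        num = (loss_with(field, idx, h) - loss_with(field, idx, -h)) / (2 * h)
        err = abs(num - analytic) / max(abs(num), abs(analytic), 1e-2)
        worst = max(worst, err)

    G, j, k = triple.G, triple.j, triple.k
    for pos, t in enumerate(G):
        for col in range(model.U.shape[1]):
            compare(grads["U"][pos, col], "U", (int(t), col))
    for col in range(model.V.shape[1]):
        compare(grads["Vj"][col], "V", (j, col))
        compare(grads["Vk"][col], "V", (k, col))
    compare(grads["bj"], "b", j)
    compare(grads["bk"], "b", k)
    return worst
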