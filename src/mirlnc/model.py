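"""Group-preference Bayesian pairwise ranking for bipartite link prediction.

The model scores a miRNA *i* against a lncRNA *j* with a latent-factor
form ``Score_ij = U_i . V_j + b_j`` (U: nm x d miRNA factors, V: nl x d
lncRNA factors, b: per-lncRNA bias).  Because only positive interactions
are observed, training is pairwise: an observed pair (i, j) should outrank
an unobserved pair (i, k).  On top of the individual preference, a *group
preference* is injected: a group G of miRNAs all observed with j (with the
anchor i in G) contributes the mean score

    Score_Gj = (1/|G|) sum_{t in G} Score_tj,

fused with the individual score via a tradeoff rho in [0, 1]:

    Score_Gij = rho * Score_Gj + (1 - rho) * Score_ij.

The per-triple objective is the Bayesian pairwise ranking loss

    f(G,i,j,k) = ln(1 + exp(-(Score_Gij - Score_ik)))
                 + (alpha_m/2) sum_{t in G} ||U_t||^2
                 + (alpha_l/2) ||V_j||^2 + (alpha_l/2) ||V_k||^2
                 + (beta_l/2) b_j^2 + (beta_l/2) b_k^2,

minimized by stochastic gradient descent over uniformly sampled triples
(one epoch = |observed pairs| triples).  With |G| = 1 the model reduces
exactly to standard Bayesian personalized ranking.

For final prediction the latent score of an unobserved pair is augmented
with similarity evidence pooled from training neighbors:

    Score_ij += (delta_m/|M_j|) sum_{i' in M_j} max(0, S_m(i,i'))
              + (delta_l/|L_i|) sum_{j' in L_i} max(0, S_l(j,j')),

where M_j are the observed miRNA partners of j and L_i the observed lncRNA
partners of i.  Negative similarities are clamped to zero here (and only
here): the aggregation is a nonnegative evidence-pooling step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_data import InteractionNetwork, SimilarityMatrix

logger = logging.getLogger("mirlnc")

__all__ = [
    "Hyperparams",
    "RankingModel",
    "TrainingTriple",
    "TrainingDiverged",
    "predict_score",
    "group_score",
    "fused_score",
    "triple_loss",
    "triple_gradients",
    "sgd_step",
    "sample_triple",
    "init_model",
    "train",
    "aggregate_score",
    "score_candidates",
    "rank_candidates",
    "save_model",
    "load_model",
]


class TrainingDiverged(RuntimeError):
    """Raised when parameters go non-finite during SGD."""


@dataclass(frozen=True)
class Hyperparams:
    """Training and scoring hyperparameters.

    d           latent dimension of U and V rows (default 16)
    rho         group/individual tradeoff in [0, 1] (default 0.5)
    gamma       SGD learning rate (default 0.1)
    T           number of epochs; one epoch samples |pairs| triples
                (default 500)
    alpha_m     L2 weight on group members' U rows (default 0.01)
    alpha_l     L2 weight on V_j / V_k (default 0.01)
    beta_l      L2 weight on biases b_j / b_k (default 0.01)
    delta_m     weight of pooled miRNA-side similarity evidence (default 1)
    delta_l     weight of pooled lncRNA-side similarity evidence (default 1)
    group_size  target |G| including the anchor miRNA (default 3)
    seed        RNG seed for initialization and triple sampling
    init        'random' (N(0, 0.01) entries) or 'similarity'
                (leading eigenvectors of S_m / S_l, rescaled)
    """

    d: int = 16
    rho: float = 0.5
    gamma: float = 0.1
    T: int = 500
    alpha_m: float = 0.01
    alpha_l: float = 0.01
    beta_l: float = 0.01
    delta_m: float = 1.0
    delta_l: float = 1.0
    group_size: int = 3
    seed: int = 0
    init: str = "random"
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.d < 1 or self.group_size < 1:
            raise ValueError("d and group_size must be >= 1")
        for name in ("alpha_m", "alpha_l", "beta_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.init not in ("random", "similarity"):
            raise ValueError("init must be 'random' or 'similarity'")


@dataclass
class RankingModel:
    """Trained latent factors plus the hyperparameters that produced them."""

    U: np.ndarray  # (nm, d)
    V: np.ndarray  # (nl, d)
    b: np.ndarray  # (nl,)
    hyper: Hyperparams
    mirna_ids: list[str]
    lncrna_ids: list[str]
    epoch_losses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        nm, nl = len(self.mirna_ids), len(self.lncrna_ids)
        d = self.hyper.d
        if self.U.shape != (nm, d) or self.V.shape != (nl, d) or self.b.shape != (nl,):
            raise ValueError("parameter shapes inconsistent with network and d")

    def check_finite(self, epoch: int | None = None) -> None:
        if not (np.isfinite(self.U).all() and np.isfinite(self.V).all() and np.isfinite(self.b).all()):
            where = f" at epoch {epoch}" if epoch is not None else ""
            raise TrainingDiverged(f"non-finite parameters{where}")


@dataclass(frozen=True)
class TrainingTriple:
    """One SGD sample: anchor i, positive j, negative k, miRNA group G.

    Contract: (i, j) observed, (i, k) unobserved, i in G, and every member
    of G observed with j.
    """

    i: int
    j: int
    k: int
    G: np.ndarray  # member indices; position of i recorded for gradient shortcut

    def __post_init__(self) -> None:
        if self.i not in self.G:
            raise ValueError("anchor miRNA must belong to its group")


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------


def predict_score(model: RankingModel, i: int, j: int) -> float:
    """Latent score ``U_i . V_j + b_j``."""
    if not (0 <= i < model.U.shape[0] and 0 <= j < model.V.shape[0]):
        raise IndexError(f"index out of range: ({i}, {j})")
    return float(model.U[i] @ model.V[j] + model.b[j])


def group_score(model: RankingModel, G: np.ndarray, j: int) -> float:
    """Mean latent score of the group members on lncRNA j."""
    G = np.asarray(G, dtype=np.intp)
    if G.size == 0:
        raise ValueError("empty group")
    return float(model.U[G].mean(axis=0) @ model.V[j] + model.b[j])


def fused_score(model: RankingModel, G: np.ndarray, i: int, j: int) -> float:
    """rho-weighted fusion of group and individual preference on j."""
    rho = model.hyper.rho
    return rho * group_score(model, G, j) + (1.0 - rho) * predict_score(model, i, j)


# ---------------------------------------------------------------------------
# loss and gradients
# ---------------------------------------------------------------------------


def triple_loss(model: RankingModel, triple: TrainingTriple) -> float:
    """Pairwise ranking loss of one triple, including L2 regularization."""
    h = model.hyper
    s = fused_score(model, triple.G, triple.i, triple.j) - predict_score(model, triple.i, triple.k)
    loss = float(np.logaddexp(0.0, -s))
    loss += 0.5 * h.alpha_m * float((model.U[triple.G] ** 2).sum())
    loss += 0.5 * h.alpha_l * float((model.V[triple.j] ** 2).sum())
    loss += 0.5 * h.alpha_l * float((model.V[triple.k] ** 2).sum())
    loss += 0.5 * h.beta_l * float(model.b[triple.j] ** 2)
    loss += 0.5 * h.beta_l * float(model.b[triple.k] ** 2)
    return loss


def triple_gradients(
    model: RankingModel, triple: TrainingTriple
) -> tuple[float, dict[str, np.ndarray | float]]:
    """Analytic gradients of the per-triple loss.

    Returns ``(loss, grads)`` with grads keyed ``U`` (|G| x d, rows aligned
    with triple.G), ``Vj``, ``Vk``, ``bj``, ``bk``.  The margin is
    ``s = Score_Gij - Score_ik`` and the loss term's gradient carries the
    coefficient ``-sigma(-s)``.
    """
    h = model.hyper
    U, V, b = model.U, model.V, model.b
    G, i, j, k = triple.G, triple.i, triple.j, triple.k
    g = G.size
    pos_i = int(np.flatnonzero(G == i)[0])
    rho = h.rho

    # overflow to inf is tolerated here; divergence is caught by the
    # finite checks in sgd_step/train
    with np.errstate(over="ignore"):
        mean_u = U[G].mean(axis=0)
        score_gj = float(mean_u @ V[j] + b[j])
        score_ij = float(U[i] @ V[j] + b[j])
        score_ik = float(U[i] @ V[k] + b[k])
        s = rho * score_gj + (1.0 - rho) * score_ij - score_ik
        loss = float(np.logaddexp(0.0, -s))
        loss += 0.5 * h.alpha_m * float((U[G] ** 2).sum())
        loss += 0.5 * h.alpha_l * float((V[j] ** 2).sum() + (V[k] ** 2).sum())
        loss += 0.5 * h.beta_l * float(b[j] ** 2 + b[k] ** 2)

        # c = -d loss_term / d s = sigma(-s)
        c = 1.0 / (1.0 + np.exp(s)) if s > -30 else 1.0

    # ds/dU_t = (rho/g) V_j for t in G, plus ((1-rho) V_j - V_k) for the anchor.
    # The anchor's V_j coefficient is folded into one scalar so that at
    # |G| = 1 the arithmetic matches plain pairwise BPR bitwise.
    coefs = np.full(g, rho / g)
    coefs[pos_i] += 1.0 - rho
    dU = coefs[:, None] * V[j][None, :]
    dU[pos_i] -= V[k]
    gU = -c * dU + h.alpha_m * U[G]

    dVj = rho * mean_u + (1.0 - rho) * U[i]
    gVj = -c * dVj + h.alpha_l * V[j]
    gVk = -c * (-U[i]) + h.alpha_l * V[k]
    gbj = -c * 1.0 + h.beta_l * b[j]
    gbk = -c * (-1.0) + h.beta_l * b[k]
    grads = {"U": gU, "Vj": gVj, "Vk": gVk, "bj": float(gbj), "bk": float(gbk)}
    return loss, grads


def sgd_step(model: RankingModel, triple: TrainingTriple) -> RankingModel:
    """One in-place SGD update ``theta <- theta - gamma * grad``; returns model."""
    loss, grads = triple_gradients(model, triple)
    if not np.isfinite(loss):
        raise TrainingDiverged("non-finite loss in SGD step")
    gamma = model.hyper.gamma
    G, j, k = triple.G, triple.j, triple.k
    model.U[G] = model.U[G] - gamma * grads["U"]
    model.V[j] = model.V[j] - gamma * grads["Vj"]
    model.V[k] = model.V[k] - gamma * grads["Vk"]
    model.b[j] = model.b[j] - gamma * grads["bj"]
    model.b[k] = model.b[k] - gamma * grads["bk"]
    return model


# ---------------------------------------------------------------------------
# triple sampling
# ---------------------------------------------------------------------------


def _partner_arrays(net: InteractionNetwork) -> tuple[list[np.ndarray], list[np.ndarray], list[set[int]]]:
    lnc_partners = net.lnc_partners()
    mir_partners = net.mir_partners()
    lnc_sets = [set(a.tolist()) for a in lnc_partners]
    return lnc_partners, mir_partners, lnc_sets


def sample_triple(
    net: InteractionNetwork,
    rng: np.random.Generator,
    group_size: int = 3,
    _cache: tuple | None = None,
) -> TrainingTriple:
    """Draw one uniform training triple.

    i is drawn uniformly from miRNAs with at least one observed and one
    unobserved lncRNA, j uniformly from L_i, k uniformly from the
    complement of L_i, and G = {i} plus a uniform sample without
    replacement of min(group_size-1, |M_j|-1) other observed partners of j.
    miRNAs with a full row (no unobserved candidate) are never eligible.
    """
    if _cache is None:
        lnc_partners, mir_partners, lnc_sets = _partner_arrays(net)
        eligible = np.array(
            [i for i in range(net.nm) if 0 < lnc_partners[i].size < net.nl],
            dtype=np.intp,
        )
    else:
        lnc_partners, mir_partners, lnc_sets, eligible = _cache
    if eligible.size == 0:
        raise ValueError("no miRNA has both an observed and an unobserved lncRNA")
    nl = net.nl
    i = int(eligible[rng.integers(eligible.size)])
    li = lnc_partners[i]
    j = int(li[rng.integers(li.size)])
    li_set = lnc_sets[i]
    while True:
        k = int(rng.integers(nl))
        if k not in li_set:
            break
    mj = mir_partners[j]
    n_extra = min(group_size - 1, mj.size - 1)
    if n_extra > 0:
        others = mj[mj != i]
        extra = rng.choice(others, size=n_extra, replace=False)
        G = np.concatenate(([i], np.asarray(extra, dtype=np.intp)))
    else:
        G = np.array([i], dtype=np.intp)
    return TrainingTriple(i=i, j=j, k=k, G=G)


# ---------------------------------------------------------------------------
# initialization and training
# ---------------------------------------------------------------------------


def _similarity_init(sim: SimilarityMatrix | None, n: int, d: int, scale: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Top-d eigenvector init from a similarity matrix, rescaled to `scale`."""
    mat = rng.normal(0.0, scale, size=(n, d))
    if sim is None:
        return mat
    vals, vecs = np.linalg.eigh(sim.values)
    order = np.argsort(vals)[::-1][:d]
    basis = vecs[:, order]
    rms = np.sqrt((basis**2).mean())
    if rms > 0:
        mat = basis * (scale / rms)
    return mat


def init_model(
    net: InteractionNetwork,
    hyper: Hyperparams,
    S_m: SimilarityMatrix | None = None,
    S_l: SimilarityMatrix | None = None,
) -> RankingModel:
    """Initialize U, V, b from the seeded RNG (or similarity eigenvectors)."""
    rng = np.random.default_rng(hyper.seed)
    if hyper.init == "similarity":
        U = _similarity_init(S_m, net.nm, hyper.d, hyper.init_scale, rng)
        V = _similarity_init(S_l, net.nl, hyper.d, hyper.init_scale, rng)
    else:
        U = rng.normal(0.0, hyper.init_scale, size=(net.nm, hyper.d))
        V = rng.normal(0.0, hyper.init_scale, size=(net.nl, hyper.d))
    b = np.zeros(net.nl)
    return RankingModel(U, V, b, hyper, list(net.mirna_ids), list(net.lncrna_ids))


def train(
    net: InteractionNetwork,
    S_m: SimilarityMatrix | None = None,
    S_l: SimilarityMatrix | None = None,
    hyper: Hyperparams | None = None,
) -> RankingModel:
    """Fit the model by SGD over sampled triples.

    Runs ``hyper.T`` epochs of ``|pairs|`` triples each and records the
    mean per-triple loss per epoch in ``model.epoch_losses``.  Entirely
    deterministic given ``hyper.seed``.
    """
    hyper = hyper or Hyperparams()
    if not net.pairs:
        raise ValueError("cannot train on an empty network")
    model = init_model(net, hyper, S_m, S_l)
    rng = np.random.default_rng(np.random.SeedSequence([hyper.seed, 1]))
    lnc_partners, mir_partners, lnc_sets = _partner_arrays(net)
    eligible = np.array(
        [i for i in range(net.nm) if 0 < lnc_partners[i].size < net.nl], dtype=np.intp
    )
    if eligible.size < net.nm:
        logger.warning(
            "%d miRNA(s) have no unobserved lncRNA or no observed partner; skipped in sampling",
            net.nm - eligible.size,
        )
    cache = (lnc_partners, mir_partners, lnc_sets, eligible)
    n_steps = net.n_pairs
    for epoch in range(1, hyper.T + 1):
        total = 0.0
        for _ in range(n_steps):
            triple = sample_triple(net, rng, hyper.group_size, _cache=cache)
            loss, grads = triple_gradients(model, triple)
            total += loss
            gamma = hyper.gamma
            G, j, k = triple.G, triple.j, triple.k
            model.U[G] = model.U[G] - gamma * grads["U"]
            model.V[j] = model.V[j] - gamma * grads["Vj"]
            model.V[k] = model.V[k] - gamma * grads["Vk"]
            model.b[j] = model.b[j] - gamma * grads["bj"]
            model.b[k] = model.b[k] - gamma * grads["bk"]
        mean_loss = total / n_steps
        if not np.isfinite(mean_loss):
            raise TrainingDiverged(f"training diverged at epoch {epoch}")
        model.epoch_losses.append(mean_loss)
    model.check_finite()
    return model


# ---------------------------------------------------------------------------
# similarity-aggregated prediction
# ---------------------------------------------------------------------------


def _pooled_similarity(sim: SimilarityMatrix | None, query: int, neighbors: np.ndarray) -> float:
    """Mean of max(0, sim(query, n')) over training neighbors; 0 if no data."""
    if sim is None or neighbors.size == 0:
        return 0.0
    if not sim.valid[query]:
        return 0.0
    row = sim.values[query, neighbors]
    return float(np.clip(row, 0.0, None).mean())


def aggregate_score(
    model: RankingModel,
    net: InteractionNetwork,
    S_m: SimilarityMatrix | None,
    S_l: SimilarityMatrix | None,
    i: int,
    j: int,
    hyper: Hyperparams | None = None,
) -> float:
    """Final prediction score of the unobserved pair (i, j).

    Latent score plus delta-weighted mean positive similarity of i to the
    observed miRNA partners of j (under S_m) and of j to the observed
    lncRNA partners of i (under S_l).  Invalid similarity rows and empty
    neighbor sets contribute 0.
    """
    hyper = hyper or model.hyper
    score = predict_score(model, i, j)
    mj = np.array(sorted({ii for ii, jj in net.pairs if jj == j}), dtype=np.intp)
    li = np.array(sorted({jj for ii, jj in net.pairs if ii == i}), dtype=np.intp)
    score += hyper.delta_m * _pooled_similarity(S_m, i, mj)
    score += hyper.delta_l * _pooled_similarity(S_l, j, li)
    return score


def score_candidates(
    model: RankingModel,
    net: InteractionNetwork,
    S_m: SimilarityMatrix | None,
    S_l: SimilarityMatrix | None,
    i: int,
    mir_partners: list[np.ndarray] | None = None,
    lnc_partners: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Aggregate scores of miRNA i against every lncRNA (vectorized).

    Observed pairs receive scores too; callers decide what to exclude.
    """
    hyper = model.hyper
    if mir_partners is None:
        mir_partners = net.mir_partners()
    if lnc_partners is None:
        lnc_partners = net.lnc_partners()
    scores = model.V @ model.U[i] + model.b
    li = lnc_partners[i]
    if S_l is not None and li.size > 0:
        block = np.clip(S_l.values[:, li], 0.0, None)
        scores = scores + hyper.delta_l * block.mean(axis=1)
    if S_m is not None and S_m.valid[i]:
        row = np.clip(S_m.values[i], 0.0, None)
        add = np.zeros(net.nl)
        for j in range(net.nl):
            mj = mir_partners[j]
            if mj.size:
                add[j] = row[mj].mean()
        scores = scores + hyper.delta_m * add
    return scores


def rank_candidates(
    model: RankingModel,
    net: InteractionNetwork,
    S_m: SimilarityMatrix | None,
    S_l: SimilarityMatrix | None,
    query_mirna: str,
    k: int = 50,
) -> list[tuple[str, float]]:
    """Top-k unobserved lncRNA candidates for one miRNA, best first.

    Observed partners are excluded; ties break lexicographically on
    candidate id.
    """
    try:
        i = net.mirna_index()[query_mirna]
    except KeyError:
        raise KeyError(f"unknown miRNA id {query_mirna!r}") from None
    observed = {jj for ii, jj in net.pairs if ii == i}
    if len(observed) == net.nl:
        raise ValueError(f"{query_mirna} has no unobserved candidate lncRNA")
    scores = score_candidates(model, net, S_m, S_l, i)
    cands = [
        (net.lncrna_ids[j], float(scores[j])) for j in range(net.nl) if j not in observed
    ]
    cands.sort(key=lambda cs: (-cs[1], cs[0]))
    return cands[:k]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: RankingModel, path: str | Path) -> None:
    """Persist U, V, b, hyperparameters and id lists to one .npz file."""
    meta = {
        "hyper": {k: getattr(model.hyper, k) for k in Hyperparams.__dataclass_fields__},
        "mirna_ids": model.mirna_ids,
        "lncrna_ids": model.lncrna_ids,
        "epoch_losses": model.epoch_losses,
    }
    np.savez(path, U=model.U, V=model.V, b=model.b, meta=json.dumps(meta))


def load_model(path: str | Path) -> RankingModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = RankingModel(
            U=data["U"],
            V=data["V"],
            b=data["b"],
            hyper=Hyperparams(**meta["hyper"]),
            mirna_ids=meta["mirna_ids"],
            lncrna_ids=meta["lncrna_ids"],
            epoch_losses=list(meta["epoch_losses"]),
        )
    return model
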