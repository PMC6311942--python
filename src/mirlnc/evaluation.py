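"""Cross-validation protocols, local AUC, and cluster correlation analysis.

Evaluation follows a *local* scoring scheme: candidate lncRNAs are ranked
separately within each miRNA's own candidate set rather than pooling all
pairs globally, which removes the preference bias induced by the very
uneven miRNA degrees.  The per-miRNA AUC is the rank-based (Mann-Whitney)
concordance between held-out positives and unobserved candidates, with
half credit for ties; fold AUCs are macro-averages over miRNAs.

The cluster analysis compares, for each anchor RNA, the mean pairwise
similarity within its observed partner cluster against the mean pairwise
similarity within the non-partner (unobserved) group, the latter serving
as the baseline.  An anchor is "remarkable" when the two means differ by
more than 0.3 observed-group standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .io_data import InteractionNetwork, SimilarityMatrix
from .model import Hyperparams, score_candidates, train

logger = logging.getLogger("mirlnc")

__all__ = [
    "CVResult",
    "ClusterRecord",
    "ClusterAnalysisResult",
    "local_auc",
    "kfold_cv",
    "loocv",
    "cluster_pcc_analysis",
    "model_predictor",
]

# A predictor is fit(train_net, seed) -> score(i) -> np.ndarray over all lncRNAs.
Predictor = Callable[[InteractionNetwork, int], Callable[[int], np.ndarray]]


@dataclass
class CVResult:
    scheme: str  # 'LOOCV' or 'k-fold'
    k: int | None
    repeats: int
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    seed: int
    approximate: bool = False

    def summary(self) -> str:
        label = self.scheme if not self.approximate else f"{self.scheme} (fold-approximate)"
        return f"{label}: AUC {self.mean_auc:.4f} +/- {self.sd_auc:.4f} over {len(self.fold_aucs)} fold(s)"


def local_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Rank-based AUC: (#concordant + 0.5 #ties) / (|pos| * |neg|)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("local AUC needs nonempty positive and negative score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    return float((rank_sum - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


def model_predictor(
    S_m: SimilarityMatrix | None,
    S_l: SimilarityMatrix | None,
    hyper: Hyperparams,
) -> Predictor:
    """Default predictor: train the ranking model on the fold's training
    network and score candidates with similarity aggregation."""

    def fit(train_net: InteractionNetwork, seed: int) -> Callable[[int], np.ndarray]:
        model = train(train_net, S_m, S_l, replace(hyper, seed=seed))
        mir_partners = train_net.mir_partners()
        lnc_partners = train_net.lnc_partners()

        def score(i: int) -> np.ndarray:
            return score_candidates(
                model, train_net, S_m, S_l, i,
                mir_partners=mir_partners, lnc_partners=lnc_partners,
            )

        return score

    return fit


def _fold_auc(
    net: InteractionNetwork,
    train_pairs: set[tuple[int, int]],
    test_pairs: set[tuple[int, int]],
    score_of: Callable[[int], np.ndarray],
) -> float | None:
    """Macro-averaged per-miRNA local AUC for one fold.

    Negatives for a miRNA are the lncRNAs never observed with it anywhere
    in the full network: positives held out in *other* folds are known
    positives, not negatives.
    """
    observed_full: dict[int, set[int]] = {}
    for i, j in net.pairs:
        observed_full.setdefault(i, set()).add(j)
    test_by_mirna: dict[int, list[int]] = {}
    for i, j in test_pairs:
        test_by_mirna.setdefault(i, []).append(j)
    aucs = []
    for i, pos_js in test_by_mirna.items():
        neg_js = [j for j in range(net.nl) if j not in observed_full[i]]
        if not neg_js:
            logger.warning("miRNA index %d has no unobserved candidate; skipped", i)
            continue
        scores = score_of(i)
        aucs.append(local_auc(scores[pos_js], scores[neg_js]))
    if not aucs:
        return None
    return float(np.mean(aucs))


def _subnet(net: InteractionNetwork, pairs: set[tuple[int, int]]) -> InteractionNetwork:
    return InteractionNetwork(list(net.mirna_ids), list(net.lncrna_ids), set(pairs))


def kfold_cv(
    net: InteractionNetwork,
    S_m: SimilarityMatrix | None = None,
    S_l: SimilarityMatrix | None = None,
    hyper: Hyperparams | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    predictor: Predictor | None = None,
) -> CVResult:
    """k-fold cross-validation over observed pairs with local AUC.

    Observed pairs are partitioned uniformly at random into k folds; each
    fold's pairs are withheld, the predictor is fit on the remainder, every
    test pair is ranked against its miRNA's unobserved candidates, and the
    per-miRNA AUCs are macro-averaged.  Mean and SD are taken over all
    k x repeats fold AUCs.
    """
    hyper = hyper or Hyperparams()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > net.n_pairs:
        raise ValueError(f"k={k} exceeds the number of observed pairs ({net.n_pairs})")
    if predictor is None:
        predictor = model_predictor(S_m, S_l, hyper)
    all_pairs = sorted(net.pairs)
    fold_aucs: list[float] = []
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        perm = rng.permutation(len(all_pairs))
        folds = np.array_split(perm, k)
        for f, idx in enumerate(folds):
            test_pairs = {all_pairs[t] for t in idx.tolist()}
            train_pairs = set(all_pairs) - test_pairs
            fit_seed = int(rng.integers(2**31 - 1))
            score_of = predictor(_subnet(net, train_pairs), fit_seed)
            auc = _fold_auc(net, train_pairs, test_pairs, score_of)
            if auc is None:
                logger.warning("fold %d of repeat %d produced no evaluable miRNA", f, r)
                continue
            fold_aucs.append(auc)
    mean = float(np.mean(fold_aucs))
    sd = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    return CVResult("k-fold", k, repeats, fold_aucs, mean, sd, seed)


def loocv(
    net: InteractionNetwork,
    S_m: SimilarityMatrix | None = None,
    S_l: SimilarityMatrix | None = None,
    hyper: Hyperparams | None = None,
    mode: str = "fold-approximate",
    seed: int = 0,
    predictor: Predictor | None = None,
    n_retrains: int = 20,
    exact_cap: int = 400,
) -> CVResult:
    """Leave-one-out cross-validation over observed pairs.

    ``exact`` retrains once per held-out pair (refused above ``exact_cap``
    pairs; use fold-approximate instead).  ``fold-approximate`` groups the
    singleton tests into ``n_retrains`` retrains; each held-out pair is
    still scored individually against its miRNA's unobserved candidates,
    and the result is labelled an approximation.
    """
    hyper = hyper or Hyperparams()
    if mode not in ("exact", "fold-approximate"):
        raise ValueError("mode must be 'exact' or 'fold-approximate'")
    if predictor is None:
        predictor = model_predictor(S_m, S_l, hyper)
    all_pairs = sorted(net.pairs)
    if mode == "exact" and len(all_pairs) > exact_cap:
        raise ValueError(
            f"exact LOOCV over {len(all_pairs)} pairs exceeds the cap of {exact_cap}; "
            "use mode='fold-approximate' or raise exact_cap"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    if mode == "exact":
        groups = [[p] for p in all_pairs]
    else:
        perm = rng.permutation(len(all_pairs))
        groups = [
            [all_pairs[t] for t in idx.tolist()]
            for idx in np.array_split(perm, min(n_retrains, len(all_pairs)))
        ]
    observed_full: dict[int, set[int]] = {}
    for i, j in net.pairs:
        observed_full.setdefault(i, set()).add(j)
    aucs: list[float] = []
    for group in groups:
        if not group:
            continue
        train_pairs = set(all_pairs) - set(group)
        fit_seed = int(rng.integers(2**31 - 1))
        score_of = predictor(_subnet(net, train_pairs), fit_seed)
        score_cache: dict[int, np.ndarray] = {}
        for i, j in group:
            neg_js = [jj for jj in range(net.nl) if jj not in observed_full[i]]
            if not neg_js:
                logger.warning("miRNA index %d has no unobserved candidate; skipped", i)
                continue
            if i not in score_cache:
                score_cache[i] = score_of(i)
            scores = score_cache[i]
            aucs.append(local_auc([scores[j]], scores[neg_js]))
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    return CVResult("LOOCV", None, 1, aucs, mean, sd, seed,
                    approximate=(mode == "fold-approximate"))


# ---------------------------------------------------------------------------
# observed-vs-unobserved cluster similarity analysis
# ---------------------------------------------------------------------------


@dataclass
class ClusterRecord:
    anchor_id: str
    degree: int
    observed_mean: float
    baseline_mean: float
    observed_sd: float
    remarkable: bool


@dataclass
class ClusterAnalysisResult:
    side: str
    min_degree: int
    records: list[ClusterRecord]
    n_anchors: int
    n_invalid: int
    frac_invalid: float
    frac_higher: float
    remarkable_threshold: float = 0.3

    def summary(self) -> str:
        return (
            f"{self.side} clusters: {self.n_anchors} anchors, "
            f"{100 * self.frac_invalid:.1f}% invalid, "
            f"{100 * self.frac_higher:.2f}% higher than baseline"
        )


def _group_pairwise(values: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Off-diagonal pairwise similarity values within a member set."""
    sub = values[np.ix_(members, members)]
    iu = np.triu_indices(members.size, k=1)
    return sub[iu]


def cluster_pcc_analysis(
    net: InteractionNetwork,
    similarity: SimilarityMatrix,
    side: str = "mirna",
    min_degree: int = 2,
    remarkable_threshold: float = 0.3,
) -> ClusterAnalysisResult:
    """Compare observed-partner clusters with the unobserved baseline.

    ``side='mirna'`` analyzes, for each lncRNA anchor, the cluster of
    miRNAs observed to interact with it under a miRNA-miRNA similarity;
    ``side='lncrna'`` is the transpose.  Anchors need at least
    ``min_degree`` partners.  The baseline for an anchor is the mean
    pairwise similarity within its unobserved (non-partner) group.
    Anchors with fewer than 2 valid members in either group are counted
    invalid and excluded from the summary fractions.
    """
    if side not in ("mirna", "lncrna"):
        raise ValueError("side must be 'mirna' or 'lncrna'")
    if min_degree < 2:
        raise ValueError("min_degree must be >= 2")
    if side == "mirna":
        anchors = range(net.nl)
        anchor_ids = net.lncrna_ids
        partner_lists = net.mir_partners()
        n_members = net.nm
    else:
        anchors = range(net.nm)
        anchor_ids = net.mirna_ids
        partner_lists = net.lnc_partners()
        n_members = net.nl
    if len(similarity.rna_ids) != n_members:
        raise ValueError("similarity matrix does not match the chosen side")
    valid = similarity.valid
    records: list[ClusterRecord] = []
    n_invalid = 0
    n_qualifying = 0
    for a in anchors:
        partners = partner_lists[a]
        if partners.size < min_degree:
            continue
        n_qualifying += 1
        obs = partners[valid[partners]]
        non = np.setdiff1d(np.flatnonzero(valid), partners, assume_unique=False)
        if obs.size < 2 or non.size < 2:
            n_invalid += 1
            continue
        obs_vals = _group_pairwise(similarity.values, obs)
        non_vals = _group_pairwise(similarity.values, non)
        obs_mean = float(obs_vals.mean())
        base_mean = float(non_vals.mean())
        obs_sd = float(obs_vals.std())
        remarkable = abs(obs_mean - base_mean) > remarkable_threshold * obs_sd
        records.append(
            ClusterRecord(anchor_ids[a], int(partners.size), obs_mean, base_mean, obs_sd, remarkable)
        )
    if n_qualifying == 0:
        logger.warning("no anchor meets min_degree=%d", min_degree)
    n_valid = len(records)
    frac_invalid = n_invalid / n_qualifying if n_qualifying else 0.0
    frac_higher = (
        sum(r.observed_mean > r.baseline_mean for r in records) / n_valid if n_valid else 0.0
    )
    return ClusterAnalysisResult(
        side=side,
        min_degree=min_degree,
        records=records,
        n_anchors=n_qualifying,
        n_invalid=n_invalid,
        frac_invalid=frac_invalid,
        frac_higher=frac_higher,
        remarkable_threshold=remarkable_threshold,
    )


def write_cv_report(result: CVResult, path, comment: str | None = None) -> None:
    """Per-fold AUCs plus a summary row, as tab-delimited text."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# {result.summary()}\n")
        fh.write("fold\tauc\n")
        for f, auc in enumerate(result.fold_aucs):
            fh.write(f"{f}\t{auc:.6f}\n")
        fh.write(f"mean\t{result.mean_auc:.6f}\n")
        fh.write(f"sd\t{result.sd_auc:.6f}\n")


def write_cluster_report(result: ClusterAnalysisResult, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# {result.summary()}\n")
        fh.write("anchor_id\tdegree\tobserved_mean\tbaseline_mean\tobserved_sd\tremarkable\n")
        for r in result.records:
            fh.write(
                f"{r.anchor_id}\t{r.degree}\t{r.observed_mean:.6f}\t{r.baseline_mean:.6f}"
                f"\t{r.observed_sd:.6f}\t{int(r.remarkable)}\n"
            )
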