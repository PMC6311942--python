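"""The three RNA-RNA similarity families fused by the ranking model.

Three independent data channels yield a symmetric similarity matrix over
one RNA class (miRNAs or lncRNAs):

* **expression** — Pearson correlation of expression profiles across N
  tissue/cell-line attributes; values in [-1, 1].
* **sequence** — Needleman-Wunsch global alignment score under affine-gap
  scoring, normalized to [0, 1] by dividing by the best achievable score
  ``match_score * min(len_i, len_j)`` (so self-similarity is exactly 1).
* **function** — neighbor-overlap indices on the RNA-to-target-gene
  bipartite graph: Common Neighbors (CN), Adamic-Adar (AA), Jaccard (JA)
  and Salton cosine (SA).

The default pairing used downstream is function-based (AA) similarity for
miRNAs and expression-profile similarity for lncRNAs; when function-based
similarity is requested for lncRNAs the Salton index is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .io_data import (
    ExpressionProfileSet,
    InteractionNetwork,
    SequenceSet,
    SimilarityMatrix,
    TargetGeneNetwork,
)

__all__ = [
    "AlignmentParams",
    "SimilaritySources",
    "expression_similarity",
    "sequence_similarity",
    "function_similarity",
    "select_similarity",
    "FUNCTION_INDICES",
]

FUNCTION_INDICES = ("CN", "AA", "JA", "SA")


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap nucleotide alignment scoring.

    Defaults: match +2, gap-open -0.5, gap-extend -0.1 (the open score is
    the score of the first gap position).  The mismatch score is not pinned
    by the similarity definition and defaults to -1.
    """

    match_score: float = 2.0
    mismatch_score: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.1

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")


@dataclass
class SimilaritySources:
    """Optional raw inputs for one RNA class."""

    expression: ExpressionProfileSet | None = None
    sequence: SequenceSet | None = None
    targets: TargetGeneNetwork | None = None


# ---------------------------------------------------------------------------
# expression-profile similarity (Pearson)
# ---------------------------------------------------------------------------


def expression_similarity(profiles: ExpressionProfileSet) -> SimilarityMatrix:
    """Pearson correlation matrix of expression profiles.

    ES(i,j) = sum_k (e_ik - mean_i)(e_jk - mean_j) / sqrt(sum (e_ik-mean_i)^2
    sum (e_jk-mean_j)^2).  RNAs without a profile, or with a zero-variance
    profile, get all-zero rows flagged invalid; the diagonal is 1 for valid
    RNAs.
    """
    if profiles.n_attributes < 2:
        raise ValueError("Pearson correlation undefined for N < 2 attributes")
    usable = profiles.usable()
    if usable.sum() < 2:
        raise ValueError("need at least 2 usable expression profiles")
    n = len(profiles.rna_ids)
    values = np.zeros((n, n))
    x = profiles.profiles[usable]
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    corr = (centered @ centered.T) / np.outer(norms, norms)
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    idx = np.flatnonzero(usable)
    values[np.ix_(idx, idx)] = corr
    return SimilarityMatrix(list(profiles.rna_ids), values, usable.copy(), "expression")


# ---------------------------------------------------------------------------
# sequence similarity (global affine-gap alignment)
# ---------------------------------------------------------------------------


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def alignment_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global alignment score of two nucleotide sequences."""
    params = params or AlignmentParams()
    return float(_make_aligner(params).score(a, b))


def sequence_similarity(
    seqs: SequenceSet, params: AlignmentParams | None = None
) -> SimilarityMatrix:
    """Normalized global-alignment similarity in [0, 1].

    The raw optimum under affine-gap scoring is clipped at 0 and divided by
    ``match_score * min(len_i, len_j)``, the score of a perfect alignment of
    the shorter sequence, so identical sequences score exactly 1.
    """
    params = params or AlignmentParams()
    if len(seqs.rna_ids) < 2:
        raise ValueError("need at least 2 sequences")
    aligner = _make_aligner(params)
    n = len(seqs.rna_ids)
    values = np.ones((n, n))
    denom_unit = params.match_score
    for i in range(n):
        for j in range(i + 1, n):
            raw = float(aligner.score(seqs.sequences[i], seqs.sequences[j]))
            cap = denom_unit * min(len(seqs.sequences[i]), len(seqs.sequences[j]))
            val = min(max(raw, 0.0) / cap, 1.0)
            values[i, j] = values[j, i] = val
    return SimilarityMatrix(
        list(seqs.rna_ids), values, np.ones(n, dtype=bool), "sequence"
    )


# ---------------------------------------------------------------------------
# function similarity (target-gene neighbor overlap)
# ---------------------------------------------------------------------------


def function_similarity(tg: TargetGeneNetwork, index: str = "AA") -> SimilarityMatrix:
    """Neighbor-overlap similarity on the RNA-target-gene graph.

    With Γ_i the target-gene set of RNA i and |Γ_z| the RNA-degree of
    gene z:

    * ``CN(i,j) = |Γ_i ∩ Γ_j|``
    * ``AA(i,j) = Σ_{z ∈ Γ_i ∩ Γ_j} 1/ln|Γ_z|`` (genes with degree <= 1
      are skipped: they carry no co-neighbor evidence and 1/ln 1 diverges)
    * ``JA(i,j) = |Γ_i ∩ Γ_j| / |Γ_i ∪ Γ_j|``
    * ``SA(i,j) = |Γ_i ∩ Γ_j| / sqrt(|Γ_i| |Γ_j|)``

    Pairs involving an empty neighborhood score 0; the diagonal is the
    index's self-value (1 for JA/SA when Γ_i is nonempty).
    """
    if index not in FUNCTION_INDICES:
        raise ValueError(f"unknown function-similarity index {index!r}")
    if not tg.edges:
        raise ValueError("target-gene network has no edges")
    hoods = tg.neighborhoods()
    gene_deg = tg.gene_degrees()
    # AA weight per gene; degree-<=1 genes contribute nothing
    aa_w = np.zeros(len(tg.gene_ids))
    big = gene_deg > 1
    aa_w[big] = 1.0 / np.log(gene_deg[big].astype(float))
    n = len(tg.rna_ids)
    values = np.zeros((n, n))
    for i in range(n):
        gi = hoods[i]
        if not gi:
            continue
        for j in range(i, n):
            gj = hoods[j]
            if not gj:
                continue
            inter = gi & gj
            if index == "CN":
                val = float(len(inter))
            elif index == "AA":
                val = float(sum(aa_w[z] for z in inter))
            elif index == "JA":
                val = len(inter) / len(gi | gj)
            else:  # SA
                val = len(inter) / math.sqrt(len(gi) * len(gj))
            values[i, j] = values[j, i] = val
    valid = np.ones(n, dtype=bool)
    return SimilarityMatrix(list(tg.rna_ids), values, valid, "function")


# ---------------------------------------------------------------------------
# similarity selection for the model
# ---------------------------------------------------------------------------


def _build(
    kind: str,
    sources: SimilaritySources,
    side: str,
    function_index: str,
    align_params: AlignmentParams | None,
) -> SimilarityMatrix:
    if kind == "expression":
        if sources.expression is None:
            raise ValueError(f"expression similarity requested for {side} but no profiles supplied")
        return expression_similarity(sources.expression)
    if kind == "sequence":
        if sources.sequence is None:
            raise ValueError(f"sequence similarity requested for {side} but no sequences supplied")
        return sequence_similarity(sources.sequence, align_params)
    if kind == "function":
        if sources.targets is None:
            raise ValueError(f"function similarity requested for {side} but no target-gene data supplied")
        return function_similarity(sources.targets, function_index)
    raise ValueError(f"unknown similarity kind {kind!r}")


def select_similarity(
    net: InteractionNetwork,
    mirna_sources: SimilaritySources,
    lncrna_sources: SimilaritySources,
    kind_mirna: str = "function",
    kind_lncrna: str = "expression",
    mirna_function_index: str = "AA",
    lncrna_function_index: str = "SA",
    align_params: AlignmentParams | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Build (S_m, S_l) aligned to the network's id ordering.

    Defaults follow the best-performing pairing: function-based (AA index)
    similarity for miRNAs and expression-profile similarity for lncRNAs;
    function-based lncRNA similarity uses the SA index by default.  RNAs
    absent from the chosen source get all-zero rows flagged invalid.
    """
    s_m = _build(kind_mirna, mirna_sources, "miRNA", mirna_function_index, align_params)
    s_l = _build(kind_lncrna, lncrna_sources, "lncRNA", lncrna_function_index, align_params)
    return s_m.reindex(net.mirna_ids), s_l.reindex(net.lncrna_ids)
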