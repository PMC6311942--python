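"""Planted-block synthetic data with the statistical structure the model assumes.

The generator emulates a sparse bipartite miRNA-lncRNA interaction network
together with the three side-data channels used for similarity:

* miRNAs and lncRNAs are assigned to co-regulation blocks; an interaction
  (i, j) is drawn with probability ``p_in`` when i and j share a block and
  ``p_out`` otherwise, so within-block link density is the planted signal.
* expression profiles are block mean vectors plus Gaussian noise, making
  same-block RNAs positively correlated; a configurable fraction of
  profiles is blanked to emulate RNAs absent from expression databases.
* target-gene sets are drawn mostly from a per-block gene pool plus random
  extras, giving same-block pairs high neighbor-overlap (CN/AA/JA/SA).
* sequences are uniform-random nucleotides with a short block motif
  embedded, deliberately the weakest channel.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_data import (
    ExpressionProfileSet,
    InteractionNetwork,
    SequenceSet,
    TargetGeneNetwork,
    write_expression_profiles,
    write_interactions,
    write_sequences,
    write_target_genes,
)

__all__ = ["GeneratorConfig", "SyntheticData", "generate", "paper_scale_config", "write_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the planted-block generator.

    Defaults give a 60 x 100 network with 4 blocks at ~9% density and a
    moderate expression signal-to-noise ratio.
    """

    nm: int = 60
    nl: int = 100
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    expr_dims: tuple[int, int] = (172, 22)  # (miRNA N, lncRNA N)
    expr_noise: float = 0.5  # noise SD relative to unit block signal
    missing_frac_mirna: float = 0.1
    missing_frac_lncrna: float = 0.1
    n_genes: int = 120
    genes_per_block: int = 15
    gene_keep_prob: float = 0.8
    extra_genes: int = 5
    seq_len_mirna: tuple[int, int] = (20, 24)
    seq_len_lncrna: tuple[int, int] = (200, 400)
    motif_len: int = 8
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1 for planted structure")
        if min(self.nm, self.nl, self.n_blocks) < 1:
            raise ValueError("counts must be >= 1")
        for frac in (self.missing_frac_mirna, self.missing_frac_lncrna):
            if not 0.0 <= frac < 1.0:
                raise ValueError("missing fractions must lie in [0, 1)")
        if self.expected_density() == 0.0:
            raise ValueError("degenerate config: expected degree is zero")

    def expected_density(self) -> float:
        share_in = 1.0 / self.n_blocks
        return self.p_in * share_in + self.p_out * (1.0 - share_in)


@dataclass
class SyntheticData:
    net: InteractionNetwork
    mirna_expression: ExpressionProfileSet
    lncrna_expression: ExpressionProfileSet
    mirna_targets: TargetGeneNetwork
    lncrna_targets: TargetGeneNetwork
    mirna_sequences: SequenceSet
    lncrna_sequences: SequenceSet
    mirna_blocks: np.ndarray
    lncrna_blocks: np.ndarray


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    return np.arange(n) % n_blocks


def _expression(
    ids: list[str],
    blocks: np.ndarray,
    n_attr: int,
    noise: float,
    missing_frac: float,
    rng: np.random.Generator,
) -> ExpressionProfileSet:
    n_blocks = int(blocks.max()) + 1
    means = rng.normal(0.0, 1.0, size=(n_blocks, n_attr))
    profiles = means[blocks] + noise * rng.normal(0.0, 1.0, size=(len(ids), n_attr))
    available = np.ones(len(ids), dtype=bool)
    n_missing = int(round(missing_frac * len(ids)))
    if n_missing:
        gone = rng.choice(len(ids), size=n_missing, replace=False)
        available[gone] = False
        profiles[gone] = 0.0
    return ExpressionProfileSet(ids, profiles, available)


def _target_genes(
    ids: list[str],
    blocks: np.ndarray,
    cfg: GeneratorConfig,
    prefix: str,
    rng: np.random.Generator,
) -> TargetGeneNetwork:
    gene_ids = [f"{prefix}-gene-{g:04d}" for g in range(cfg.n_genes)]
    pools = [
        rng.choice(cfg.n_genes, size=min(cfg.genes_per_block, cfg.n_genes), replace=False)
        for _ in range(cfg.n_blocks)
    ]
    edges: set[tuple[int, int]] = set()
    for r, b in enumerate(blocks):
        pool = pools[int(b)]
        keep = pool[rng.random(pool.size) < cfg.gene_keep_prob]
        extras = rng.choice(cfg.n_genes, size=cfg.extra_genes, replace=False)
        for g in np.concatenate([keep, extras]):
            edges.add((r, int(g)))
    return TargetGeneNetwork(ids, gene_ids, edges)


_BASES = np.array(list("ACGT"))


def _sequences(
    ids: list[str],
    blocks: np.ndarray,
    len_range: tuple[int, int],
    motif_len: int,
    rng: np.random.Generator,
) -> SequenceSet:
    n_blocks = int(blocks.max()) + 1
    motifs = ["".join(rng.choice(_BASES, size=motif_len)) for _ in range(n_blocks)]
    seqs = []
    lo, hi = len_range
    for b in blocks:
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(_BASES, size=length))
        motif = motifs[int(b)]
        if length > motif_len:
            pos = int(rng.integers(0, length - motif_len))
            seq[pos : pos + motif_len] = list(motif)
        seqs.append("".join(seq))
    return SequenceSet(ids, seqs)


def generate(config: GeneratorConfig | None = None) -> SyntheticData:
    """Draw one complete dataset; byte-identical given the same config."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    mirna_ids = [f"miR-{i:04d}" for i in range(cfg.nm)]
    lncrna_ids = [f"lnc-{j:04d}" for j in range(cfg.nl)]
    mb = _blocks(cfg.nm, cfg.n_blocks)
    lb = _blocks(cfg.nl, cfg.n_blocks)

    same = mb[:, None] == lb[None, :]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    adj = rng.random((cfg.nm, cfg.nl)) < prob
    pairs = {(int(i), int(j)) for i, j in zip(*np.nonzero(adj))}
    if not pairs:
        raise ValueError("generated network has no interactions; raise p_in/p_out")
    net = InteractionNetwork(mirna_ids, lncrna_ids, pairs)

    n_attr_m, n_attr_l = cfg.expr_dims
    expr_m = _expression(mirna_ids, mb, n_attr_m, cfg.expr_noise, cfg.missing_frac_mirna, rng)
    expr_l = _expression(lncrna_ids, lb, n_attr_l, cfg.expr_noise, cfg.missing_frac_lncrna, rng)
    tg_m = _target_genes(mirna_ids, mb, cfg, "m", rng)
    tg_l = _target_genes(lncrna_ids, lb, cfg, "l", rng)
    seq_m = _sequences(mirna_ids, mb, cfg.seq_len_mirna, cfg.motif_len, rng)
    seq_l = _sequences(lncrna_ids, lb, cfg.seq_len_lncrna, cfg.motif_len, rng)
    return SyntheticData(net, expr_m, expr_l, tg_m, tg_l, seq_m, seq_l, mb, lb)


def paper_scale_config(seed: int = 7) -> GeneratorConfig:
    """Config matching the reference dataset's shape statistics.

    275 miRNAs x 780 lncRNAs at an expected density of 2.49% (about 5342
    expected interactions), 172-attribute miRNA and 22-attribute lncRNA
    expression profiles, with 16.4% of miRNA and 42.3% of lncRNA profiles
    missing.  Block probabilities keep the default 15:1 in/out ratio and
    are solved so that p_in/B + p_out(1 - 1/B) equals the target density.
    """
    target_density = 0.0249
    n_blocks = 4
    ratio = 15.0
    p_out = target_density / (ratio / n_blocks + (1.0 - 1.0 / n_blocks))
    p_in = ratio * p_out
    return GeneratorConfig(
        nm=275,
        nl=780,
        n_blocks=n_blocks,
        p_in=p_in,
        p_out=p_out,
        expr_dims=(172, 22),
        missing_frac_mirna=0.164,
        missing_frac_lncrna=0.423,
        seed=seed,
    )


def write_dataset(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write all fixture files in the standard text formats; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "mirna_expression": outdir / "mirna_expression.tsv",
        "lncrna_expression": outdir / "lncrna_expression.tsv",
        "mirna_targets": outdir / "mirna_targets.tsv",
        "lncrna_targets": outdir / "lncrna_targets.tsv",
        "mirna_sequences": outdir / "mirna_sequences.fasta",
        "lncrna_sequences": outdir / "lncrna_sequences.fasta",
    }
    write_interactions(data.net, paths["interactions"])
    write_expression_profiles(data.mirna_expression, paths["mirna_expression"])
    write_expression_profiles(data.lncrna_expression, paths["lncrna_expression"])
    write_target_genes(data.mirna_targets, paths["mirna_targets"])
    write_target_genes(data.lncrna_targets, paths["lncrna_targets"])
    write_sequences(data.mirna_sequences, paths["mirna_sequences"])
    write_sequences(data.lncrna_sequences, paths["lncrna_sequences"])
    return paths
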