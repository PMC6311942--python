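"""Containers and text-format I/O for bipartite miRNA-lncRNA interaction data.

The central object is :class:`InteractionNetwork`, the observed bipartite
graph of miRNA-lncRNA interactions.  Side data used to build RNA-RNA
similarity matrices come in three flavours: expression profiles (numeric
matrices over tissues/cell lines), RNA-to-target-gene edge lists, and
nucleotide sequences (FASTA).  All on-disk formats are plain delimited text;
edge lists are tab- or comma-delimited with the delimiter auto-detected.

Identifiers are matched case-sensitively and never aliased.  Internally all
indexing is 0-based; files always carry identifiers, never indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mirlnc")

__all__ = [
    "InteractionNetwork",
    "ExpressionProfileSet",
    "TargetGeneNetwork",
    "SequenceSet",
    "SimilarityMatrix",
    "ParseError",
    "load_interactions",
    "write_interactions",
    "network_density",
    "average_mirna_degree",
    "load_expression_profiles",
    "write_expression_profiles",
    "load_target_genes",
    "write_target_genes",
    "load_sequences",
    "write_sequences",
    "load_similarity",
    "write_similarity",
    "write_ranking_lists",
]


class ParseError(ValueError):
    """Raised when an input file is malformed; message names the line."""


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------


@dataclass
class InteractionNetwork:
    """Observed bipartite interaction graph over ``nm`` miRNAs x ``nl`` lncRNAs.

    ``pairs`` holds 0-based ``(mirna_index, lncrna_index)`` tuples of the
    observed (positive) interactions only; unobserved pairs are unlabeled,
    not negative.
    """

    mirna_ids: list[str]
    lncrna_ids: list[str]
    pairs: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA identifiers")
        if not self.mirna_ids or not self.lncrna_ids:
            raise ValueError("network needs at least one miRNA and one lncRNA")
        nm, nl = self.nm, self.nl
        for i, j in self.pairs:
            if not (0 <= i < nm and 0 <= j < nl):
                raise ValueError(f"pair index out of range: ({i}, {j})")

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def nl(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def mirna_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.mirna_ids)}

    def lncrna_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.lncrna_ids)}

    def lnc_partners(self) -> list[np.ndarray]:
        """Observed lncRNA partner indices per miRNA (the sets L_i)."""
        out: list[list[int]] = [[] for _ in range(self.nm)]
        for i, j in self.pairs:
            out[i].append(j)
        return [np.array(sorted(js), dtype=np.intp) for js in out]

    def mir_partners(self) -> list[np.ndarray]:
        """Observed miRNA partner indices per lncRNA (the sets M_j)."""
        out: list[list[int]] = [[] for _ in range(self.nl)]
        for i, j in self.pairs:
            out[j].append(i)
        return [np.array(sorted(ii), dtype=np.intp) for ii in out]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.nm, self.nl), dtype=bool)
        for i, j in self.pairs:
            a[i, j] = True
        return a


@dataclass
class ExpressionProfileSet:
    """Per-RNA expression vectors over N tissue/cell-line attributes.

    RNAs whose profile is absent from the source carry ``available=False``
    and a zero vector; zero-variance profiles are kept but flagged unusable
    for correlation via :meth:`usable`.
    """

    rna_ids: list[str]
    profiles: np.ndarray  # shape (n_rna, N)
    available: np.ndarray  # bool, shape (n_rna,)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.available = np.asarray(self.available, dtype=bool)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != len(self.rna_ids):
            raise ValueError("profiles must be (n_rna, N)")
        if self.profiles.shape[1] < 2:
            raise ValueError("profiles need at least N=2 attributes")
        if self.available.shape != (len(self.rna_ids),):
            raise ValueError("available flag shape mismatch")

    @property
    def n_attributes(self) -> int:
        return self.profiles.shape[1]

    def usable(self) -> np.ndarray:
        """Available AND non-constant: rows for which Pearson r is defined."""
        variances = self.profiles.var(axis=1)
        return self.available & (variances > 0)


@dataclass
class TargetGeneNetwork:
    """RNA -> target-gene bipartite edges; Γ_i is the gene set of RNA i."""

    rna_ids: list[str]
    gene_ids: list[str]
    edges: set[tuple[int, int]]

    def __post_init__(self) -> None:
        nr, ng = len(self.rna_ids), len(self.gene_ids)
        for r, g in self.edges:
            if not (0 <= r < nr and 0 <= g < ng):
                raise ValueError(f"edge index out of range: ({r}, {g})")

    def neighborhoods(self) -> list[set[int]]:
        """Γ_i for every RNA i (possibly empty)."""
        out: list[set[int]] = [set() for _ in self.rna_ids]
        for r, g in self.edges:
            out[r].add(g)
        return out

    def gene_degrees(self) -> np.ndarray:
        """Number of RNAs linked to each gene (|Γ_z| with z a gene)."""
        deg = np.zeros(len(self.gene_ids), dtype=np.intp)
        for _, g in self.edges:
            deg[g] += 1
        return deg


@dataclass
class SequenceSet:
    """Nucleotide sequences per RNA; U is normalized to T on construction."""

    rna_ids: list[str]
    sequences: list[str]

    _ALPHABET = frozenset("ACGTN")

    def __post_init__(self) -> None:
        if len(self.rna_ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        norm = []
        for rid, seq in zip(self.rna_ids, self.sequences):
            s = seq.upper().replace("U", "T")
            if not s:
                raise ValueError(f"empty sequence for {rid}")
            bad = set(s) - self._ALPHABET
            if bad:
                raise ValueError(f"non-nucleotide characters {sorted(bad)} in {rid}")
            norm.append(s)
        self.sequences = norm


@dataclass
class SimilarityMatrix:
    """Symmetric RNA-RNA similarity over one RNA class.

    ``kind`` declares the value range contract: sequence in [0,1],
    expression in [-1,1], function >= 0.  Rows/columns of RNAs absent from
    the source data are all-zero and flagged ``valid=False``.
    """

    rna_ids: list[str]
    values: np.ndarray
    valid: np.ndarray
    kind: str

    KINDS = ("sequence", "expression", "function")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.rna_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over rna_ids")
        if self.valid.shape != (n,):
            raise ValueError("valid flag shape mismatch")

    def check(self, atol: float = 1e-9) -> None:
        """Assert the symmetry/range/invalid-row invariants."""
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite similarity values")
        if not np.array_equal(v, v.T):
            raise ValueError("similarity matrix not symmetric")
        lo, hi = {"sequence": (0.0, 1.0), "expression": (-1.0, 1.0), "function": (0.0, np.inf)}[self.kind]
        if v.min() < lo - atol or v.max() > hi + atol:
            raise ValueError(f"{self.kind} similarity outside [{lo}, {hi}]")
        invalid = ~self.valid
        if invalid.any() and (np.abs(v[invalid]).max() > 0 or np.abs(v[:, invalid]).max() > 0):
            raise ValueError("invalid rows/columns must be all zero")

    def reindex(self, rna_ids: Sequence[str]) -> "SimilarityMatrix":
        """Project onto a new id ordering; unknown ids get invalid zero rows."""
        old = {s: i for i, s in enumerate(self.rna_ids)}
        n = len(rna_ids)
        values = np.zeros((n, n))
        valid = np.zeros(n, dtype=bool)
        present = [(a, old[s]) for a, s in enumerate(rna_ids) if s in old]
        if present:
            new_idx = np.array([a for a, _ in present], dtype=np.intp)
            old_idx = np.array([b for _, b in present], dtype=np.intp)
            values[np.ix_(new_idx, new_idx)] = self.values[np.ix_(old_idx, old_idx)]
            valid[new_idx] = self.valid[old_idx]
        # ids that were invalid in the source stay zero; re-zero defensively
        values[~valid, :] = 0.0
        values[:, ~valid] = 0.0
        return SimilarityMatrix(list(rna_ids), values, valid, self.kind)


# ---------------------------------------------------------------------------
# edge-list parsing
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _read_edge_rows(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column delimited edge list, skipping '#' comments.

    A header row is detected when neither of the first row's tokens occurs
    again anywhere in the file as an identifier.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        lineno = 0
        delim = None
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            fields = [f.strip() for f in line.split(delim)]
            if len(fields) != 2 or not all(fields):
                raise ParseError(f"{path}: malformed line {lineno}: {line!r}")
            rows.append((fields[0], fields[1]))
    if not rows:
        raise ParseError(f"{path}: empty edge list")
    if len(rows) > 1:
        head = set(rows[0])
        rest = {tok for row in rows[1:] for tok in row}
        if not head & rest:
            rows = rows[1:]
    return rows


def _index_edges(rows: Iterable[tuple[str, str]], what: str) -> tuple[list[str], list[str], set[tuple[int, int]]]:
    left_ids: list[str] = []
    right_ids: list[str] = []
    left_pos: dict[str, int] = {}
    right_pos: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_dup = 0
    for a, b in rows:
        if a not in left_pos:
            left_pos[a] = len(left_ids)
            left_ids.append(a)
        if b not in right_pos:
            right_pos[b] = len(right_ids)
            right_ids.append(b)
        e = (left_pos[a], right_pos[b])
        if e in edges:
            n_dup += 1
        else:
            edges.add(e)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", what, n_dup)
    return left_ids, right_ids, edges


def load_interactions(path: str | Path) -> InteractionNetwork:
    """Load a (miRNA_id, lncRNA_id) edge list into an :class:`InteractionNetwork`.

    Identifiers are deduplicated preserving first-seen order; duplicate
    edges are collapsed with a logged warning.
    """
    rows = _read_edge_rows(path)
    mirna_ids, lncrna_ids, pairs = _index_edges(rows, f"interactions {path}")
    return InteractionNetwork(mirna_ids, lncrna_ids, pairs)


def write_interactions(net: InteractionNetwork, path: str | Path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("mirna_id\tlncrna_id\n")
        for i, j in sorted(net.pairs):
            fh.write(f"{net.mirna_ids[i]}\t{net.lncrna_ids[j]}\n")


def load_target_genes(path: str | Path) -> TargetGeneNetwork:
    """Load an (RNA_id, gene_id) edge list."""
    rows = _read_edge_rows(path)
    rna_ids, gene_ids, edges = _index_edges(rows, f"target genes {path}")
    return TargetGeneNetwork(rna_ids, gene_ids, edges)


def write_target_genes(tg: TargetGeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rna_id\tgene_id\n")
        for r, g in sorted(tg.edges):
            fh.write(f"{tg.rna_ids[r]}\t{tg.gene_ids[g]}\n")


# ---------------------------------------------------------------------------
# network statistics
# ---------------------------------------------------------------------------


def network_density(net: InteractionNetwork) -> tuple[float, float]:
    """Fraction of possible miRNA-lncRNA pairs that are observed.

    Returns ``(fraction, percentage)`` where percentage is 100x the
    fraction.  The reference network of 5348 interactions over 275 miRNAs
    and 780 lncRNAs has a density of 2.49%.
    """
    frac = net.n_pairs / (net.nm * net.nl)
    return frac, 100.0 * frac


def average_mirna_degree(net: InteractionNetwork) -> float:
    """Mean number of observed lncRNA partners per miRNA (|pairs| / nm)."""
    return net.n_pairs / net.nm


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------


def load_expression_profiles(path: str | Path, delimiter: str | None = None) -> ExpressionProfileSet:
    """Load a delimited matrix: first column RNA id, remaining N numeric columns.

    Rows containing any empty cell are treated as missing profiles
    (``available=False``), matching sources that blank unprofiled RNAs.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c",
                     index_col=0, comment="#")
    ids = [str(s) for s in df.index]
    values = df.to_numpy(dtype=float)
    missing = np.isnan(values).any(axis=1)
    values = np.where(np.isnan(values), 0.0, values)
    return ExpressionProfileSet(ids, values, ~missing)


def write_expression_profiles(profiles: ExpressionProfileSet, path: str | Path) -> None:
    n = profiles.n_attributes
    with open(path, "w") as fh:
        fh.write("rna_id\t" + "\t".join(f"attr{k+1}" for k in range(n)) + "\n")
        for rid, row, avail in zip(profiles.rna_ids, profiles.profiles, profiles.available):
            if avail:
                fh.write(rid + "\t" + "\t".join(format(x, ".6g") for x in row) + "\n")
            else:
                fh.write(rid + "\t" * n + "\n")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def load_sequences(path: str | Path) -> SequenceSet:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ParseError(f"{path}: no FASTA records")
    return SequenceSet(ids, seqs)


def write_sequences(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(seqs.rna_ids, seqs.sequences):
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write an id-labelled delimited matrix with self-describing comments."""
    invalid = [s for s, ok in zip(sim.rna_ids, sim.valid) if not ok]
    with open(path, "w") as fh:
        fh.write(f"# kind={sim.kind}\n")
        fh.write("# invalid=" + ",".join(invalid) + "\n")
        fh.write("rna_id\t" + "\t".join(sim.rna_ids) + "\n")
        for rid, row in zip(sim.rna_ids, sim.values):
            fh.write(rid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def load_similarity(path: str | Path) -> SimilarityMatrix:
    kind = "expression"
    invalid: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("kind="):
                kind = body[5:]
            elif body.startswith("invalid="):
                invalid = {s for s in body[8:].split(",") if s}
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    ids = [str(s) for s in df.index]
    valid = np.array([s not in invalid for s in ids], dtype=bool)
    return SimilarityMatrix(ids, df.to_numpy(dtype=float), valid, kind)


# ---------------------------------------------------------------------------
# ranking output
# ---------------------------------------------------------------------------


def write_ranking_lists(
    rankings: dict[str, list[tuple[str, float]]],
    k: int,
    path: str | Path,
    comment: str | None = None,
) -> None:
    """Write per-query top-k candidate lists as 4-column delimited text.

    ``rankings`` maps each query RNA id to ``(candidate_id, score)`` pairs.
    Rows are sorted by descending score with deterministic lexicographic
    tie-break on candidate id, truncated to ``k`` rows per query.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("query_id\tcandidate_id\tscore\trank\n")
        for query in rankings:
            scored = rankings[query]
            for cand, score in scored:
                if not np.isfinite(score):
                    raise ValueError(f"non-finite score for ({query}, {cand})")
            ordered = sorted(scored, key=lambda cs: (-cs[1], cs[0]))[:k]
            for rank, (cand, score) in enumerate(ordered, start=1):
                fh.write(f"{query}\t{cand}\t{score:.6f}\t{rank}\n")
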