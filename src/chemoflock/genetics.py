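"""Genetic-side bookkeeping for the concordance analysis.

This module does not infer trees or fit substitution models — published
tools do that. It implements the arithmetic and validation around them:
multilocus concatenation with a minimum-genes inclusion rule and
missing-data padding, IUPAC ambiguity coding of heterozygous SNP sites,
posterior-sample accounting for MCMC tree samples, simple p-distance
phylogroup delimitation for synthetic cohorts, and Newick tree
ingestion with tip annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO


class GeneticsError(ValueError):
    pass


_IUPAC_PAIRS = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
}

_MISSING = set("-?NRYSWKMBDHV")  # treated as missing for p-distances


@dataclass
class GenePartition:
    """One aligned gene: id -> sequence, all sequences equal length."""

    gene: str
    alignment: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise GeneticsError(
                f"partition {self.gene!r} is ragged: sequence lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        if not self.alignment:
            return 0
        return len(next(iter(self.alignment.values())))

    @classmethod
    def from_fasta(cls, gene: str, path: str | Path) -> "GenePartition":
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise GeneticsError(f"{path}: no sequences")
        return cls(gene=gene, alignment=records)


@dataclass
class ConcatenatedAlignment:
    matrix: dict[str, str]
    boundaries: dict[str, tuple[int, int]]  # gene -> [start, end) columns
    excluded: dict[str, int] = field(default_factory=dict)  # id -> n genes present

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.boundaries.values())

    @property
    def included_ids(self) -> list[str]:
        return list(self.matrix)


def concatenate(partitions: list[GenePartition], min_genes: int = 2,
                missing_char: str = "?") -> ConcatenatedAlignment:
    """Join gene partitions column-wise per individual.

    Individuals represented in fewer than ``min_genes`` partitions are
    excluded (recorded in the ``excluded`` manifest with their gene
    count); absent genes for included individuals are padded with the
    missing character. Gaps present in the source alignments are
    preserved; downstream both '-' and '?' count as missing data.
    """
    if not partitions:
        raise GeneticsError("need at least one partition")
    names = [p.gene for p in partitions]
    if len(set(names)) != len(names):
        raise GeneticsError(f"duplicate gene names: {names}")
    counts: dict[str, int] = {}
    for p in partitions:
        for ind in p.alignment:
            counts[ind] = counts.get(ind, 0) + 1
    included = [ind for ind in counts if counts[ind] >= min_genes]
    excluded = {ind: c for ind, c in counts.items() if c < min_genes}
    boundaries: dict[str, tuple[int, int]] = {}
    start = 0
    for p in partitions:
        boundaries[p.gene] = (start, start + p.length)
        start += p.length
    matrix = {
        ind: "".join(
            p.alignment.get(ind, missing_char * p.length) for p in partitions
        )
        for ind in included
    }
    return ConcatenatedAlignment(matrix=matrix, boundaries=boundaries,
                                 excluded=excluded)


def code_ambiguity(seq: str, het_sites: list[tuple[int, str, str]]) -> str:
    """Replace heterozygous SNP sites (1-based positions) with IUPAC codes.

    Each site's two observed bases map to the two-base ambiguity code
    (A/G -> R, C/T -> Y, A/C -> M, G/T -> K, A/T -> W, C/G -> S).
    Re-application with the same sites raises, because the coded symbol
    is no longer a plain base.
    """
    chars = list(seq)
    for pos, b1, b2 in het_sites:
        if not (1 <= pos <= len(seq)):
            raise GeneticsError(f"site position {pos} outside sequence of length {len(seq)}")
        b1, b2 = b1.upper(), b2.upper()
        key = frozenset((b1, b2))
        if b1 == b2 or key not in _IUPAC_PAIRS:
            raise GeneticsError(f"no two-base IUPAC code for pair ({b1}, {b2})")
        current = chars[pos - 1].upper()
        if current not in "ACGT":
            raise GeneticsError(
                f"site {pos} holds {current!r}, not a plain base; already coded?"
            )
        chars[pos - 1] = _IUPAC_PAIRS[key]
    return "".join(chars)


@dataclass(frozen=True)
class TreeSamplePlan:
    """MCMC sampling layout used to account for retained posterior trees."""

    n_runs: int
    n_generations: int
    sample_freq: int
    burnin_frac: float = 0.10
    include_generation_zero: bool = True

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_generations < 1 or self.sample_freq < 1:
            raise GeneticsError("runs, generations and sample_freq must be positive")
        if not (0 <= self.burnin_frac < 1):
            raise GeneticsError(f"burnin_frac {self.burnin_frac} outside [0, 1)")


def posterior_sample_accounting(plan: TreeSamplePlan) -> int:
    """Trees retained after per-run burn-in removal.

    Samples per run = generations / sample_freq, plus one if the
    generation-zero state is sampled; burn-in per run discards
    ``floor(burnin_frac * samples)``. With 8 runs of 20 M generations
    sampled every 1000 (generation zero included) and 10% burn-in this
    yields 144,008 retained trees.
    """
    if plan.n_generations % plan.sample_freq != 0:
        raise GeneticsError(
            f"sample_freq {plan.sample_freq} does not divide "
            f"n_generations {plan.n_generations}"
        )
    per_run = plan.n_generations // plan.sample_freq
    if plan.include_generation_zero:
        per_run += 1
    burnin = int(np.floor(plan.burnin_frac * per_run))
    return plan.n_runs * (per_run - burnin)


# ---------------------------------------------------------------------------
# phylogroup assignment
# ---------------------------------------------------------------------------

@dataclass
class PhylogroupAssignment:
    assignment: dict[str, str]
    nuclear_cluster: dict[str, str] | None = None
    source: str = "provided"

    def __post_init__(self) -> None:
        empty = [i for i, lab in self.assignment.items() if not lab]
        if empty:
            raise GeneticsError(f"empty phylogroup label for: {empty}")


def p_distance(seq_a: str, seq_b: str, min_shared: int = 50) -> float:
    """Proportion of differing sites over shared unambiguous positions.

    Sites where either sequence is a gap, '?', N or an ambiguity code
    are skipped. Raises if fewer than ``min_shared`` comparable sites
    remain.
    """
    if len(seq_a) != len(seq_b):
        raise GeneticsError("sequences differ in length")
    shared = diff = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _MISSING or b in _MISSING:
            continue
        shared += 1
        if a != b:
            diff += 1
    if shared < min_shared:
        raise GeneticsError(
            f"only {shared} shared unambiguous sites (< {min_shared})"
        )
    return diff / shared


def assign_phylogroups(partition: GenePartition, method: str = "distance_threshold",
                       threshold: float = 0.05, min_shared: int = 50,
                       provided: dict[str, str] | None = None) -> PhylogroupAssignment:
    """Delimit phylogroups by single-linkage clustering of p-distances.

    Individuals with pairwise distance <= ``threshold`` are linked;
    connected components become phylogroups labelled PG1, PG2, ... in
    order of first member appearance. ``method="provided"`` validates
    and passes through an existing labelling instead.
    """
    ids = list(partition.alignment)
    if method == "provided":
        if provided is None:
            raise GeneticsError("provided-labels mode needs a labelling")
        missing = [i for i in ids if i not in provided]
        if missing:
            raise GeneticsError(f"no provided label for: {missing}")
        return PhylogroupAssignment(assignment={i: provided[i] for i in ids},
                                    source="provided")
    if method != "distance_threshold":
        raise GeneticsError(f"unknown method {method!r}")

    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx_a in range(len(ids)):
        for idx_b in range(idx_a + 1, len(ids)):
            a, b = ids[idx_a], ids[idx_b]
            try:
                d = p_distance(partition.alignment[a], partition.alignment[b],
                               min_shared=min_shared)
            except GeneticsError as e:
                raise GeneticsError(f"pair ({a}, {b}): {e}") from e
            if d <= threshold:
                parent[find(a)] = find(b)
    labels: dict[str, str] = {}
    assignment: dict[str, str] = {}
    for i in ids:
        root = find(i)
        if root not in labels:
            labels[root] = f"PG{len(labels) + 1}"
        assignment[i] = labels[root]
    return PhylogroupAssignment(assignment=assignment, source="distance_threshold")


def read_phylogroup_tsv(path: str | Path) -> PhylogroupAssignment:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "individual_id" not in df.columns or "phylogroup" not in df.columns:
        raise GeneticsError(f"{path}: need columns individual_id, phylogroup")
    nuclear = None
    if "nuclear_cluster" in df.columns:
        nuclear = dict(zip(df["individual_id"], df["nuclear_cluster"]))
    return PhylogroupAssignment(
        assignment=dict(zip(df["individual_id"], df["phylogroup"])),
        nuclear_cluster=nuclear,
    )


def write_phylogroup_tsv(assignment: PhylogroupAssignment, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        cols = ["individual_id", "phylogroup"]
        if assignment.nuclear_cluster is not None:
            cols.append("nuclear_cluster")
        fh.write("\t".join(cols) + "\n")
        for ind, pg in assignment.assignment.items():
            row = [ind, pg]
            if assignment.nuclear_cluster is not None:
                row.append(assignment.nuclear_cluster.get(ind, ""))
            fh.write("\t".join(row) + "\n")
    return path


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as e:  # dendropy raises several parse error types
        raise GeneticsError(f"{path}: malformed Newick ({e})") from e


def map_tips(tree: dendropy.Tree,
             assignment: PhylogroupAssignment) -> tuple[dendropy.Tree, list[str]]:
    """Annotate tree tips with phylogroup labels; report unmatched tips."""
    unmatched = []
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is not None and name in assignment.assignment:
            leaf.annotations.add_new("phylogroup", assignment.assignment[name])
        else:
            unmatched.append(name if name is not None else "<unlabelled>")
    return tree, unmatched


def phylogroups_are_sister(tree: dendropy.Tree, tips_a: list[str],
                           tips_b: list[str]) -> bool:
    """True if the union of the two tip sets forms its own clade.

    Used to operationalize "closely related": two phylogroups whose
    combined members are exclusive descendants of one node are adjacent
    on the tree.
    """
    wanted = set(tips_a) | set(tips_b)
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    if not wanted <= present:
        return False
    for node in tree.preorder_internal_node_iter():
        clade = {leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon}
        if clade == wanted:
            return True
    return False
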