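"""Condition-level comparison of binding profiles.

Covers the descriptive comparisons made across disease conditions: exact
Venn partitions of bound-gene sets, intersections of gene sets from
different footprinting methods, gained/lost footprint bases between
conditions, and k-mer motif enrichment in footprint sequences against a
dinucleotide-preserving shuffle null.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .intervals import ConsensusFootprint, GenomicInterval, IntervalSet, subtract

__all__ = [
    "VennPartition",
    "MotifEnrichment",
    "FootprintDelta",
    "venn_partition",
    "genes_common",
    "footprint_delta",
    "kmer_enrichment",
    "dinucleotide_shuffle",
]


@dataclass
class VennPartition:
    """Exclusive-region counts of a multi-set partition of bound genes.

    ``counts`` maps a sorted tuple of condition labels to the number of
    genes found in exactly those conditions; ``percentages`` expresses each
    region as a percentage of the union.
    """

    counts: dict[tuple[str, ...], int]
    percentages: dict[tuple[str, ...], float]
    union_size: int
    empty: bool = False


@dataclass
class MotifEnrichment:
    motif: str
    observed: int
    shuffle_mean: float
    shuffle_sd: float
    z: float
    p_empirical: float
    n_shuffles: int
    n_skipped: int = 0


@dataclass
class FootprintDelta:
    """Bases lost and gained between two consensus footprint sets."""

    lost: IntervalSet
    gained: IntervalSet
    per_gene: dict[str, dict[str, int]] = field(default_factory=dict)

    def lost_bases(self) -> int:
        return sum(len(iv) for iv in self.lost)

    def gained_bases(self) -> int:
        return sum(len(iv) for iv in self.gained)


def venn_partition(sets: dict[str, set[str]]) -> VennPartition:
    """Exact exclusive-region counts for two or more labelled gene sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 conditions")
    labels = sorted(sets)
    union: set[str] = set().union(*sets.values())
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            counts[combo] = 0
    for gene in union:
        members = tuple(lab for lab in labels if gene in sets[lab])
        counts[members] += 1
    if not union:
        return VennPartition(counts=counts,
                             percentages={k: 0.0 for k in counts},
                             union_size=0, empty=True)
    percentages = {k: 100.0 * v / len(union) for k, v in counts.items()}
    return VennPartition(counts=counts, percentages=percentages,
                         union_size=len(union))


def genes_common(method_a: set[str], method_b: set[str]) -> list[str]:
    """Genes found by both footprinting methods, in sorted order."""
    return sorted(set(method_a) & set(method_b))


def _regions_with_gene(footprints: list[ConsensusFootprint]) -> IntervalSet:
    from dataclasses import replace
    ivs = []
    for fp in footprints:
        gene = fp.genes[0] if fp.genes else None
        ivs.append(replace(fp.region, name=gene))
    return IntervalSet(ivs)


def footprint_delta(cond_a: list[ConsensusFootprint],
                    cond_b: list[ConsensusFootprint]) -> FootprintDelta:
    """Footprint bases lost and gained going from condition a to condition b.

    lost = bases covered in a but not b; gained = bases covered in b but
    not a.  Fragments inherit the closest-gene label of their source
    consensus region, and per-gene base-pair totals are summarized.
    """
    a = _regions_with_gene(cond_a)
    b = _regions_with_gene(cond_b)
    lost = subtract(a, b)
    gained = subtract(b, a)
    per_gene: dict[str, dict[str, int]] = {}
    for tag, frags in (("lost_bp", lost), ("gained_bp", gained)):
        for iv in frags:
            gene = iv.name or "unassigned"
            per_gene.setdefault(gene, {"lost_bp": 0, "gained_bp": 0})
            per_gene[gene][tag] += len(iv)
    return FootprintDelta(lost=lost, gained=gained, per_gene=per_gene)


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

def _count_occurrences(seq: str, motif: str) -> int:
    """Exact-match occurrences, overlaps counted."""
    n, k, count, i = len(seq), len(motif), 0, 0
    while True:
        i = seq.find(motif, i)
        if i == -1:
            return count
        count += 1
        i += 1  # allow overlapping matches


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erickson construction: the sequence is a walk on the
    dinucleotide multigraph; a random set of last-exit edges forming an
    arborescence into the final character is drawn, the remaining out-edges
    are permuted, and the walk is replayed.
    """
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges.keys())
    for v in vertices:
        edges.setdefault(v, [])

    for _ in range(1000):
        last_edge: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            outs = edges[v]
            if not outs:
                ok = False
                break
            last_edge[v] = outs[int(rng.integers(len(outs)))]
        if not ok:
            break
        # every vertex's last-edge chain must reach the terminal vertex
        def reaches(v: str) -> bool:
            seen = set()
            while v != last:
                if v in seen or v not in last_edge:
                    return False
                seen.add(v)
                v = last_edge[v]
            return True
        if all(reaches(v) for v in vertices if v != last):
            shuffled: dict[str, list[str]] = {}
            for v in vertices:
                outs = list(edges[v])
                if v in last_edge:
                    outs.remove(last_edge[v])
                perm = [outs[i] for i in rng.permutation(len(outs))]
                if v in last_edge:
                    perm.append(last_edge[v])
                shuffled[v] = perm
            out = [seq[0]]
            ptr = {v: 0 for v in vertices}
            v = seq[0]
            for _ in range(len(seq) - 1):
                nxt = shuffled[v][ptr[v]]
                ptr[v] += 1
                out.append(nxt)
                v = nxt
            return "".join(out)
    return seq  # degenerate composition: no valid arborescence found


def _mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    return "".join(chars[i] for i in rng.permutation(len(chars)))


def kmer_enrichment(sequences: list[str] | list[tuple[str, str]],
                    motif: str, n_shuffles: int = 100,
                    seed: int = 0,
                    shuffle: str = "dinucleotide") -> MotifEnrichment:
    """Motif occurrence enrichment against a composition-preserving null.

    ``observed`` is the total number of exact (overlap-counted) motif
    occurrences across all sequences.  The null re-counts occurrences after
    per-sequence shuffles (dinucleotide-preserving by default, which keeps
    local composition; mononucleotide available).  The empirical p-value
    uses the add-one rule, p = (1 + #{shuffle totals >= observed}) /
    (n_shuffles + 1), and so is never zero.  Motifs in the RNA alphabet are
    matched after U->T mapping; sequences shorter than the motif are skipped
    and counted.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    if shuffle not in ("dinucleotide", "mononucleotide"):
        raise ValueError(f"unknown shuffle mode {shuffle!r}")
    motif_dna = motif.upper().replace("U", "T")
    seqs = [s[1] if isinstance(s, tuple) else s for s in sequences]
    usable = [s.upper() for s in seqs if len(s) >= len(motif_dna)]
    n_skipped = len(seqs) - len(usable)
    if not usable:
        raise ValueError("no sequence is at least as long as the motif")

    observed = sum(_count_occurrences(s, motif_dna) for s in usable)
    rng = np.random.default_rng(seed)
    shuffler = (dinucleotide_shuffle if shuffle == "dinucleotide"
                else _mononucleotide_shuffle)
    null = np.empty(n_shuffles)
    for j in range(n_shuffles):
        null[j] = sum(_count_occurrences(shuffler(s, rng), motif_dna)
                      for s in usable)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd > 0:
        z = (observed - mean) / sd
    else:
        z = 0.0 if observed == mean else float(np.sign(observed - mean)) * np.inf
    p = (1 + int((null >= observed).sum())) / (n_shuffles + 1)
    return MotifEnrichment(motif=motif, observed=observed, shuffle_mean=mean,
                           shuffle_sd=sd, z=float(z), p_empirical=p,
                           n_shuffles=n_shuffles, n_skipped=n_skipped)
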