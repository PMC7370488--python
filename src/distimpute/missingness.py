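"""Mechanisms that introduce missing data for benchmarking.

Two mechanisms mirror how incomplete distance matrices arise in practice:

*direct*
    Entries of an existing distance matrix are deleted uniformly at random
    (unordered pairs: both triangles of a pair are masked together).  The
    true values are retained under the mask so downstream evaluation can
    score imputations, but they are never written to disk.

*indirect*
    Whole gene blocks are removed from a concatenated multi-gene alignment.
    If gene 1 is removed from a set of n1 taxa and gene 2 from a disjoint
    set of n2 taxa, those n1 x n2 cross pairs share no homologous sites, so
    the distance matrix computed with pairwise deletion has exactly n1 x n2
    missing entries.

All randomness is explicitly seeded; there is no implicit global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .distances import Alignment
from .matrix import MaskedDistanceMatrix

__all__ = ["GenePartition", "delete_random_entries", "remove_gene_blocks"]


@dataclass(frozen=True)
class GenePartition:
    """Named contiguous gene blocks covering an alignment.

    ``blocks`` maps gene name -> (start, end), 1-based inclusive.  Blocks
    must be disjoint, ordered, and jointly cover sites 1..L.
    """

    blocks: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        blocks = tuple((str(g), int(a), int(b)) for g, a, b in self.blocks)
        if not blocks:
            raise ValueError("partition has no genes")
        names = [g for g, _, _ in blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        pos = 1
        for g, a, b in blocks:
            if a != pos or b < a:
                raise ValueError(
                    f"gene {g!r}: interval ({a},{b}) breaks contiguous coverage at {pos}"
                )
            pos = b + 1
        object.__setattr__(self, "blocks", blocks)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _, _ in self.blocks)

    @property
    def length(self) -> int:
        return self.blocks[-1][2]

    def interval(self, gene: str) -> tuple[int, int]:
        for g, a, b in self.blocks:
            if g == gene:
                return a, b
        raise KeyError(f"unknown gene {gene!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePartition":
        """Read a ``gene<TAB>start<TAB>end`` table (1-based inclusive)."""
        rows = []
        for ln in Path(path).read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            g, a, b = ln.split("\t")
            rows.append((g, int(a), int(b)))
        return cls(tuple(rows))

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{g}\t{a}\t{b}\n" for g, a, b in self.blocks)
        )


def delete_random_entries(
    m: MaskedDistanceMatrix, n_missing: int, seed: int
) -> MaskedDistanceMatrix:
    """Mask ``n_missing`` additional unordered pairs chosen uniformly.

    Pairs are sampled without replacement from the currently observed
    off-diagonal pairs with a generator seeded by ``seed``; the same seed
    always yields the same mask.  Values under the new mask are retained
    internally (for evaluation) but are never emitted by the writer.
    """
    if n_missing < 0:
        raise ValueError("number of entries to delete must be >= 0")
    observed = list(m.observed_pairs())
    if n_missing > len(observed):
        raise ValueError(
            f"cannot delete {n_missing} of {len(observed)} observed pairs"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(observed), size=n_missing, replace=False)
    mask = m.mask.copy()
    for idx in chosen:
        i, j = observed[int(idx)]
        mask[i, j] = mask[j, i] = True
    return m.with_mask(mask)


def remove_gene_blocks(
    aln: Alignment,
    part: GenePartition,
    removals: Mapping[str, set[str] | frozenset[str] | list[str] | tuple[str, ...]],
) -> Alignment:
    """Replace the listed gene blocks with ``?`` for the listed taxa.

    ``removals`` maps taxon label -> genes to remove.  Removed characters
    are ``?`` (unknown data, not indels); the alignment length is
    unchanged.  A removal that would leave a taxon with no genes at all is
    rejected.
    """
    if part.length != aln.length:
        raise ValueError(
            f"partition covers {part.length} sites but alignment has {aln.length}"
        )
    label_set = set(aln.labels)
    for taxon, genes in removals.items():
        if taxon not in label_set:
            raise KeyError(f"unknown taxon {taxon!r}")
        genes = set(genes)
        for g in genes:
            part.interval(g)  # raises on unknown gene
        if genes >= set(part.genes):
            raise ValueError(f"removal would empty taxon {taxon!r} entirely")
    new_seqs = []
    for lab, seq in zip(aln.labels, aln.sequences):
        if lab in removals:
            chars = list(seq)
            for g in set(removals[lab]):
                a, b = part.interval(g)
                chars[a - 1 : b] = "?" * (b - a + 1)
            seq = "".join(chars)
        new_seqs.append(seq)
    return Alignment(aln.labels, tuple(new_seqs))
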