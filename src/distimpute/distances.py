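"""Pairwise evolutionary distances from multiple sequence alignments.

Two estimators are provided, both computed with *pairwise deletion*: for
each pair of taxa only the alignment columns where both sequences carry an
unambiguous character are used.

TN93
    The Tamura–Nei (1993) closed-form nucleotide distance.  The model
    distinguishes the two transition classes (A<->G among purines, C<->T
    among pyrimidines) from transversions, with unequal base frequencies.

LogDet
    The log-determinant (paralinear) distance ``d = -ln det(F)``, where F is
    the K x K divergence matrix of site-pattern proportions (K = 4 for
    nucleotides, K = 20 for amino acids).  Robust to compositional
    heterogeneity across the tree.

Either estimator can be undefined for a pair — no shared sites, a singular
divergence matrix, or a logarithm-domain violation at saturation.  Such
pairs are *missing*, represented as ``None`` here and as masked entries in
the matrix returned by :func:`alignment_to_matrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import MaskedDistanceMatrix

__all__ = [
    "Alignment",
    "shared_sites",
    "logdet_distance",
    "tn93_distance",
    "alignment_to_matrix",
]

_DNA = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"
_DNA_CODE = {c: i for i, c in enumerate(_DNA)}
_AA_CODE = {c: i for i, c in enumerate(_AA)}

# nucleotide indices
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass(frozen=True)
class Alignment:
    """Equal-length labeled sequences.

    Characters outside the unambiguous alphabet (gap ``-``, unknown ``?``,
    IUPAC ambiguity codes such as R/Y/N) are treated as missing data and are
    removed pairwise when distances are computed.
    """

    labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.sequences and len(self.sequences[0]) < 1:
            raise ValueError("alignment length must be >= 1")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(
            self, "sequences", tuple(s.upper() for s in self.sequences)
        )

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no FASTA records")
        return cls(
            tuple(r.id for r in records), tuple(str(r.seq) for r in records)
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=lab, description="")
            for lab, s in zip(self.labels, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


def _encode(seq: str, alphabet: Literal["dna", "protein"] = "dna") -> np.ndarray:
    """Map a sequence to integer codes; anything ambiguous becomes -1."""
    code = _DNA_CODE if alphabet == "dna" else _AA_CODE
    return np.array([code.get(c, -1) for c in seq.upper()], dtype=np.int64)


def shared_sites(x: str, y: str) -> np.ndarray:
    """Indices where both sequences carry an unambiguous nucleotide.

    This is the pairwise-deletion site set: columns where either sequence
    has a gap, ``?`` or an ambiguity code are discarded for that pair only.
    """
    if len(x) != len(y):
        raise ValueError("sequences have different lengths")
    ex, ey = _encode(x), _encode(y)
    return np.flatnonzero((ex >= 0) & (ey >= 0))


def _divergence_matrix(
    ex: np.ndarray, ey: np.ndarray, k: int
) -> tuple[np.ndarray, int]:
    """Site-pattern proportion matrix F and the shared-site count.

    ``F[i, j]`` is the proportion of shared sites with state i in x and
    state j in y; entries sum to 1 when any site is shared.
    """
    valid = (ex >= 0) & (ey >= 0)
    s = int(valid.sum())
    if s == 0:
        return np.zeros((k, k)), 0
    counts = np.bincount(ex[valid] * k + ey[valid], minlength=k * k)
    return counts.reshape(k, k) / s, s


def logdet_distance(
    x: str, y: str, alphabet: Literal["dna", "protein"] = "dna"
) -> float | None:
    """LogDet distance ``-ln det(F_xy)``, or ``None`` when undefined.

    Undefined when the pair shares no sites or det(F) <= 0 (e.g. a state
    absent from both sequences makes F singular).
    """
    if len(x) != len(y):
        raise ValueError("sequences have different lengths")
    k = 4 if alphabet == "dna" else 20
    if y < x:  # det(F^T) = det(F); canonical order keeps symmetry bit-exact
        x, y = y, x
    f, s = _divergence_matrix(_encode(x, alphabet), _encode(y, alphabet), k)
    if s == 0:
        return None
    det = float(np.linalg.det(f))
    if det <= 0.0:
        return None
    return -math.log(det)


def tn93_distance(x: str, y: str) -> float | None:
    """Tamura–Nei (1993) nucleotide distance, or ``None`` when undefined.

    Base frequencies are pooled over both sequences at the shared sites, so
    the estimate is symmetric in its arguments.  With P1, P2 the observed
    A<->G and C<->T transition proportions, Q the transversion proportion,
    and pi_R = pi_A + pi_G, pi_Y = pi_C + pi_T::

        d = -k1*ln(1 - pi_R*P1/(2 pi_A pi_G) - Q/(2 pi_R))
            -k2*ln(1 - pi_Y*P2/(2 pi_T pi_C) - Q/(2 pi_Y))
            -k3*ln(1 - Q/(2 pi_R pi_Y))

    with k1 = 2 pi_A pi_G / pi_R, k2 = 2 pi_T pi_C / pi_Y and
    k3 = 2 (pi_R pi_Y - pi_A pi_G pi_Y / pi_R - pi_T pi_C pi_R / pi_Y).

    Returns ``None`` when no sites are shared, a required frequency product
    is zero, or a log argument is non-positive (saturation).
    """
    if len(x) != len(y):
        raise ValueError("sequences have different lengths")
    f, s = _divergence_matrix(_encode(x), _encode(y), 4)
    if s == 0:
        return None
    return _tn93_from_f(f)


def alignment_to_matrix(
    aln: Alignment,
    model: Literal["tn93", "logdet"] = "tn93",
    alphabet: Literal["dna", "protein"] = "dna",
    min_shared: int = 1,
) -> MaskedDistanceMatrix:
    """Distance matrix for all taxon pairs; undefined pairs become masked.

    Each unordered pair is evaluated once.  A pair is masked when it shares
    fewer than ``min_shared`` sites or when the chosen estimator is
    undefined for it.  Estimates are floored at zero (finite-sample noise
    can produce marginally negative values).
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if model not in ("tn93", "logdet"):
        raise ValueError(f"unknown model {model!r}")
    if model == "tn93" and alphabet != "dna":
        raise ValueError("TN93 is defined for nucleotide sequences only")
    n = aln.n_taxa
    k = 4 if alphabet == "dna" else 20
    enc = [_encode(s, alphabet) for s in aln.sequences]
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(1, n):
        for j in range(i):
            f, s = _divergence_matrix(enc[i], enc[j], k)
            d: float | None
            if s < min_shared or s == 0:
                d = None
            elif model == "logdet":
                det = float(np.linalg.det(f))
                d = -math.log(det) if det > 0 else None
            else:
                d = _tn93_from_f(f)
            if d is None:
                mask[i, j] = mask[j, i] = True
            else:
                values[i, j] = values[j, i] = max(0.0, d)
    return MaskedDistanceMatrix(aln.labels, values, mask)


def _tn93_from_f(f: np.ndarray) -> float | None:
    """TN93 distance from a precomputed 4x4 divergence matrix."""
    pi = (f.sum(axis=1) + f.sum(axis=0)) / 2.0
    pa, pc, pg, pt = pi[_A], pi[_C], pi[_G], pi[_T]
    pr, py = pa + pg, pc + pt
    p1 = f[_A, _G] + f[_G, _A]
    p2 = f[_C, _T] + f[_T, _C]
    q = (
        f[_A, _C] + f[_C, _A] + f[_A, _T] + f[_T, _A]
        + f[_G, _C] + f[_C, _G] + f[_G, _T] + f[_T, _G]
    )
    if pa * pg == 0 or pt * pc == 0 or pr * py == 0:
        return None
    arg1 = 1.0 - pr * p1 / (2.0 * pa * pg) - q / (2.0 * pr)
    arg2 = 1.0 - py * p2 / (2.0 * pt * pc) - q / (2.0 * py)
    arg3 = 1.0 - q / (2.0 * pr * py)
    if arg1 <= 0.0 or arg2 <= 0.0 or arg3 <= 0.0:
        return None
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pt * pc / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    return -k1 * math.log(arg1) - k2 * math.log(arg2) - k3 * math.log(arg3)
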