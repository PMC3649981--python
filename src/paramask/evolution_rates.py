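"""Protein divergence (Ka) between codon-aligned sequences, Li's 1993 way.

Each codon position is classified by degeneracy under the standard
genetic code: fourfold degenerate when all three possible nucleotide
changes are synonymous, nondegenerate (zerofold) when none is, and
twofold otherwise. This generic rule reproduces the protocol's special
cases: the third position of isoleucine codons (two of three changes
synonymous) counts as twofold, as do the first positions of the
CTA/CTG/TTA/TTG leucine and CGA/CGG/AGA/AGG arginine codons.

Site counts L0, L2, L4 are averaged over the two sequences; each
observed difference is split as a transition or transversion and
assigned half-weight to the class of the site in each sequence. The
per-class proportions P_i (transitions) and Q_i (transversions) are
corrected for multiple hits with Kimura's two-parameter model:

    A_i = -1/2 ln(1 - 2P_i - Q_i) + 1/4 ln(1 - 2Q_i)
    B_i = -1/2 ln(1 - 2Q_i)

and the nonsynonymous distance is

    Ka = [L0 (A0 + B0) + L2 B2] / (L0 + L2)

(at twofold sites transitions are synonymous, so only the transversional
component B2 contributes). When a logarithm argument is non-positive the
estimate is saturated and Ka is undefined.

Ka_pair is this distance between the two members of a duplicate pair;
Ka_CeCb is the mean of the distances between each member and its
C. briggsae ortholog, the pair-level rate of protein evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "SiteCounts",
    "KaEstimate",
    "SaturationError",
    "DEGENERACY",
    "classify_site_degeneracy",
    "count_site_classes_and_differences",
    "k2p_components",
    "ka_li93",
    "ka_pair",
    "ka_cecb",
    "read_codon_alignment_fasta",
]

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_CODE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)


def _build_degeneracy_table() -> dict[str, tuple[int, int, int]]:
    table: dict[str, tuple[int, int, int]] = {}
    for codon, aa in _CODE.forward_table.items():
        classes = []
        for pos in range(3):
            syn = 0
            for base in _BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                # changes to stop codons are nonsynonymous
                if alt not in _STOPS and _CODE.forward_table[alt] == aa:
                    syn += 1
            if syn == 3:
                classes.append(4)
            elif syn == 0:
                classes.append(0)
            else:
                classes.append(2)
        table[codon] = tuple(classes)
    return table


#: degeneracy class (0, 2 or 4) of each position of each sense codon
DEGENERACY: dict[str, tuple[int, int, int]] = _build_degeneracy_table()


class SaturationError(ValueError):
    """Observed divergence too high for the multiple-hit correction."""


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of aligned coding sequences, frame anchored at position 0."""

    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        s1 = self.seq1.upper()
        s2 = self.seq2.upper()
        object.__setattr__(self, "seq1", s1)
        object.__setattr__(self, "seq2", s2)
        if len(s1) != len(s2):
            raise ValueError("aligned sequences have unequal lengths")
        if len(s1) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")

    def comparable_codons(self) -> list[tuple[str, str]]:
        """Codon pairs with both codons ungapped, unambiguous sense codons.

        Gapped or ambiguous codon columns are dropped pairwise; stop
        codons are likewise excluded from the comparison.
        """
        out = []
        for i in range(0, len(self.seq1), 3):
            c1, c2 = self.seq1[i : i + 3], self.seq2[i : i + 3]
            if c1 in DEGENERACY and c2 in DEGENERACY:
                out.append((c1, c2))
        return out


@dataclass
class SiteCounts:
    """Per-degeneracy-class site counts and difference proportions."""

    L: dict[int, float]
    P: dict[int, float]
    Q: dict[int, float]
    n_codons_used: int = 0


@dataclass(frozen=True)
class KaEstimate:
    ka: float | None
    n_codons_used: int
    saturated: bool


def classify_site_degeneracy(codon: str, position: int) -> int:
    """Degeneracy class (0, 2 or 4) of one position of a sense codon."""
    codon = codon.upper()
    if codon not in DEGENERACY:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    if position not in (0, 1, 2):
        raise ValueError("position must be 0, 1 or 2")
    return DEGENERACY[codon][position]


def count_site_classes_and_differences(aln: CodonAlignment) -> SiteCounts:
    """Li-1993 site classification and difference counts for an alignment.

    L_i is the mean over the two sequences of the number of class-i
    sites. A differing position contributes one transition or one
    transversion, half to the class of the site in each sequence (the
    halves coincide when both sequences agree on the class).
    """
    codons = aln.comparable_codons()
    if not codons:
        raise ValueError("no comparable codons in alignment")
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    T = {0: 0.0, 2: 0.0, 4: 0.0}  # transitions
    V = {0: 0.0, 2: 0.0, 4: 0.0}  # transversions
    for c1, c2 in codons:
        d1, d2 = DEGENERACY[c1], DEGENERACY[c2]
        for pos in range(3):
            k1, k2 = d1[pos], d2[pos]
            L[k1] += 0.5
            L[k2] += 0.5
            b1, b2 = c1[pos], c2[pos]
            if b1 != b2:
                bucket = T if (b1, b2) in _TRANSITIONS else V
                bucket[k1] += 0.5
                bucket[k2] += 0.5
    P = {k: (T[k] / L[k] if L[k] > 0 else 0.0) for k in L}
    Q = {k: (V[k] / L[k] if L[k] > 0 else 0.0) for k in L}
    return SiteCounts(L=L, P=P, Q=Q, n_codons_used=len(codons))


def k2p_components(P: float, Q: float) -> tuple[float, float]:
    """Kimura two-parameter transitional (A) and transversional (B)
    distance components from observed proportions; raises
    ``SaturationError`` when a log argument is non-positive."""
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(f"saturated: P={P:.4f}, Q={Q:.4f}")
    A = -0.5 * math.log(a1) + 0.25 * math.log(a2)
    B = -0.5 * math.log(a2)
    return A, B


def ka_li93(counts: SiteCounts) -> KaEstimate:
    """Nonsynonymous distance Ka = [L0(A0+B0) + L2 B2] / (L0 + L2)."""
    L0, L2 = counts.L[0], counts.L[2]
    if L0 + L2 <= 0:
        return KaEstimate(ka=None, n_codons_used=counts.n_codons_used, saturated=False)
    try:
        A0, B0 = k2p_components(counts.P[0], counts.Q[0])
        _, B2 = k2p_components(counts.P[2], counts.Q[2])
    except SaturationError:
        return KaEstimate(ka=None, n_codons_used=counts.n_codons_used, saturated=True)
    ka = (L0 * (A0 + B0) + L2 * B2) / (L0 + L2)
    return KaEstimate(
        ka=max(ka, 0.0), n_codons_used=counts.n_codons_used, saturated=False
    )


def ka_pair(aln: CodonAlignment) -> KaEstimate:
    """Ka between the two members of a duplicate pair."""
    return ka_li93(count_site_classes_and_differences(aln))


def ka_cecb(
    ortholog_alignment_1: CodonAlignment | None,
    ortholog_alignment_2: CodonAlignment | None,
) -> float:
    """Mean Ka across the two ortholog comparisons of a duplicate pair."""
    if ortholog_alignment_1 is None or ortholog_alignment_2 is None:
        raise ValueError("both ortholog alignments are required")
    estimates = [ka_pair(ortholog_alignment_1), ka_pair(ortholog_alignment_2)]
    if any(e.saturated or e.ka is None for e in estimates):
        raise SaturationError("an ortholog comparison is saturated or undefined")
    return (estimates[0].ka + estimates[1].ka) / 2.0


def read_codon_alignment_fasta(path) -> CodonAlignment:
    """Read a paired codon alignment (exactly two FASTA records)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned sequences")
    return CodonAlignment(seq1=str(records[0].seq), seq2=str(records[1].seq))
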