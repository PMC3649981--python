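"""Duplicate-pair discovery from all-vs-all protein similarity searches.

Paralog pairs are defined as reciprocal best hits (RBH) in an all-vs-all
protein BLAST: two genes that are each other's most significant non-self
match, with the match spanning a minimum fraction of both proteins. Pairs
are then screened for the presence of a close third paralog using the
*duplicate isolation value*: the log-scale similarity of the pair to their
closest shared third hit, relative to the log-scale similarity within the
pair. An isolation value near 0 means the pair is an isolated two-member
family; near 1 means a third paralog is almost as close as the pair itself.

RNAi reagent specificity is modelled separately: a probe's primary targets
are genes matched at >=95% nucleotide identity over >=100 bp, secondary
targets at >=80% identity over >=200 bp. A pair is uniquely targetable
when each member has a probe with exactly one primary target and no
secondary targets.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "AlignmentHit",
    "DuplicatePair",
    "ProbeTargetSegment",
    "protein_lengths_from_fasta",
    "read_hit_table",
    "reciprocal_best_pairs",
    "classify_single_copy",
    "isolation_value",
    "compute_isolation",
    "filter_isolated_pairs",
    "probe_target_classes",
    "uniquely_targetable_pairs",
]

#: e-values of exactly zero (underflow in the search engine) are clamped
#: here before taking logs so isolation stays finite and reproducible.
EVALUE_FLOOR = 1e-180

#: columns of the standard 12-column tabular alignment format (outfmt 6)
BLAST6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    """A directed query->subject protein similarity record (best HSP)."""

    query_id: str
    subject_id: str
    evalue: float
    qcov: float
    scov: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")
        if not (0.0 <= self.qcov <= 1.0 and 0.0 <= self.scov <= 1.0):
            raise ValueError(
                f"coverage outside [0,1] for {self.query_id}->{self.subject_id}"
            )


@dataclass
class DuplicatePair:
    """A mutual-best paralog pair, canonically ordered gene1 < gene2."""

    gene1: str
    gene2: str
    pair_evalue: float
    isolation: float | None = None
    family_role: str = ""

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValueError("a pair must join two distinct genes")
        if self.gene1 > self.gene2:
            self.gene1, self.gene2 = self.gene2, self.gene1

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


@dataclass(frozen=True)
class ProbeTargetSegment:
    """One nucleotide-identity segment between an RNAi probe and a gene."""

    probe_id: str
    gene_id: str
    identity: float
    span_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity outside [0,1] for probe {self.probe_id}")
        if self.span_bp < 1:
            raise ValueError(f"non-positive span for probe {self.probe_id}")


def protein_lengths_from_fasta(path) -> dict[str, int]:
    """Read per-gene protein lengths (longest-isoform FASTA) for coverage."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        n = len(str(record.seq).replace("-", "").replace("*", ""))
        prev = lengths.get(record.id)
        if prev is None or n > prev:
            lengths[record.id] = n
    return lengths


def _better_hsp(a: tuple, b: tuple) -> bool:
    """True if HSP tuple a=(evalue, -bitscore) beats b."""
    return a < b


def read_hit_table(
    path, protein_lengths: Mapping[str, int]
) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file into AlignmentHit records.

    Self-hits are dropped. Multiple HSPs per directed gene pair are reduced
    to the single most significant HSP (smallest e-value, ties broken by
    larger bitscore); coverage is that HSP's span divided by each protein's
    length. Raises ``ValueError`` naming the offending line on malformed
    rows, and ``KeyError`` naming the gene when a protein length is missing.
    """
    best: dict[tuple[str, str], tuple[float, float, int, int, int, int]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(row)}"
                )
            q, s = row[0], row[1]
            if q == s:
                continue
            try:
                evalue = float(row[10])
                bitscore = float(row[11])
                qstart, qend = int(row[6]), int(row[7])
                sstart, send = int(row[8]), int(row[9])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            key = (q, s)
            cand = (evalue, -bitscore, qstart, qend, sstart, send)
            if key not in best or _better_hsp(cand[:2], best[key][:2]):
                best[key] = cand
    hits = []
    for (q, s), (evalue, neg_bits, qstart, qend, sstart, send) in sorted(best.items()):
        for gene in (q, s):
            if gene not in protein_lengths:
                raise KeyError(f"no protein length for gene {gene!r}")
        qcov = (abs(qend - qstart) + 1) / protein_lengths[q]
        scov = (abs(send - sstart) + 1) / protein_lengths[s]
        hits.append(
            AlignmentHit(
                query_id=q,
                subject_id=s,
                evalue=evalue,
                qcov=min(qcov, 1.0),
                scov=min(scov, 1.0),
                bitscore=-neg_bits,
            )
        )
    return hits


def _best_hits(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best non-self hit per query: smallest e-value, then larger bitscore,
    then lexicographically smallest subject id (deterministic)."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        a = (h.evalue, -h.bitscore, h.subject_id)
        b = (cur.evalue, -cur.bitscore, cur.subject_id)
        if a < b:
            best[h.query_id] = h
    return best


def reciprocal_best_pairs(
    hits: Sequence[AlignmentHit],
    max_evalue: float = 1e-9,
    min_cov: float = 0.60,
) -> list[DuplicatePair]:
    """Mutual-best paralog pairs under e-value and coverage filters.

    A pair (A, B) is emitted iff B is A's best non-self hit and vice versa,
    both directed hits have ``evalue < max_evalue``, and both query and
    subject coverage are >= ``min_cov`` in both directions. The pair
    e-value is the more significant (smaller) of the two directed values.
    The mutual-best property guarantees each gene appears in at most one
    pair.
    """
    best = _best_hits(hits)
    pairs: list[DuplicatePair] = []
    for gene, hit in sorted(best.items()):
        other = hit.subject_id
        if gene >= other:
            continue  # canonical orientation; handled from the smaller id
        back = best.get(other)
        if back is None or back.subject_id != gene:
            continue
        fwd, rev = hit, back
        if fwd.evalue >= max_evalue or rev.evalue >= max_evalue:
            continue
        if min(fwd.qcov, fwd.scov, rev.qcov, rev.scov) < min_cov:
            continue
        pairs.append(
            DuplicatePair(
                gene1=gene, gene2=other, pair_evalue=min(fwd.evalue, rev.evalue)
            )
        )
    return pairs


def classify_single_copy(
    hits: Sequence[AlignmentHit],
    genes: Iterable[str],
    max_evalue: float = 0.01,
) -> set[str]:
    """Genes with no non-self match below ``max_evalue`` in either direction."""
    matched: set[str] = set()
    for h in hits:
        if h.query_id != h.subject_id and h.evalue < max_evalue:
            matched.add(h.query_id)
            matched.add(h.subject_id)
    return set(genes) - matched


def _neglog10(evalue: float) -> float:
    return -math.log10(max(evalue, EVALUE_FLOOR))


def isolation_value(
    pair: DuplicatePair,
    hits: Sequence[AlignmentHit],
    shared_hit_max_evalue: float = 0.01,
) -> float:
    """Duplicate isolation value of a pair, in [0, 1].

    Candidate shared hits are third genes matched by *both* pair members at
    e-value < ``shared_hit_max_evalue`` (either search direction; the best
    directed e-value per gene-third combination is used). Each candidate t
    is scored by max(e(g1,t), e(g2,t)) — the weaker of its two matches,
    which best reflects sequence shared between the pair members — and the
    closest shared hit minimises that score. The isolation value is

        -log10(closest shared score) / -log10(pair e-value),

    0 when no shared hit exists, clamped to [0, 1] (a third hit more
    significant than the pair hit is mathematically possible).
    """
    g1, g2 = pair.genes
    to_third: dict[str, dict[str, float]] = {g1: {}, g2: {}}
    for h in hits:
        for a, b in ((h.query_id, h.subject_id), (h.subject_id, h.query_id)):
            if a in to_third and b not in (g1, g2):
                cur = to_third[a].get(b)
                if cur is None or h.evalue < cur:
                    to_third[a][b] = h.evalue
    best_score: float | None = None
    for third, e1 in to_third[g1].items():
        e2 = to_third[g2].get(third)
        if e2 is None:
            continue
        if e1 >= shared_hit_max_evalue or e2 >= shared_hit_max_evalue:
            continue
        score = max(e1, e2)
        if best_score is None or score < best_score:
            best_score = score
    if best_score is None:
        return 0.0
    denom = _neglog10(pair.pair_evalue)
    if denom <= 0:
        # pair e-value >= 1: pair similarity carries no log signal; any
        # shared hit makes the third paralog at least as close
        return 1.0
    value = _neglog10(best_score) / denom
    return min(max(value, 0.0), 1.0)


def compute_isolation(
    pairs: Sequence[DuplicatePair],
    hits: Sequence[AlignmentHit],
    shared_hit_max_evalue: float = 0.01,
) -> list[DuplicatePair]:
    """Return copies of ``pairs`` with the isolation field filled in."""
    return [
        replace(p, isolation=isolation_value(p, hits, shared_hit_max_evalue))
        for p in pairs
    ]


def filter_isolated_pairs(
    pairs: Sequence[DuplicatePair], cutoff: float = 0.83
) -> list[DuplicatePair]:
    """Retain pairs without a close third paralog (isolation <= cutoff)."""
    out = []
    for p in pairs:
        if p.isolation is None:
            raise ValueError(f"isolation not computed for pair {p.genes}")
        if p.isolation <= cutoff:
            out.append(p)
    return out


def probe_target_classes(
    segments: Sequence[ProbeTargetSegment],
    primary_identity: float = 0.95,
    primary_span: int = 100,
    secondary_identity: float = 0.80,
    secondary_span: int = 200,
) -> dict[str, dict[str, str]]:
    """Per-probe map of gene -> {'primary','secondary','none'}.

    A gene is a primary target of a probe if any segment reaches
    >=95% identity over >=100 bp; otherwise a secondary target if any
    segment reaches >=80% identity over >=200 bp; otherwise 'none'.
    """
    by_probe: dict[str, dict[str, list[ProbeTargetSegment]]] = {}
    for seg in segments:
        by_probe.setdefault(seg.probe_id, {}).setdefault(seg.gene_id, []).append(seg)
    out: dict[str, dict[str, str]] = {}
    for probe, gene_segs in by_probe.items():
        out[probe] = {}
        for gene, segs in gene_segs.items():
            if any(
                s.identity >= primary_identity and s.span_bp >= primary_span
                for s in segs
            ):
                out[probe][gene] = "primary"
            elif any(
                s.identity >= secondary_identity and s.span_bp >= secondary_span
                for s in segs
            ):
                out[probe][gene] = "secondary"
            else:
                out[probe][gene] = "none"
    return out


def _clean_probes_for(gene: str, probe_classes: Mapping[str, Mapping[str, str]]):
    """Probes that target ``gene`` as their only primary target with no
    secondary targets anywhere."""
    for probe, targets in probe_classes.items():
        primaries = [g for g, c in targets.items() if c == "primary"]
        secondaries = [g for g, c in targets.items() if c == "secondary"]
        if primaries == [gene] and not secondaries:
            yield probe


def uniquely_targetable_pairs(
    pairs: Sequence[DuplicatePair],
    probe_classes: Mapping[str, Mapping[str, str]],
) -> list[DuplicatePair]:
    """Pairs where each member has at least one uniquely-targeting probe."""
    return [
        p
        for p in pairs
        if all(any(True for _ in _clean_probes_for(g, probe_classes)) for g in p.genes)
    ]


def write_pairs_tsv(pairs: Sequence[DuplicatePair], path, cutoff: float = 0.83) -> None:
    """Write a pairs table (gene1, gene2, pair_evalue, isolation, retained)."""
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tpair_evalue\tisolation\tretained\n")
        for p in pairs:
            iso = "" if p.isolation is None else f"{p.isolation:.4f}"
            retained = (
                "" if p.isolation is None else str(int(p.isolation <= cutoff))
            )
            fh.write(f"{p.gene1}\t{p.gene2}\t{p.pair_evalue:.3g}\t{iso}\t{retained}\n")
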