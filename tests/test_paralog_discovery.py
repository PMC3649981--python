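"""Reciprocal-best-hit discovery, isolation values and probe specificity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paramask.paralog_discovery import (
    AlignmentHit,
    DuplicatePair,
    ProbeTargetSegment,
    classify_single_copy,
    compute_isolation,
    filter_isolated_pairs,
    isolation_value,
    probe_target_classes,
    read_hit_table,
    reciprocal_best_pairs,
    uniquely_targetable_pairs,
)


def hit(q, s, evalue, cov=0.9, bits=200.0):
    return AlignmentHit(q, s, evalue, cov, cov, bits)


# ---------------------------------------------------------------------------
# hit-table parsing


def write_rows(tmp_path, rows, name="hits.tsv"):
    path = tmp_path / name
    path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
    return path


def blast_row(q, s, evalue, qstart=1, qend=90, sstart=1, send=90, bits=180.0):
    return [q, s, 95.0, qend - qstart + 1, 2, 0, qstart, qend, sstart, send,
            evalue, bits]


def test_empty_hit_table(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert read_hit_table(path, {}) == []


def test_single_row_transcription(tmp_path):
    path = write_rows(tmp_path, [blast_row("A", "B", 1e-50)])
    hits = read_hit_table(path, {"A": 100, "B": 100})
    assert len(hits) == 1
    h = hits[0]
    assert (h.query_id, h.subject_id) == ("A", "B")
    assert h.evalue == 1e-50
    assert h.qcov == pytest.approx(0.9)
    assert h.scov == pytest.approx(0.9)


def test_self_hits_dropped_against_row_count(tmp_path):
    rows = [
        blast_row("A", "A", 0.0),
        blast_row("A", "B", 1e-30),
        blast_row("B", "A", 1e-30),
        blast_row("B", "B", 0.0),
        blast_row("A", "C", 1e-5),
    ]
    path = write_rows(tmp_path, rows)
    hits = read_hit_table(path, {"A": 100, "B": 100, "C": 100})
    # brute force: count distinct non-self directed pairs in the fixture
    expected = {(r[0], r[1]) for r in rows if r[0] != r[1]}
    assert {(h.query_id, h.subject_id) for h in hits} == expected


def test_best_hsp_kept_per_directed_pair(tmp_path):
    rows = [
        blast_row("A", "B", 1e-10, qend=50, bits=90.0),
        blast_row("A", "B", 1e-40, qend=95, bits=220.0),
    ]
    hits = read_hit_table(write_rows(tmp_path, rows), {"A": 100, "B": 100})
    assert len(hits) == 1
    assert hits[0].evalue == 1e-40
    assert hits[0].qcov == pytest.approx(0.95)


def test_malformed_row_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("A\tB\tnot-enough-columns\n")
    with pytest.raises(ValueError, match="line 1"):
        read_hit_table(path, {"A": 100, "B": 100})


def test_missing_protein_length_names_gene(tmp_path):
    path = write_rows(tmp_path, [blast_row("A", "B", 1e-50)])
    with pytest.raises(KeyError, match="B"):
        read_hit_table(path, {"A": 100})


# ---------------------------------------------------------------------------
# reciprocal best hits


def test_mutual_pair_emitted():
    hits = [hit("A", "B", 1e-50), hit("B", "A", 1e-48)]
    pairs = reciprocal_best_pairs(hits)
    assert len(pairs) == 1
    assert pairs[0].genes == ("A", "B")
    assert pairs[0].pair_evalue == 1e-50  # more significant of the two


def test_reciprocity_violation_blocks_pair():
    hits = [
        hit("A", "B", 1e-50),
        hit("B", "C", 1e-60),
        hit("B", "A", 1e-40),
        hit("C", "B", 1e-60),
    ]
    pairs = reciprocal_best_pairs(hits)
    assert all("A" not in p.genes for p in pairs)
    assert [p.genes for p in pairs] == [("B", "C")]


def test_coverage_and_evalue_filters():
    assert reciprocal_best_pairs(
        [hit("A", "B", 1e-50, cov=0.5), hit("B", "A", 1e-50, cov=0.9)]
    ) == []
    assert reciprocal_best_pairs(
        [hit("A", "B", 1e-8), hit("B", "A", 1e-8)]
    ) == []


def _random_hit_table(rng, n_genes):
    genes = [f"g{i}" for i in range(n_genes)]
    hits = []
    for q in genes:
        for s in genes:
            if q == s or rng.random() < 0.5:
                continue
            hits.append(
                hit(
                    q,
                    s,
                    10.0 ** rng.uniform(-80, -3),
                    cov=rng.uniform(0.3, 1.0),
                    bits=rng.uniform(50, 300),
                )
            )
    return genes, hits


def _exhaustive_mutual_best(genes, hits, max_evalue=1e-9, min_cov=0.60):
    """Independent oracle: check the mutual-best predicate for every
    unordered gene pair directly."""
    directed = {(h.query_id, h.subject_id): h for h in hits}

    def best_of(g):
        cands = [h for h in hits if h.query_id == g]
        if not cands:
            return None
        return min(cands, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))

    out = set()
    for a in genes:
        for b in genes:
            if a >= b:
                continue
            ba, bb = best_of(a), best_of(b)
            if ba is None or bb is None:
                continue
            if ba.subject_id != b or bb.subject_id != a:
                continue
            fwd, rev = directed[(a, b)], directed[(b, a)]
            if fwd.evalue >= max_evalue or rev.evalue >= max_evalue:
                continue
            if min(fwd.qcov, fwd.scov, rev.qcov, rev.scov) < min_cov:
                continue
            out.add((a, b))
    return out


@pytest.mark.parametrize("seed", range(8))
def test_rbh_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    genes, hits = _random_hit_table(rng, int(rng.integers(4, 13)))
    got = {p.genes for p in reciprocal_best_pairs(hits)}
    assert got == _exhaustive_mutual_best(genes, hits)


@pytest.mark.parametrize("seed", range(4))
def test_no_gene_in_two_pairs(seed):
    rng = np.random.default_rng(100 + seed)
    _, hits = _random_hit_table(rng, 12)
    seen = []
    for p in reciprocal_best_pairs(hits):
        seen.extend(p.genes)
    assert len(seen) == len(set(seen))


# ---------------------------------------------------------------------------
# single-copy classification


def test_single_copy_thresholds():
    genes = {"A", "B", "C", "D"}
    hits = [hit("A", "B", 0.5), hit("C", "D", 1e-3)]
    single = classify_single_copy(hits, genes)
    assert "A" in single and "B" in single  # only match is above 0.01
    assert "C" not in single and "D" not in single
    assert classify_single_copy([], {"X"}) == {"X"}


# ---------------------------------------------------------------------------
# isolation value


def pair(e=1e-100):
    return DuplicatePair("A", "B", pair_evalue=e)


def test_isolation_worked_examples():
    hits = [hit("A", "T", 1e-83), hit("B", "T", 1e-90)]
    assert isolation_value(pair(1e-100), hits) == pytest.approx(0.83)
    hits2 = [hit("A", "T", 3.5e-13), hit("B", "T", 1e-14)]
    assert isolation_value(pair(1e-15), hits2) == pytest.approx(0.830, abs=5e-4)


def test_isolation_no_shared_hit_is_zero():
    assert isolation_value(pair(), []) == 0.0
    # a third gene hit by only one member does not count
    assert isolation_value(pair(), [hit("A", "T", 1e-50)]) == 0.0
    # shared hit must clear the 0.01 candidacy threshold for both members
    assert isolation_value(pair(), [hit("A", "T", 1e-50), hit("B", "T", 0.5)]) == 0.0


def test_isolation_clamped_to_one():
    hits = [hit("A", "T", 1e-120), hit("B", "T", 1e-130)]
    assert isolation_value(pair(1e-100), hits) == 1.0


def test_isolation_uses_max_evalue_of_closest_shared_hit():
    # two shared thirds; the closest minimises max(e1, e2)
    hits = [
        hit("A", "T1", 1e-50), hit("B", "T1", 1e-20),
        hit("A", "T2", 1e-30), hit("B", "T2", 1e-30),
    ]
    v = isolation_value(pair(1e-100), hits)
    assert v == pytest.approx(30 / 100)


@settings(derandomize=True, max_examples=50)
@given(
    pair_exp=st.floats(min_value=-150, max_value=-10),
    shared_exp=st.floats(min_value=-150, max_value=-3),
)
def test_isolation_bounds_and_monotonicity(pair_exp, shared_exp):
    p = pair(10.0**pair_exp)
    hits = [hit("A", "T", 10.0**shared_exp), hit("B", "T", 10.0**shared_exp)]
    v = isolation_value(p, hits)
    assert 0.0 <= v <= 1.0
    # a more significant shared hit never decreases isolation
    closer = [hit("A", "T", 10.0 ** (shared_exp - 5)),
              hit("B", "T", 10.0 ** (shared_exp - 5))]
    assert isolation_value(p, closer) >= v


def test_filter_isolated_pairs_cutoff_inclusive():
    pairs = [
        DuplicatePair("A", "B", 1e-100, isolation=0.83),
        DuplicatePair("C", "D", 1e-100, isolation=0.84),
        DuplicatePair("E", "F", 1e-100, isolation=0.0),
    ]
    kept = filter_isolated_pairs(pairs)
    assert [p.genes for p in kept] == [("A", "B"), ("E", "F")]


def test_filter_brute_force_subset(rng):
    pairs = [
        DuplicatePair(f"a{i}", f"b{i}", 1e-50, isolation=float(x))
        for i, x in enumerate(rng.uniform(0, 1, 10))
    ]
    kept = filter_isolated_pairs(pairs, cutoff=0.5)
    assert kept == [p for p in pairs if p.isolation <= 0.5]


def test_filter_cutoff_one_is_identity():
    pairs = [
        DuplicatePair("A", "B", 1e-100, isolation=1.0),
        DuplicatePair("C", "D", 1e-100, isolation=0.0),
    ]
    assert filter_isolated_pairs(pairs, cutoff=1.0) == pairs


# ---------------------------------------------------------------------------
# probe specificity


def seg(probe, gene, identity, span):
    return ProbeTargetSegment(probe, gene, identity, span)


def test_probe_target_classes():
    classes = probe_target_classes(
        [
            seg("p1", "g1", 0.96, 120),
            seg("p1", "g2", 0.85, 250),
            seg("p1", "g3", 0.70, 500),
        ]
    )
    assert classes["p1"] == {"g1": "primary", "g2": "secondary", "g3": "none"}


def test_probe_boundary_thresholds():
    classes = probe_target_classes(
        [seg("p", "a", 0.95, 100), seg("p", "b", 0.80, 200),
         seg("p", "c", 0.95, 99), seg("p", "d", 0.80, 199)]
    )
    assert classes["p"]["a"] == "primary"
    assert classes["p"]["b"] == "secondary"
    assert classes["p"]["c"] == "none"
    assert classes["p"]["d"] == "none"


def _clean_probe_oracle(gene, probe_classes):
    for targets in probe_classes.values():
        kinds = sorted(targets.values())
        if targets.get(gene) == "primary" and "secondary" not in kinds and (
            sum(1 for v in targets.values() if v == "primary") == 1
        ):
            return True
    return False


def test_uniquely_targetable_pairs():
    pairs = [DuplicatePair("g1", "g2", 1e-50)]
    clean = probe_target_classes(
        [seg("p1", "g1", 0.99, 300), seg("p2", "g2", 0.99, 300)]
    )
    assert uniquely_targetable_pairs(pairs, clean) == pairs
    # one gene's only probe also hits its paralog at 0.85 over 300 bp
    dirty = probe_target_classes(
        [seg("p1", "g1", 0.99, 300), seg("p1", "g2", 0.85, 300),
         seg("p2", "g2", 0.99, 300)]
    )
    assert uniquely_targetable_pairs(pairs, dirty) == []


def test_uniquely_targetable_matches_brute_force(rng):
    pairs = [DuplicatePair(f"a{i}", f"b{i}", 1e-50) for i in range(8)]
    segments = []
    for i in range(8):
        for gene in (f"a{i}", f"b{i}"):
            probe = f"probe_{gene}"
            segments.append(seg(probe, gene, rng.uniform(0.9, 1.0), 150))
            if rng.random() < 0.4:  # off-target segment
                other = f"b{i}" if gene.startswith("a") else f"a{i}"
                segments.append(
                    seg(probe, other, rng.uniform(0.7, 0.95),
                        int(rng.integers(100, 400)))
                )
    classes = probe_target_classes(segments)
    got = uniquely_targetable_pairs(pairs, classes)
    expected = [
        p for p in pairs
        if all(_clean_probe_oracle(g, classes) for g in p.genes)
    ]
    assert got == expected
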