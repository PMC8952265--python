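import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutreads import iupac
from gutreads.io_formats import AlignmentHit, CodingInterval, ValidationError
from gutreads.lazaro import (Assignment, LazaroConfig, assign_read,
                             detect_prey, in_coding_region, passes_threshold,
                             reanalyze_hit, run_lazaro)
from gutreads.synthetic import (GutCommunitySpec, hits_from_truth,
                                make_reference_db, simulate_gut_reads,
                                truth_species_summary)


def make_hit(qseq, sseq, subject_id="mito_00", query_id="q1", bitscore=None,
             sstart=None, send=None):
    length = len(qseq)
    mism = sum(1 for a, b in zip(qseq, sseq)
               if a != "-" and b != "-" and a != b)
    gaps = sum(1 for a, b in zip(qseq, sseq) if a == "-" or b == "-")
    gapopen = 1 if gaps else 0
    ident = sum(1 for a, b in zip(qseq, sseq) if a != "-" and a == b)
    qlen = sum(1 for c in qseq if c != "-")
    slen = sum(1 for c in sseq if c != "-")
    if sstart is None:
        sstart, send = 1, slen
    if bitscore is None:
        bitscore = float(ident - mism - 2 * gaps)
    return AlignmentHit(query_id, subject_id, 100.0 * ident / length, length,
                        mism, gapopen, 1, qlen, sstart, send, 0.0, bitscore,
                        qseq, sseq)


# ---------------------------------------------------------------------------
# mismatch reanalysis
# ---------------------------------------------------------------------------

def brute_force_reanalysis(qseq, sseq):
    """Independent per-column classification used as the oracle."""
    false_mm = true_mm = gaps = 0
    for q, s in zip(qseq, sseq):
        if q == "-" or s == "-":
            gaps += 1
        elif q == s:
            pass
        elif iupac.expand(q) & iupac.expand(s):
            false_mm += 1
        else:
            true_mm += 1
    pid = 100.0 * (len(qseq) - gaps - true_mm) / len(qseq)
    return false_mm, true_mm, gaps, pid


@pytest.mark.parametrize("qseq,sseq,false_mm,true_mm,pident", [
    # one degenerate-code mismatch over 140 columns is credited back
    ("A" * 139 + "A", "A" * 139 + "R", 1, 0, 100.0),
    # identity over 130 columns
    ("C" * 130, "C" * 130, 0, 0, 100.0),
    # one true mismatch over 150 columns
    ("A" * 149 + "A", "A" * 149 + "C", 0, 1, 100.0 * 149 / 150),
    # degenerate-vs-degenerate with intersecting expansions is false
    ("R" + "A" * 129, "D" + "A" * 129, 1, 0, 100.0),
    # degenerate-vs-degenerate with disjoint expansions is true
    ("R" + "A" * 129, "Y" + "A" * 129, 0, 1, 100.0 * 129 / 130),
])
def test_reanalyze_examples(qseq, sseq, false_mm, true_mm, pident):
    ch = reanalyze_hit(make_hit(qseq, sseq))
    assert (ch.false_mismatches, ch.true_mismatches) == (false_mm, true_mm)
    assert ch.corrected_pident == pytest.approx(pident, abs=1e-9)
    assert brute_force_reanalysis(qseq, sseq) == (
        ch.false_mismatches, ch.true_mismatches, ch.gap_columns,
        pytest.approx(ch.corrected_pident))


def test_gap_columns_count_against_identity():
    ch = reanalyze_hit(make_hit("ACGT-ACGT" + "A" * 121,
                                "ACGTTACGT" + "A" * 121))
    assert ch.gap_columns == 1
    assert ch.corrected_pident == pytest.approx(100.0 * 129 / 130)
    assert not passes_threshold(ch, LazaroConfig())


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from("ACGTRYSWKMBDHVN-"),
                          st.sampled_from("ACGTRYSWKMBDHVN-")),
                min_size=5, max_size=60))
def test_reanalysis_matches_brute_force_and_never_lowers_identity(columns):
    cols = [(q, s) for q, s in columns if not (q == "-" and s == "-")]
    qseq = "".join(q for q, _ in cols)
    sseq = "".join(s for _, s in cols)
    if not qseq.strip("-") or not sseq.strip("-"):
        return
    hit = make_hit(qseq, sseq)
    ch = reanalyze_hit(hit)
    f, t, g, pid = brute_force_reanalysis(qseq, sseq)
    assert (ch.false_mismatches, ch.true_mismatches, ch.gap_columns) == (f, t, g)
    assert ch.corrected_pident == pytest.approx(pid)
    assert ch.false_mismatches + ch.true_mismatches == hit.mismatch
    assert ch.corrected_pident >= hit.pident - 1e-9
    if not (set(qseq) | set(sseq)) & iupac.DEGENERATE:
        assert ch.corrected_pident == pytest.approx(hit.pident, abs=0.01)
    assert (ch.corrected_pident == 100.0) == (t == 0 and g == 0)


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,mismatched,expected", [
    (130, False, True),    # at both boundaries
    (129, False, False),   # one base short
    (150, True, False),    # 99.33% identity fails the 100% default
])
def test_overlap_identity_threshold(length, mismatched, expected):
    qseq = "A" * length
    sseq = ("C" + "A" * (length - 1)) if mismatched else qseq
    ch = reanalyze_hit(make_hit(qseq, sseq))
    assert passes_threshold(ch, LazaroConfig()) is expected


# ---------------------------------------------------------------------------
# best-hit assignment
# ---------------------------------------------------------------------------

def test_assign_single_passing_hit(small_db, default_cfg):
    ch = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01"))
    a = assign_read([ch], small_db, default_cfg)
    assert a.status == "assigned" and a.species == "Species_01"


def test_assign_tie_across_species_is_ambiguous(small_db, default_cfg):
    h1 = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01"))
    h2 = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_02"))
    assert assign_read([h1, h2], small_db, default_cfg).status == "ambiguous"


def test_assign_tie_within_one_species_is_assigned(small_db, default_cfg):
    h1 = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01"))
    h2 = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01"))
    a = assign_read([h1, h2], small_db, default_cfg)
    assert a.status == "assigned" and a.species == "Species_01"


def test_assign_all_below_threshold_is_unassigned(small_db, default_cfg):
    ch = reanalyze_hit(make_hit("A" * 100, "A" * 100, subject_id="mito_01"))
    assert assign_read([ch], small_db, default_cfg).status == "unassigned"


def test_assign_unknown_subject_raises(small_db, default_cfg):
    ch = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_99"))
    with pytest.raises(ValidationError, match="taxonomy"):
        assign_read([ch], small_db, default_cfg)


def test_threshold_then_rank_equals_rank_then_threshold(small_db, default_cfg):
    """Filtering to passing hits before ranking gives the same assignment as
    ranking everything first and thresholding the winners (the rank keys are
    the thresholded quantities, so the order of the two steps is immaterial)."""
    from gutreads.lazaro import _rank_key

    rng = np.random.default_rng(3)
    for _ in range(40):
        hits = []
        for _k in range(int(rng.integers(1, 6))):
            length = int(rng.integers(120, 150))
            n_mm = int(rng.integers(0, 3))
            qseq = "A" * length
            sseq = "C" * n_mm + "A" * (length - n_mm)
            sid = f"mito_{int(rng.integers(0, 4)):02d}"
            hits.append(reanalyze_hit(make_hit(
                qseq, sseq, subject_id=sid,
                bitscore=float(rng.integers(50, 300)))))
        a1 = assign_read(hits, small_db, default_cfg)

        # alternative order: rank all, walk down ranks, threshold at the top
        ranked = sorted(hits, key=_rank_key)
        alt_status, alt_species = "unassigned", None
        for ch in ranked:
            if passes_threshold(ch, default_cfg):
                key = _rank_key(ch)
                top = [c for c in ranked if _rank_key(c) == key
                       and passes_threshold(c, default_cfg)]
                species = {small_db.species_of(c.subject_id) for c in top}
                if len(species) > 1:
                    alt_status = "ambiguous"
                else:
                    alt_status, alt_species = "assigned", species.pop()
                break
        assert (a1.status, a1.species) == (alt_status, alt_species)


# ---------------------------------------------------------------------------
# coding-region filter
# ---------------------------------------------------------------------------

def _db_with_coding(small_db, intervals):
    db = dataclasses.replace(small_db)
    db.coding = dict(small_db.coding)
    db.coding["mito_01"] = intervals
    return db


def test_alignment_fully_inside_cds_passes(small_db, default_cfg):
    db = _db_with_coding(small_db,
                         [CodingInterval("mito_01", 100, 1000, "CDS", "+")])
    ch = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01",
                                sstart=200, send=339))
    assert in_coding_region(ch, db, default_cfg)


def test_partial_overlap_below_fraction_fails(small_db, default_cfg):
    # 30 of 140 aligned bases inside the CDS: fraction 0.214 < 0.5
    db = _db_with_coding(small_db,
                         [CodingInterval("mito_01", 1, 229, "CDS", "+")])
    ch = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01",
                                sstart=200, send=339))
    assert not in_coding_region(ch, db, default_cfg)
    # interval-arithmetic oracle
    assert min(339, 229) - max(200, 1) + 1 == 30


def test_minus_strand_hit_counts_against_plus_strand_cds(small_db, default_cfg):
    db = _db_with_coding(small_db,
                         [CodingInterval("mito_01", 100, 1000, "CDS", "+")])
    ch = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01",
                                sstart=339, send=200))
    assert in_coding_region(ch, db, default_cfg)


def test_missing_annotation_fail_or_pass(small_db):
    db = _db_with_coding(small_db, [])
    ch = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id="mito_01",
                                sstart=200, send=339))
    assert not in_coding_region(ch, db, LazaroConfig())
    assert in_coding_region(ch, db, LazaroConfig(missing_annotation="pass"))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _assigned(species, n, db, start=200):
    out = []
    sid = {t.species: s for s, t in db.taxonomy.items()}[species]
    for i in range(n):
        ch = reanalyze_hit(make_hit("A" * 140, "A" * 140, subject_id=sid,
                                    query_id=f"{species}_{i}",
                                    sstart=start, send=start + 139))
        out.append(Assignment(f"{species}_{i}", "assigned", species, ch))
    return out


def test_singleton_species_removed(small_db, default_cfg):
    assignments = (_assigned("Species_01", 16, small_db)
                   + _assigned("Species_02", 2, small_db)
                   + _assigned("Species_03", 1, small_db))
    res = detect_prey(assignments, default_cfg, small_db)
    got = dict(zip(res.prey["species"], res.prey["read_count"]))
    assert got == {"Species_01": 16, "Species_02": 2}
    assert set(res.audit.loc[res.audit["status"] == "singleton",
                             "species"]) == {"Species_03"}


def test_predator_reported_separately_not_as_prey(small_db, default_cfg):
    assignments = (_assigned("Species_00", 40, small_db)
                   + _assigned("Species_01", 3, small_db))
    res = detect_prey(assignments, default_cfg, small_db)
    assert res.predator_reads == 40
    assert list(res.prey["species"]) == ["Species_01"]
    pred_rows = res.detections[res.detections["is_predator"]]
    assert list(pred_rows["read_count"]) == [40]


def test_empty_assignments_give_empty_table(small_db, default_cfg):
    res = detect_prey([], default_cfg, small_db)
    assert res.detections.empty


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_run_lazaro_detects_exactly_truth_qualified_species(
        small_db, gut_sample, default_cfg):
    reads, truth = gut_sample
    hits = hits_from_truth(reads, truth, small_db)
    res = run_lazaro(hits, small_db, default_cfg)
    summary = truth_species_summary(truth, small_db, default_cfg)
    expected = set(summary.loc[summary["expected_detected"], "species"])
    expected -= {default_cfg.predator_species}
    assert set(res.prey["species"]) == expected
    # counts equal the truth's qualifying-read counts
    by_truth = dict(zip(summary["species"], summary["qualifying_reads"]))
    for sp, n in zip(res.prey["species"], res.prey["read_count"]):
        assert n == by_truth[sp]


def test_run_lazaro_min_overlap_above_read_length_empties_table(
        small_db, gut_sample):
    reads, truth = gut_sample
    hits = hits_from_truth(reads, truth, small_db)
    cfg = LazaroConfig(min_overlap=151, predator_species="Species_00")
    res = run_lazaro(hits, small_db, cfg)
    assert res.detections.empty


def test_run_lazaro_deterministic(small_db, gut_sample, default_cfg, tmp_path):
    from gutreads.io_formats import write_detection_csv
    reads, truth = gut_sample
    hits = hits_from_truth(reads, truth, small_db)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_detection_csv(run_lazaro(hits, small_db, default_cfg).detections, p1)
    write_detection_csv(run_lazaro(hits, small_db, default_cfg).detections, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_audit_log_accounts_for_every_read(small_db, gut_sample, default_cfg):
    reads, truth = gut_sample
    hits = hits_from_truth(reads, truth, small_db)
    res = run_lazaro(hits, small_db, default_cfg)
    assert len(res.audit) == truth["read_id"].nunique()
    assert set(res.audit["status"]) <= {"counted", "unassigned", "ambiguous",
                                        "non_coding", "singleton"}


def test_tightening_any_filter_is_monotone(small_db, gut_sample, default_cfg):
    """Raising any threshold never adds a detection or increases a count."""
    reads, truth = gut_sample
    hits = hits_from_truth(reads, truth, small_db)
    base = run_lazaro(hits, small_db, default_cfg)
    base_counts = dict(zip(base.detections["species"],
                           base.detections["read_count"]))
    tighter = [
        dataclasses.replace(default_cfg, min_overlap=140),
        dataclasses.replace(default_cfg, min_reads_per_species=5),
        dataclasses.replace(default_cfg, coding_overlap_fraction=0.9),
        dataclasses.replace(default_cfg, min_identity=100.0,
                            min_overlap=135, min_reads_per_species=3),
    ]
    for cfg in tighter:
        res = run_lazaro(hits, small_db, cfg)
        got = dict(zip(res.detections["species"], res.detections["read_count"]))
        assert set(got) <= set(base_counts)
        for sp, n in got.items():
            assert n <= base_counts[sp]
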