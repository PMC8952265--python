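import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutreads import iupac
from gutreads.io_formats import read_fasta
from gutreads.synthetic import (GutCommunitySpec, MeltTransition,
                                hits_from_truth, make_reference_db, melt_grid,
                                melt_fluorescence, oracle_align,
                                qpcr_fluorescence, simulate_gut_reads,
                                simulate_melt, simulate_qpcr,
                                write_reference_db)


# ---------------------------------------------------------------------------
# reference database generator
# ---------------------------------------------------------------------------

def test_reference_db_schema_and_determinism(tmp_path):
    db1 = make_reference_db(seed=1, n_species=8, genome_len=2000)
    db2 = make_reference_db(seed=1, n_species=8, genome_len=2000)
    assert len(db1.records) == 8
    assert [r.sequence for r in db1.records] == [r.sequence for r in db2.records]
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_reference_db(db1, d1)
    write_reference_db(db2, d2)
    for name in ("references.fasta", "references.gff3", "taxonomy.csv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    # written files re-validate through the io layer
    recs = read_fasta(d1 / "references.fasta")
    assert len(recs) == 8


def test_reference_db_coding_fraction_zero_gives_no_annotation():
    db = make_reference_db(seed=1, n_species=2, genome_len=2000,
                           coding_fraction=0.0)
    assert all(len(v) == 0 for v in db.coding.values())


def test_reference_db_coding_fraction_is_respected():
    db = make_reference_db(seed=3, n_species=3, genome_len=16000,
                           coding_fraction=0.9)
    for sid, ivs in db.coding.items():
        covered = sum(iv.end - iv.start + 1 for iv in ivs)
        assert covered == pytest.approx(0.9 * 16000, rel=0.02)


def test_reference_sequences_are_dissimilar():
    db = make_reference_db(seed=5, n_species=4, genome_len=4000)
    seqs = [r.sequence for r in db.records]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident = np.mean([a == b for a, b in zip(seqs[i], seqs[j])])
            assert ident < 0.8


# ---------------------------------------------------------------------------
# gut reads
# ---------------------------------------------------------------------------

def test_species_totals_within_multinomial_bounds(small_db):
    props = {"Species_00": 0.95, "Species_01": 0.02, "Species_02": 0.02,
             "Species_03": 0.01}
    spec = GutCommunitySpec(seed=3, proportions=props, n_reads=10000)
    _, truth = simulate_gut_reads(spec, small_db)
    counts = truth["species"].value_counts()
    for sp, p in props.items():
        lo = stats.binom.ppf(0.005, 10000, p)
        hi = stats.binom.ppf(0.995, 10000, p)
        assert lo <= counts.get(sp, 0) <= hi


def test_error_free_reads_are_exact_substrings(small_db, gut_sample):
    reads, truth = gut_sample
    refs = {r.id: r.sequence for r in small_db.records}
    by_id = {r.id: r for r in reads}
    for row in truth.sample(60, random_state=0).itertuples():
        frag = refs[row.subject_id][row.start:row.end]
        got = by_id[row.read_id].sequence
        assert got == (frag if row.strand == "+"
                       else iupac.reverse_complement(frag))


def test_read_lengths_respect_truncation(gut_sample):
    _, truth = gut_sample
    assert truth["length"].between(30, 150).all()


def test_substitution_errors_are_recorded(small_db):
    spec = GutCommunitySpec(seed=4, proportions={"Species_00": 1.0},
                            n_reads=200, error_rate=0.02)
    reads, truth = simulate_gut_reads(spec, small_db)
    refs = {r.id: r.sequence for r in small_db.records}
    by_id = {r.id: r for r in reads}
    assert truth["n_errors"].sum() > 0
    for row in truth.head(50).itertuples():
        frag = refs[row.subject_id][row.start:row.end]
        if row.strand == "-":
            frag = iupac.reverse_complement(frag)
        diffs = sum(a != b for a, b in zip(frag, by_id[row.read_id].sequence))
        assert diffs == row.n_errors


@pytest.mark.parametrize("kwargs,match", [
    (dict(proportions={"Species_00": 0.5}, n_reads=10), "sum to 1"),
    (dict(proportions={"Species_00": 1.0}, n_reads=10, min_len=150,
          max_len=100), "max_len"),
])
def test_gut_spec_validation(kwargs, match):
    with pytest.raises(ValueError, match=match):
        GutCommunitySpec(seed=1, **kwargs)


def test_unknown_species_proportion_rejected(small_db):
    spec = GutCommunitySpec(seed=1, proportions={"Nobody": 1.0}, n_reads=10)
    with pytest.raises(ValueError, match="unknown species"):
        simulate_gut_reads(spec, small_db)


# ---------------------------------------------------------------------------
# alignment oracle
# ---------------------------------------------------------------------------

def test_oracle_align_error_free_read(small_db):
    ref = small_db.record("mito_01").sequence
    from gutreads.io_formats import SequenceRecord
    read = SequenceRecord("r1", "", ref[500:650])
    hits = oracle_align([read], small_db)
    best = max(hits, key=lambda h: h.bitscore)
    assert best.subject_id == "mito_01"
    assert best.pident == 100.0 and best.length == 150
    assert (best.sstart, best.send) == (501, 650)


def test_oracle_align_reverse_complement_convention(small_db):
    ref = small_db.record("mito_01").sequence
    from gutreads.io_formats import SequenceRecord
    read = SequenceRecord("r1", "", iupac.reverse_complement(ref[500:650]))
    hits = oracle_align([read], small_db)
    best = max(hits, key=lambda h: h.bitscore)
    assert best.subject_id == "mito_01"
    assert best.is_minus_strand
    assert (best.sstart, best.send) == (650, 501)


def test_oracle_align_single_substitution_pident(small_db):
    ref = small_db.record("mito_02").sequence
    frag = list(ref[1000:1150])
    frag[75] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[75]]
    from gutreads.io_formats import SequenceRecord
    read = SequenceRecord("r1", "", "".join(frag))
    hits = [h for h in oracle_align([read], small_db)
            if h.subject_id == "mito_02"]
    best = max(hits, key=lambda h: h.bitscore)
    assert best.pident == pytest.approx(100 * 149 / 150, abs=0.01)
    assert best.mismatch == 1


def test_truth_hits_equal_oracle_hits_for_error_free_reads(small_db,
                                                           gut_sample):
    reads, truth = gut_sample
    subset = truth.head(25)
    reads_sub = [r for r in reads if r.id in set(subset["read_id"])]
    fast = {h.query_id: h for h in hits_from_truth(reads_sub, subset, small_db)}
    for h in oracle_align(reads_sub, small_db):
        want = fast[h.query_id]
        if h.subject_id != want.subject_id:
            continue  # spurious partial cross-hits score below min anyway
        assert (h.qseq, h.sseq) == (want.qseq, want.sseq)
        assert (h.sstart, h.send) == (want.sstart, want.send)
        assert h.pident == want.pident and h.bitscore == want.bitscore


# ---------------------------------------------------------------------------
# melt and qPCR generators
# ---------------------------------------------------------------------------

def test_melt_grid_is_211_points_six_per_degree():
    t = melt_grid()
    assert len(t) == 211
    assert t[0] == 60.0 and t[-1] == 95.0
    assert np.allclose(np.diff(t), 1 / 6)


def test_two_transitions_give_two_peaks():
    from gutreads.mca import derivative_curve
    t, f = melt_fluorescence([MeltTransition(76.5, 2.0, 0.5),
                              MeltTransition(84.0, 1.0, 0.5)])
    dc = derivative_curve(t, f)
    tms = sorted(p.tm for p in dc.peaks[:2])
    assert tms[0] == pytest.approx(76.5, abs=0.2)
    assert tms[1] == pytest.approx(84.0, abs=0.2)


def test_zero_amplitude_has_no_peak_and_negative_call():
    from gutreads.mca import call_with_control, derivative_curve
    t, f = melt_fluorescence([MeltTransition(76.5, 0.0, 0.5)])
    curves = {f"r{i}": derivative_curve(t, f) for i in range(3)}
    assert call_with_control(curves, expected_tm=76.5).call == "negative"


def test_simulators_are_seed_deterministic():
    assays = {("s", "a", f"r{i}"): [MeltTransition(76.5, 2.0, 0.5)]
              for i in range(3)}
    m1 = simulate_melt(assays, seed=6, noise_sd=0.01)
    m2 = simulate_melt(assays, seed=6, noise_sd=0.01)
    pd.testing.assert_frame_equal(m1, m2)
    q1 = simulate_qpcr({("s", "a", "r"): (1e-6, 1.9)}, seed=6, noise_sd=0.01)
    q2 = simulate_qpcr({("s", "a", "r"): (1e-6, 1.9)}, seed=6, noise_sd=0.01)
    pd.testing.assert_frame_equal(q1, q2)


def test_qpcr_generator_validation():
    with pytest.raises(ValueError):
        qpcr_fluorescence(n0=1e-6, efficiency=2.5)
    with pytest.raises(ValueError):
        qpcr_fluorescence(n0=-1, efficiency=1.9)
    c, f = qpcr_fluorescence(n0=0.0, efficiency=1.9)
    assert np.allclose(f, 0.0)
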