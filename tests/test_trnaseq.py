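"""Adapter trimming, modification-aware alignment, normalization, profiling."""

import numpy as np
import pytest

from turnover15n import (
    SpeciesCounts,
    TRNARef,
    TrnaSimSpec,
    align_read,
    assign_read,
    assign_reads,
    count_species,
    make_trna_refs,
    normalize_and_fold_change,
    replicate_concordance,
    simulate_trna_reads,
    trim_adapters,
    truncation_profile,
)
from turnover15n._align import encode, semiglobal_dp


# -- oracle: substring enumeration edit distance ---------------------------


def brute_force_semiglobal(read, ref, mask):
    """Min global edit distance over all reference substrings, with masked
    reference positions matching any base."""
    m, n = len(read), len(ref)
    best = m  # align to the empty substring: all insertions
    for s in range(n):
        # D[i][j]: read[:i] vs ref[s:s+j]
        prev = list(range(n - s + 1))
        for i in range(1, m + 1):
            cur = [i] + [0] * (n - s)
            for j in range(1, n - s + 1):
                pos = s + j - 1
                cost = 0 if (pos in mask or ref[pos] == read[i - 1]) else 1
                cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
            prev = cur
        best = min(best, min(prev))
    return best


# -- adapter trimming -------------------------------------------------------


def brute_force_trim(seq, adapter, min_overlap):
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx]
    for ov in range(len(adapter) - 1, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[: len(seq) - ov]
    return seq


def test_trim_full_adapter_and_no_adapter():
    adapter = "AGATCGGAAGAGC"
    insert = "ACGTACGTACGTACGT"
    out = trim_adapters([("r1", insert + adapter), ("r2", insert)], adapter)
    assert out == [("r1", insert), ("r2", insert)]


def test_trim_partial_terminal_adapter_matches_brute_force():
    rng = np.random.default_rng(1)
    adapter = "AGATCGGAAGAGC"
    bases = np.array(list("ACGT"))
    for _ in range(200):
        insert = "".join(rng.choice(bases, rng.integers(10, 60)))
        keep = int(rng.integers(0, len(adapter) + 1))
        read = insert + adapter[:keep]
        (rid, got), = trim_adapters([("r", read)], adapter)
        assert got == brute_force_trim(read, adapter, 3)


def test_trim_rejects_empty_adapter():
    with pytest.raises(ValueError):
        trim_adapters([("r", "ACGT")], "")


# -- single-pair alignment --------------------------------------------------


@pytest.fixture(scope="module")
def ref():
    seq = "GGGCGAATAGCTCAGTTGGTAGAGCACGACCTTGCCAAGGTCGGGGTCGCGAGTTCGAGCCTCGTTTCGCCCACCA"
    return TRNARef("1-Ala(TGC)", seq, frozenset({8, 16, 34, 37, 46, 54, 58}))


def test_identical_read_full_length_accepted(ref):
    a = align_read(ref.sequence, ref)
    assert (a.errors, a.three_prime_offset, a.accepted) == (0, 0, True)
    assert a.aligned_length == len(ref.sequence)


def test_mismatch_at_modified_position_costs_nothing(ref):
    pos = 34
    assert pos in ref.modified_mask
    base = "A" if ref.sequence[pos] != "A" else "G"
    read = ref.sequence[:pos] + base + ref.sequence[pos + 1 :]
    a = align_read(read, ref)
    assert a.errors == 0
    assert a.accepted


def test_four_substitutions_at_unmodified_positions_rejected(ref):
    read = list(ref.sequence)
    unmod = [i for i in range(len(read)) if i not in ref.modified_mask][:4]
    for i in unmod:
        read[i] = "A" if read[i] != "A" else "G"
    a = align_read("".join(read), ref, max_errors=3)
    assert a.errors == 4
    assert not a.accepted
    assert a.species_id is None


def test_three_prime_truncation_offset(ref):
    for k in (1, 3, 7):
        read = ref.sequence[:-k]
        a = align_read(read, ref)
        assert a.errors == 0
        assert a.three_prime_offset == k


def test_short_read_rejected_without_alignment(ref):
    a = align_read(ref.sequence[:20], ref, min_length=25)
    assert not a.accepted
    assert "shorter" in a.reason


def test_dp_matches_substring_enumeration_oracle():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    for _ in range(60):
        n = int(rng.integers(30, 91))
        m = int(rng.integers(10, 41))
        ref_seq = "".join(rng.choice(bases, n))
        if rng.random() < 0.5:
            start = int(rng.integers(0, n - m + 1))
            read = list(ref_seq[start : start + m])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, len(read)))
                read[p] = str(rng.choice(bases))
            read = "".join(read)
        else:
            read = "".join(rng.choice(bases, m))
        mask = set(int(x) for x in rng.choice(n, rng.integers(0, 8), replace=False))
        mask_arr = np.zeros(n, dtype=bool)
        mask_arr[list(mask)] = True
        err, _ = semiglobal_dp(encode(read), encode(ref_seq), mask_arr, -1)
        assert err == brute_force_semiglobal(read, ref_seq, mask)


def test_adding_mask_positions_never_increases_errors():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    for _ in range(30):
        n = int(rng.integers(40, 80))
        ref_seq = "".join(rng.choice(bases, n))
        read = "".join(rng.choice(bases, int(rng.integers(25, n))))
        mask = np.zeros(n, dtype=bool)
        prev_err, _ = semiglobal_dp(encode(read), encode(ref_seq), mask, -1)
        for pos in rng.permutation(n)[:10]:
            mask[pos] = True
            err, _ = semiglobal_dp(encode(read), encode(ref_seq), mask, -1)
            assert err <= prev_err
            prev_err = err


# -- assignment -------------------------------------------------------------


def test_assignment_unique_and_unassigned(trna_refs):
    r = trna_refs[5]
    a = assign_read(r.sequence, trna_refs)
    assert a.species_id == r.species_id
    junk = "ACGT" * 15
    b = assign_read(junk, trna_refs)
    assert not b.accepted
    assert b.species_id is None


def test_ambiguous_read_resolved_lexicographically():
    shared = "GGGCGAATAGCTCAGTTGGTAGAGCACGACCTTG"
    ref_a = TRNARef("2-Ala(GGC)", shared + "AAACCA")
    ref_b = TRNARef("10-Gln(CTG)", shared + "TTTCCA")
    a = assign_read(shared, [ref_a, ref_b], min_length=25)
    assert a.accepted
    assert a.species_id == "10-Gln(CTG)"  # "10-..." sorts before "2-..."
    # order of the reference list must not matter
    b = assign_read(shared, [ref_b, ref_a], min_length=25)
    assert b.species_id == a.species_id


def test_batch_assignment_agrees_with_single_pair_path(trna_refs):
    rng = np.random.default_rng(13)
    spec = TrnaSimSpec(refs=tuple(trna_refs[:10]), read_count=300, seed=5)
    reads, _ = simulate_trna_reads(spec, "normal")
    refs_all = list(trna_refs[:10]) + [TRNARef("SPIKE", spec.spike_in_seq)]
    batch = assign_reads(reads, refs_all)
    idx = rng.choice(len(reads), size=40, replace=False)
    for i in idx:
        single_best = None
        for r in sorted(refs_all, key=lambda r: r.species_id):
            a = align_read(reads[i][1], r, read_id=reads[i][0])
            if a.accepted and (single_best is None or a.errors < single_best.errors):
                single_best = a
        got = batch[i]
        if single_best is None:
            assert not got.accepted
        else:
            assert got.accepted
            assert got.species_id == single_best.species_id
            assert got.errors == single_best.errors


def test_count_conservation(trna_refs):
    spec = TrnaSimSpec(refs=tuple(trna_refs), read_count=2000, seed=9)
    reads, _ = simulate_trna_reads(spec, "normal")
    refs_all = list(trna_refs) + [TRNARef("SPIKE", spec.spike_in_seq)]
    alignments = assign_reads(reads, refs_all)
    counts = count_species(alignments, "normal")
    assigned = sum(counts.counts.values())
    unassigned = sum(not a.accepted for a in alignments)
    assert assigned + unassigned + counts.spike_in_count == len(reads)


# -- normalization and fold change ------------------------------------------


def test_identical_libraries_fold_one():
    c = SpeciesCounts("a", {"x": 100, "y": 50}, spike_in_count=10)
    res = normalize_and_fold_change(c, c)
    assert all(f == pytest.approx(1.0) for f in res["fold_change"].values())
    assert res["mean_fold_change"] == pytest.approx(1.0)


def test_halved_counts_fold_two_and_zero_stress_excluded():
    cn = SpeciesCounts("n", {"x": 100, "y": 50, "z": 30}, spike_in_count=10)
    cs = SpeciesCounts("s", {"x": 50, "y": 25, "z": 0}, spike_in_count=10)
    res = normalize_and_fold_change(cn, cs)
    assert res["fold_change"]["x"] == pytest.approx(2.0)
    assert res["mean_fold_change"] == pytest.approx(2.0)
    assert res["excluded_zero_stress"] == ["z"]


def test_zero_spike_in_rejected():
    c = SpeciesCounts("a", {"x": 1}, spike_in_count=0)
    with pytest.raises(ValueError):
        normalize_and_fold_change(c, c)


def test_depth_invariance_of_normalized_abundances(trna_refs):
    """Scaling the library size leaves spike-normalized abundances unchanged
    in expectation."""
    refs = tuple(trna_refs[:12])
    spike = TRNARef("SPIKE", TrnaSimSpec(refs=refs).spike_in_seq)
    depths = (8000, 32000)
    norm = {}
    for depth in depths:
        spec = TrnaSimSpec(refs=refs, read_count=depth, seed=21)
        reads, _ = simulate_trna_reads(spec, "normal")
        counts = count_species(assign_reads(reads, list(refs) + [spike]), "c")
        norm[depth] = counts.normalized
    # the spike-normalized mean is dominated by spike-in Poisson noise
    # (sd ~ sqrt(1/800 + 1/3200) ~ 4%); 15% is a ~3.5 sigma band
    for s in norm[depths[0]]:
        assert norm[depths[1]][s] == pytest.approx(norm[depths[0]][s], rel=0.3)
    mean_lo = np.mean(list(norm[depths[0]].values()))
    mean_hi = np.mean(list(norm[depths[1]].values()))
    assert mean_hi == pytest.approx(mean_lo, rel=0.15)


# -- truncation profile -----------------------------------------------------


def _aln(species, offset, accepted=True):
    from turnover15n import ReadAlignment

    return ReadAlignment("r", species if accepted else None, 0, 70, offset, accepted)


def test_full_length_reads_profile_at_zero():
    alns = [_aln("x", 0) for _ in range(10)]
    prof = truncation_profile(alns, "x")
    assert prof["fractions"][0] == 1.0
    assert prof["fractions"][1:].sum() == 0.0


def test_half_reads_truncated_by_three():
    alns = [_aln("x", 0) for _ in range(50)] + [_aln("x", 3) for _ in range(50)]
    prof = truncation_profile(alns, "x")
    assert prof["fractions"][3] == pytest.approx(0.5)


def test_tandem_cca_inner_fraction_reported(trna_refs):
    tandem = next(r for r in trna_refs if r.tandem_cca)
    assert tandem.species_id in {"1-Ala(TGC)", "7-Asn(GTT)", "12-Glu(TTC)"}
    alns = [_aln(tandem.species_id, 3) for _ in range(4)] + [
        _aln(tandem.species_id, 0) for _ in range(6)
    ]
    prof = truncation_profile(alns, tandem.species_id, ref=tandem)
    assert prof["inner_cca_fraction"] == pytest.approx(0.4)


def test_simulated_truncation_pmf_recovered(trna_refs):
    refs = tuple(trna_refs[:8])
    spec = TrnaSimSpec(
        refs=refs,
        read_count=8000,
        truncation_pmf={0: 0.5, 3: 0.5},
        error_rate=0.0,
        seed=17,
    )
    reads, _ = simulate_trna_reads(spec, "normal")
    refs_all = list(refs) + [TRNARef("SPIKE", spec.spike_in_seq)]
    alignments = assign_reads(reads, refs_all)
    prof = truncation_profile(alignments, refs[0].species_id)
    n = prof["n_reads"]
    ci = 3.0 * np.sqrt(0.25 / n)  # ~3 sigma binomial interval
    assert abs(prof["fractions"][3] - 0.5) < ci


# -- replicate concordance --------------------------------------------------


def test_identical_replicates_perfect_correlation():
    c = SpeciesCounts("r1", {"a": 10, "b": 30, "c": 5}, spike_in_count=4)
    pear, spear = replicate_concordance(c, c)
    assert pear == pytest.approx(1.0)
    assert spear == pytest.approx(1.0)


def test_scaled_replicate_still_perfectly_correlated():
    c1 = SpeciesCounts("r1", {"a": 10, "b": 30, "c": 5}, spike_in_count=4)
    c2 = SpeciesCounts("r2", {"a": 100, "b": 300, "c": 50}, spike_in_count=40)
    pear, _ = replicate_concordance(c1, c2)
    assert pear == pytest.approx(1.0)


def test_too_few_shared_species_rejected():
    c1 = SpeciesCounts("r1", {"a": 1, "b": 2}, spike_in_count=1)
    with pytest.raises(ValueError):
        replicate_concordance(c1, c1)


# -- reference invariants ---------------------------------------------------


def test_reference_set_invariants(trna_refs):
    assert len(trna_refs) == 47
    assert len({r.species_id for r in trna_refs}) == 47
    tandem = {r.species_id for r in trna_refs if r.tandem_cca}
    assert tandem == {"1-Ala(TGC)", "7-Asn(GTT)", "12-Glu(TTC)"}
    for r in trna_refs:
        assert r.sequence.endswith("CCA")
        assert all(0 <= p < len(r.sequence) for p in r.modified_mask)


def test_ref_requires_cca_end():
    with pytest.raises(ValueError):
        TRNARef("x", "ACGTACGT")
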