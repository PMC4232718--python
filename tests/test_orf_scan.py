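"""ORF-disruption scanning: alignment, classification, shared events."""

import numpy as np
import pytest

from cetataste.orf_scan import (
    AlignParams,
    Disruption,
    align_codon_aware,
    detect_disruptions,
    find_shared_events,
)


# ---------------------------------------------------------------------------
# pairwise alignment vs an independent DP oracle


def _dp_score(a, b, params):
    """Independent quadratic-time affine-gap global alignment score (Gotoh)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (insertion)
    M[0, 0] = 0.0
    go, ge = params.gap_open, params.gap_extend
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = params.match if a[i - 1] == b[j - 1] else params.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)
    return max(M[n, m], X[n, m], Y[n, m])


def _aln_score(ref_row, q_row, params):
    score, i, n = 0.0, 0, len(ref_row)
    while i < n:
        if ref_row[i] == "-" or q_row[i] == "-":
            row = ref_row if ref_row[i] == "-" else q_row
            j = i
            while j < n and row[j] == "-":
                j += 1
            score += params.gap_open + params.gap_extend * (j - i - 1)
            i = j
        else:
            score += params.match if ref_row[i] == q_row[i] else params.mismatch
            i += 1
    return score


def test_identical_sequences_align_without_gaps():
    ref = "ATGAAACCCGGG"
    r, q = align_codon_aware(ref, ref)
    assert r == q == ref


def test_clean_deletion_spanning_codon_two():
    r, q = align_codon_aware("ATGAAACCC", "ATGCCC")
    assert r == "ATGAAACCC"
    assert q == "ATG---CCC"


def test_alignment_scores_match_dp_oracle(rng):
    params = AlignParams()
    for _ in range(50):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 31)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 31)))
        r, q = align_codon_aware(a, b, params)
        assert _aln_score(r, q, params) == pytest.approx(_dp_score(a, b, params))


def test_alignment_rejects_sub_codon_input():
    with pytest.raises(ValueError):
        align_codon_aware("AT", "ATG")


# ---------------------------------------------------------------------------
# disruption detection

REF = "ATGAAACCCGGGTTTCTGAAACCAGGATTCCTTAAACCCGGGTTTTAA"  # 16 codons incl stop


def test_five_nt_deletion_is_frameshifting():
    # 5 nt deleted starting at nt 13 (codon 5)
    rep = detect_disruptions((REF, REF[:12] + "-" * 5 + REF[17:]))
    dels = [d for d in rep.disruptions if d.kind == "deletion"]
    assert len(dels) == 1
    d = dels[0]
    assert d.length_nt == 5 and d.frameshifting and d.ref_codon_start == 5
    assert not rep.intact


def test_four_nt_insertion_is_frameshifting():
    ref_row = REF[:12] + "----" + REF[12:]
    q_row = REF[:12] + "CTCA" + REF[12:]
    rep = detect_disruptions((ref_row, q_row))
    ins = [d for d in rep.disruptions if d.kind == "insertion"]
    assert len(ins) == 1
    assert ins[0].length_nt == 4 and ins[0].frameshifting
    assert ins[0].ref_codon_start == 5


def test_in_frame_deletion_not_frameshifting_and_can_stay_intact():
    q_row = REF[:12] + "---" + REF[15:]
    rep = detect_disruptions((REF, q_row))
    assert len(rep.disruptions) == 1
    d = rep.disruptions[0]
    assert d.kind == "deletion" and d.length_nt == 3 and not d.frameshifting
    assert rep.first_stop_codon is None


def test_premature_stop_reported_with_truncation():
    # put TGA at codon 5 (nt 13-15)
    q = REF[:12] + "TGA" + REF[15:]
    rep = detect_disruptions((REF, q))
    stops = [d for d in rep.disruptions if d.kind == "premature_stop"]
    assert stops and stops[0].ref_codon_start == 5
    assert stops[0].stop_codon == "TGA" and stops[0].cause is None
    assert rep.first_stop_codon == 5
    # 15 protein codons; stop at 5 -> 1 - 4/15
    assert rep.truncation_fraction == pytest.approx(1 - 4 / 15)


def test_stop_at_codon_one_gives_full_truncation():
    q = "TAA" + REF[3:]
    rep = detect_disruptions((REF, q))
    assert rep.first_stop_codon == 1
    assert rep.truncation_fraction == 1.0


def test_post_frameshift_stop_cause_recorded():
    # 1-nt deletion at codon 5 shifts frame; downstream stop in local frame
    q_row = REF[:12] + "-" + REF[13:]
    rep = detect_disruptions((REF, q_row))
    stops = [d for d in rep.disruptions if d.kind == "premature_stop"]
    assert all(s.cause == "post-frameshift" for s in stops)


def test_clean_sequence_is_intact():
    rep = detect_disruptions((REF, REF))
    assert rep.intact and rep.truncation_fraction == 0.0


def test_invalid_reference_rejected():
    bad = REF[:6] + "TGA" + REF[9:]
    with pytest.raises(ValueError, match="invalid reference"):
        detect_disruptions((bad, bad))


def test_padding_with_terminal_gaps_is_ignored():
    rep1 = detect_disruptions((REF, REF[:12] + "-" * 5 + REF[17:]))
    rep2 = detect_disruptions(
        ("---" + REF + "---", "---" + REF[:12] + "-" * 5 + REF[17:] + "---")
    )
    assert [d.ref_codon_start for d in rep1.disruptions] == [
        d.ref_codon_start for d in rep2.disruptions
    ]


def test_whole_exon_deletion_annotated():
    q_row = REF[:12] + "-" * 9 + REF[21:]
    rep = detect_disruptions((REF, q_row), exon_intervals=[(1, 12), (13, 21)])
    d = [x for x in rep.disruptions if x.kind == "deletion"][0]
    assert d.note == "spans exon 2"


# ---------------------------------------------------------------------------
# shared events


def _mk(kind, codon, nt, length, taxon):
    from cetataste.orf_scan import DisruptionReport

    d = Disruption(kind, codon, nt, length, length % 3 != 0)
    return DisruptionReport(taxon=taxon, gene="g", disruptions=[d], ref_protein_length=100)


def test_identical_deletion_in_three_taxa_groups_into_one_event():
    reports = [_mk("deletion", 10, 28, 1, t) for t in ("t1", "t2", "t3")]
    events = find_shared_events(reports)
    assert len(events) == 1
    assert events[0].carriers == frozenset({"t1", "t2", "t3"})


def test_singleton_disruption_becomes_single_carrier_event():
    reports = [_mk("deletion", 10, 28, 1, "t1"), _mk("deletion", 50, 148, 2, "t2")]
    events = find_shared_events(reports)
    assert len(events) == 2
    assert all(len(ev.carriers) == 1 for ev in events)


def test_grouping_matches_brute_force_clustering(rng):
    """Exact-coordinate grouping equals pairwise-equality clustering."""
    from cetataste.orf_scan import DisruptionReport

    reports = []
    for t in range(12):
        ds = []
        for _ in range(rng.integers(0, 4)):
            codon = int(rng.integers(1, 10))
            length = int(rng.choice([1, 2, 3, 5]))
            kind = str(rng.choice(["deletion", "insertion"]))
            ds.append(Disruption(kind, codon, 3 * (codon - 1) + 1, length, length % 3 != 0))
        reports.append(
            DisruptionReport(taxon=f"t{t}", gene="g", disruptions=ds, ref_protein_length=50)
        )
    events = find_shared_events(reports)
    # brute force: bucket by full identity key
    buckets = {}
    for rep in reports:
        for d in rep.disruptions:
            key = (d.kind, d.ref_codon_start, d.ref_nt_start, d.length_nt)
            buckets.setdefault(key, set()).add(rep.taxon)
    got = {
        (
            ev.disruption.kind,
            ev.disruption.ref_codon_start,
            ev.disruption.ref_nt_start,
            ev.disruption.length_nt,
        ): set(ev.carriers)
        for ev in events
    }
    assert got == buckets


def test_mixed_genes_rejected():
    r1 = _mk("deletion", 10, 28, 1, "t1")
    r2 = _mk("deletion", 10, 28, 1, "t2")
    r2.gene = "other"
    with pytest.raises(ValueError, match="mix"):
        find_shared_events([r1, r2])
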