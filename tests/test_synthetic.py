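"""Synthetic-data generator: determinism, stationarity, injection truth."""

import numpy as np
import pytest

from cetataste.codon_models import CodonFrequencies
from cetataste.genetics import CODON_INDEX, SENSE_CODONS, GeneticCode
from cetataste.orf_scan import detect_disruptions, find_shared_events
from cetataste.event_mapping import map_event
from cetataste.phylo import PhyloTree
from cetataste.synthetic import (
    TOOTHED_WHALES,
    cetacean_tree,
    fixture_suite,
    inject_pseudogenization,
    simulate_alignment,
)


def test_identical_seed_gives_identical_alignment(tiny_tree):
    a1, _ = simulate_alignment(tiny_tree, 0.4, kappa=2.0, n_codons=50, seed=9)
    a2, _ = simulate_alignment(tiny_tree, 0.4, kappa=2.0, n_codons=50, seed=9)
    a3, _ = simulate_alignment(tiny_tree, 0.4, kappa=2.0, n_codons=50, seed=10)
    assert (a1.codes == a2.codes).all()
    assert (a1.codes != a3.codes).any()


def test_zero_branch_lengths_copy_root_to_all_leaves():
    tree = PhyloTree.from_newick("((A:0,B:0):0,C:0);")
    aln, _ = simulate_alignment(tree, 0.4, kappa=2.0, n_codons=30, seed=3)
    assert (aln.codes == aln.codes[0]).all()


def test_long_branch_converges_to_stationary_frequencies():
    tree = PhyloTree.from_newick("(A:0.001,B:50.0);")
    rng_pi = np.random.default_rng(1).dirichlet(np.full(61, 50.0))
    pi = CodonFrequencies(rng_pi, "empirical")
    aln, _ = simulate_alignment(tree, 0.5, kappa=2.0, pi=pi, n_codons=10000, seed=17)
    freq = np.bincount(aln.row("B"), minlength=61) / 10000
    assert 0.5 * np.abs(freq - pi.pi).sum() < 0.05  # total variation


def _ng86_omega(seq_i, seq_j, code):
    """Crude counting dN/dS estimator (NG86 flavour) as an independent oracle."""
    syn_sites = nonsyn_sites = 0.0
    syn_diff = nonsyn_diff = 0.0
    for ci, cj in zip(seq_i, seq_j):
        a, b = SENSE_CODONS[ci], SENSE_CODONS[cj]
        # per-codon site counts from codon a
        for pos in range(3):
            syn_frac = 0.0
            for nt in "ACGT":
                if nt == a[pos]:
                    continue
                mut = a[:pos] + nt + a[pos + 1 :]
                if mut in CODON_INDEX and code.translate_codon(mut) == code.translate_codon(a):
                    syn_frac += 1 / 3
            syn_sites += syn_frac
            nonsyn_sites += 1 - syn_frac
        diffs = [(p, x, y) for p, (x, y) in enumerate(zip(a, b)) if x != y]
        if len(diffs) == 1:
            p, x, y = diffs[0]
            if code.translate_codon(a) == code.translate_codon(b):
                syn_diff += 1
            else:
                nonsyn_diff += 1
        elif len(diffs) > 1:
            # average over substitution orders is overkill here; count each
            # differing position against the direct single-step change
            for p, x, y in diffs:
                mut = a[:p] + y + a[p + 1 :]
                if mut in CODON_INDEX:
                    if code.translate_codon(mut) == code.translate_codon(a):
                        syn_diff += 1
                    else:
                        nonsyn_diff += 1
    pn = nonsyn_diff / nonsyn_sites
    ps = syn_diff / syn_sites
    # Jukes-Cantor style correction
    dn = -3 / 4 * np.log(1 - 4 / 3 * pn)
    ds = -3 / 4 * np.log(1 - 4 / 3 * ps)
    return dn / ds


def test_counting_estimator_recovers_simulated_omega(code):
    tree = PhyloTree.from_newick("(A:0.25,B:0.25);")
    aln, _ = simulate_alignment(tree, 0.3, kappa=2.0, n_codons=5000, seed=23)
    est = _ng86_omega(aln.row("A"), aln.row("B"), code)
    assert 0.2 <= est <= 0.4


def test_injection_on_terminal_branch_affects_one_taxon():
    tree = cetacean_tree()
    aln, truth = simulate_alignment(tree, 0.3, kappa=2.0, n_codons=60, seed=5)
    rec = inject_pseudogenization(
        aln.to_nucleotide(), tree, "Lipotes",
        dict(kind="deletion", codon=20, length_nt=4), truth,
    )
    changed = [t for t in rec if "-" in rec[t]]
    assert changed == ["Lipotes"]
    assert truth.injected_events[-1]["carriers"] == ["Lipotes"]


def test_three_nt_deletion_scans_as_non_frameshifting():
    tree = cetacean_tree()
    aln, truth = simulate_alignment(tree, 0.3, kappa=2.0, n_codons=60, seed=6)
    rec = inject_pseudogenization(
        aln.to_nucleotide(), tree, "Lipotes",
        dict(kind="deletion", codon=20, length_nt=3), truth,
    )
    rep = detect_disruptions((rec["Bos"], rec["Lipotes"]))
    dels = [d for d in rep.disruptions if d.kind == "deletion"]
    assert len(dels) == 1 and not dels[0].frameshifting


def test_injection_roundtrip_recovers_kind_length_position_and_origin():
    tree = cetacean_tree()
    rng = np.random.default_rng(99)
    internal = [br.name for br in tree.branches if br.name.startswith("stem(")
                and "Bos" not in br.name and "Hippopotamus" not in br.name]
    for rep_i in range(10):
        aln, truth = simulate_alignment(tree, 0.25, kappa=2.5, n_codons=120,
                                        seed=int(rng.integers(2**31)))
        rec = aln.to_nucleotide()
        branch = internal[int(rng.integers(len(internal)))]
        kind = ["deletion", "premature_stop"][rep_i % 2]
        codon = int(rng.integers(10, 100))
        spec = dict(kind=kind, codon=codon)
        if kind == "deletion":
            spec["length_nt"] = int(rng.choice([1, 2, 4, 5, 17]))
        rec = inject_pseudogenization(rec, tree, branch, spec, truth,
                                      seed=int(rng.integers(2**31)))
        reports = [detect_disruptions((rec["Bos"], row), taxon=t, gene="g")
                   for t, row in rec.items() if t != "Bos"]
        events = find_shared_events(reports)
        matches = [ev for ev in events
                   if ev.disruption.kind == kind
                   and ev.disruption.ref_codon_start == codon
                   and ev.disruption.length_nt == spec.get("length_nt", 0)]
        assert matches, f"injected event not recovered (rep {rep_i})"
        carriers_truth = set(truth.injected_events[-1]["carriers"])
        ev = next(e for e in matches if set(e.carriers) >= carriers_truth)
        me = map_event(tree, ev)
        assert branch in me.origin_branches


def test_fixture_suite_deterministic_and_complete(tmp_path):
    w1 = fixture_suite(7, tmp_path / "a")
    w2 = fixture_suite(7, tmp_path / "b")
    assert set(w1) == {"tiny4", "taste13", "relaxed", "protein"}
    for key in w1:
        assert w1[key].read_text() == w2[key].read_text()


def test_fixture_taste13_maps_to_stem_odontoceti(tmp_path):
    from cetataste.fastaio import read_fasta
    from cetataste.synthetic import SimulationTruth

    fixture_suite(3, tmp_path)
    rec = read_fasta(tmp_path / "taste13.fasta")
    tree = PhyloTree.read_newick(tmp_path / "taste13.nwk")
    reports = [detect_disruptions((rec["Bos"], row), taxon=t, gene="g")
               for t, row in rec.items() if t != "Bos"]
    events = find_shared_events(reports)
    stem_od = "stem(" + "+".join(sorted(TOOTHED_WHALES)) + ")"
    dels = [ev for ev in events
            if ev.disruption.kind == "deletion" and ev.disruption.length_nt == 5]
    assert dels
    me = map_event(tree, dels[0])
    assert me.origin_branches == frozenset({stem_od})
    assert me.monophyletic
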