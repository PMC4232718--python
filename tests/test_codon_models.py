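"""Codon substitution machinery: generator, P(t), frequencies, site classes,
pruning likelihood, and ML fitting."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from cetataste.alignment import CodonAlignment
from cetataste.codon_models import (
    CodonFrequencies,
    EigenQ,
    FitOptions,
    ModelSpec,
    beta_category_means,
    build_generator,
    estimate_frequencies,
    fit,
    log_likelihood,
    site_classes,
    stationary_distribution,
    transition_matrix,
)
from cetataste.genetics import CODON_INDEX, SENSE_CODONS, GeneticCode
from cetataste.phylo import PhyloTree
from cetataste.synthetic import simulate_alignment

PI = CodonFrequencies.equal().pi


# ---------------------------------------------------------------------------
# generator


def test_generator_rows_sum_to_zero():
    Q = build_generator(2.5, 0.4, PI)
    assert np.abs(Q.sum(axis=1)).max() < 1e-12


def test_generator_detailed_balance():
    rng = np.random.default_rng(0)
    pi = rng.dirichlet(np.ones(61))
    Q = build_generator(3.0, 0.7, pi)
    flux = pi[:, None] * Q
    assert np.abs(flux - flux.T).max() < 1e-14


def test_generator_mean_rate_is_one():
    Q = build_generator(1.7, 1.3, PI)
    assert -(PI * np.diag(Q)).sum() == pytest.approx(1.0)


def test_generator_matches_naive_double_loop(code):
    """Brute-force construction over all 61x61 pairs."""
    kappa, omega = 2.0, 0.5
    rng = np.random.default_rng(1)
    pi = rng.dirichlet(np.ones(61))
    Q = build_generator(kappa, omega, pi)
    raw = np.zeros((61, 61))
    transitions = {frozenset("AG"), frozenset("CT")}
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            r = pi[j]
            if frozenset(diffs[0]) in transitions:
                r *= kappa
            if code.translate_codon(ci) != code.translate_codon(cj):
                r *= omega
            raw[i, j] = r
    np.fill_diagonal(raw, -raw.sum(axis=1))
    raw /= -(pi * np.diag(raw)).sum()
    assert np.abs(Q - raw).max() < 1e-13


def test_generator_rejects_bad_parameters():
    with pytest.raises(ValueError):
        build_generator(-1.0, 0.5, PI)
    with pytest.raises(ValueError):
        build_generator(np.nan, 0.5, PI)


# ---------------------------------------------------------------------------
# transition probabilities


def test_transition_matrix_at_zero_is_identity():
    Q = build_generator(2.0, 0.3, PI)
    assert np.abs(transition_matrix(Q, 0.0, PI) - np.eye(61)).max() < 1e-12


def test_transition_matrix_rows_sum_to_one(rng):
    Q = build_generator(2.0, 0.3, PI)
    for t in rng.uniform(0, 5, size=5):
        P = transition_matrix(Q, float(t), PI)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-12
        assert (P >= 0).all()


def test_transition_matrix_matches_series_expansion():
    """Scaling-and-squaring Taylor series as the independent oracle."""
    Q = build_generator(2.0, 0.3, PI)
    t = 0.37
    # exp(Qt) = (exp(Qt/2^k))^(2^k) with a 20-term series at the base
    k = 6
    A = Q * (t / 2**k)
    S = np.eye(61)
    term = np.eye(61)
    for n in range(1, 21):
        term = term @ A / n
        S = S + term
    for _ in range(k):
        S = S @ S
    P = transition_matrix(Q, t, PI)
    assert np.abs(P - S).max() < 1e-10


def test_stationary_distribution_recovers_pi():
    rng = np.random.default_rng(2)
    pi = rng.dirichlet(np.ones(61))
    Q = build_generator(2.0, 0.5, pi)
    assert np.abs(stationary_distribution(Q) - pi).max() < 1e-10


# ---------------------------------------------------------------------------
# frequencies


def test_equal_frequencies():
    f = CodonFrequencies.equal()
    assert f.pi.sum() == pytest.approx(1.0)
    assert np.allclose(f.pi, 1 / 61)


def test_f3x4_matches_hand_tabulation():
    """2-taxon, 6-codon worked example tabulated by hand."""
    recs = {"a": "ATGAAACCCGGGTTTCAA", "b": "ATGAAACCTGGGTTTCAG"}
    aln = CodonAlignment.from_nucleotide(recs)
    f = estimate_frequencies(aln, "F3x4")
    # hand-counted position-specific nucleotide frequencies over 12 codons
    seq = recs["a"] + recs["b"]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    from collections import Counter

    pos = [Counter(c[p] for c in codons) for p in range(3)]
    raw = {}
    for c in SENSE_CODONS:
        raw[c] = (pos[0][c[0]] / 12) * (pos[1][c[1]] / 12) * (pos[2][c[2]] / 12)
    total = sum(raw.values())
    assert f.pi.sum() == pytest.approx(1.0)
    for c in ("ATG", "AAA", "CCC", "TTT"):
        assert f.pi[CODON_INDEX[c]] == pytest.approx(max(raw[c], 1e-12) / total, rel=1e-9)


def test_uniform_alignment_gives_near_uniform_f3x4(rng):
    codes = rng.integers(0, 61, size=(4, 4000)).astype(np.int16)
    aln = CodonAlignment(taxa=list("abcd"), codes=codes)
    f = estimate_frequencies(aln, "F3x4")
    assert np.abs(f.pi - 1 / 61).max() < 0.005


# ---------------------------------------------------------------------------
# site classes


@pytest.mark.parametrize(
    "family,params",
    [
        ("site_M1a", dict(p0=0.6, omega0=0.2)),
        ("site_M2a", dict(v1=0.5, v2=0.8, omega0=0.1, omega2=2.0)),
        ("site_M8", dict(p0=0.9, p=0.6, q=1.4, omega_s=1.8)),
        ("site_M8a", dict(p0=0.9, p=0.6, q=1.4)),
        ("clade_C", dict(v1=0.5, v2=0.5, omega0=0.1, omega2=0.2, omega3=1.05)),
        ("clade_M2a_rel", dict(v1=0.5, v2=0.5, omega0=0.1, omega2=0.25)),
    ],
)
def test_site_class_proportions_sum_to_one(family, params):
    classes = site_classes(ModelSpec(family), params)
    assert sum(p for p, _ in classes) == pytest.approx(1.0)


def test_m8a_final_class_omega_is_exactly_one():
    classes = site_classes(ModelSpec("site_M8a"), dict(p0=0.85, p=0.4, q=1.2))
    assert classes[-1][1]["background"] == 1.0


def test_clade_m2a_rel_forces_equal_class3_omegas():
    classes = site_classes(
        ModelSpec("clade_M2a_rel"), dict(v1=0.5, v2=0.5, omega0=0.1, omega2=0.4)
    )
    assert classes[-1][1]["background"] == classes[-1][1]["foreground"] == 0.4


def test_beta_category_means_match_quadrature():
    p, q = 0.7, 1.8
    means = beta_category_means(p, q, 10)
    edges = beta_dist.ppf(np.linspace(0, 1, 11), p, q)
    for i in range(10):
        num, _ = quad(lambda x: x * beta_dist.pdf(x, p, q), edges[i], edges[i + 1])
        assert means[i] == pytest.approx(num * 10, abs=1e-6)


# ---------------------------------------------------------------------------
# likelihood


def test_single_sequence_likelihood_is_log_pi():
    codes = np.array([[0, 5, 10, 60]], dtype=np.int16)
    aln = CodonAlignment(taxa=["A"], codes=codes)
    tree = PhyloTree.from_newick("A;")
    lnl = log_likelihood(aln, tree, ModelSpec("branch_one_ratio"), {"omega": 0.5}, 2.0, pi=PI)
    assert lnl == pytest.approx(np.log(PI[[0, 5, 10, 60]]).sum())


def _enumeration_lnl(aln, Ps, tree_shape, pi):
    """Exhaustive sum over internal-node states for '((A,B)u,C[,D])' shapes."""
    total = 0.0
    for s in range(aln.n_codons):
        obs = {t: int(aln.row(t)[s]) for t in aln.taxa}
        L = 0.0
        for r in range(61):
            for u in range(61):
                term = pi[r] * Ps["u"][r, u]
                term *= Ps["A"][u, obs["A"]] * Ps["B"][u, obs["B"]]
                term *= Ps["C"][r, obs["C"]]
                if "D" in obs:
                    term *= Ps["D"][r, obs["D"]]
                L += term
        total += np.log(L)
    return total


@pytest.mark.parametrize("newick", ["((A:0.1,B:0.2):0.07,C:0.15);",
                                    "((A:0.1,B:0.2):0.07,C:0.15,D:0.25);"])
def test_pruning_equals_exhaustive_enumeration(newick):
    tree = PhyloTree.from_newick(newick)
    n_taxa = len(tree.leaf_labels)
    aln, _ = simulate_alignment(tree, 0.6, kappa=2.0, n_codons=8, seed=13)
    kappa, omega = 2.0, 0.6
    lnl = log_likelihood(aln, tree, ModelSpec("branch_one_ratio"), {"omega": omega}, kappa, pi=PI)
    eig = EigenQ(build_generator(kappa, omega, PI), PI)
    Ps = {br.name if br.name in "ABCD" else "u": eig.transition_matrix(br.length)
          for br in tree.branches}
    expected = _enumeration_lnl(aln, Ps, newick, PI)
    assert lnl == pytest.approx(expected, abs=1e-8)


def test_mixture_pruning_equals_classwise_enumeration():
    """M1a likelihood = proportion-weighted sum of per-class enumerations."""
    tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.07,C:0.15);")
    aln, _ = simulate_alignment(tree, 0.5, kappa=2.0, n_codons=6, seed=21)
    params = dict(p0=0.7, omega0=0.1)
    kappa = 2.0
    lnl = log_likelihood(aln, tree, ModelSpec("site_M1a"), params, kappa, pi=PI)
    total = 0.0
    Ps_by_class = []
    for omega in (params["omega0"], 1.0):
        eig = EigenQ(build_generator(kappa, omega, PI), PI)
        Ps_by_class.append(
            {br.name if br.name in "ABC" else "u": eig.transition_matrix(br.length)
             for br in tree.branches}
        )
    for s in range(aln.n_codons):
        site_L = 0.0
        for (prop, Ps) in zip((params["p0"], 1 - params["p0"]), Ps_by_class):
            obs = {t: int(aln.row(t)[s]) for t in aln.taxa}
            L = 0.0
            for r in range(61):
                for u in range(61):
                    L += (PI[r] * Ps["u"][r, u] * Ps["A"][u, obs["A"]]
                          * Ps["B"][u, obs["B"]] * Ps["C"][r, obs["C"]])
            site_L += prop * L
        total += np.log(site_L)
    assert lnl == pytest.approx(total, abs=1e-8)


def test_likelihood_invariant_to_rerooting():
    tree1 = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.3):0.1);")
    # same unrooted tree rerooted along the terminal branch to A
    tree2b = PhyloTree.from_newick("((B:0.2,(C:0.15,D:0.3):0.15):0.05,A:0.05);")
    aln, _ = simulate_alignment(tree1, 0.4, kappa=2.0, n_codons=20, seed=5)
    spec = ModelSpec("branch_one_ratio")
    l1 = log_likelihood(aln, tree1, spec, {"omega": 0.4}, 2.0, pi=PI)
    l2 = log_likelihood(aln, tree2b, spec, {"omega": 0.4}, 2.0, pi=PI)
    assert l1 == pytest.approx(l2, abs=1e-8)


def test_missing_states_contribute_all_ones():
    tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
    codes = np.array([[0, 1, -1], [0, 1, -1]], dtype=np.int16)
    aln3 = CodonAlignment(taxa=["A", "B"], codes=codes)
    aln2 = CodonAlignment(taxa=["A", "B"], codes=codes[:, :2])
    spec = ModelSpec("branch_one_ratio")
    l3 = log_likelihood(aln3, tree, spec, {"omega": 0.5}, 2.0, pi=PI)
    l2 = log_likelihood(aln2, tree, spec, {"omega": 0.5}, 2.0, pi=PI)
    # a fully missing column multiplies the likelihood by exactly 1
    assert l3 == pytest.approx(l2, abs=1e-10)


def test_partitioned_spec_requires_tags():
    tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
    aln, _ = simulate_alignment(tree, 0.4, kappa=2.0, n_codons=5, seed=3)
    with pytest.raises(ValueError, match="foreground"):
        log_likelihood(
            aln, tree, ModelSpec("branch_two_ratio"),
            {"omega_bg": 0.2, "omega_fg": 0.8}, 2.0, pi=PI,
        )


# ---------------------------------------------------------------------------
# fitting


def test_fixed_omega_fit_never_beats_free_omega(five_taxon_tree):
    aln, _ = simulate_alignment(five_taxon_tree, 0.3, kappa=2.0, n_codons=150, seed=8)
    opts = FitOptions(n_starts=1)
    fB = fit(aln, five_taxon_tree, ModelSpec("branch_fixed1"), opts)
    fA = fit(aln, five_taxon_tree, ModelSpec("branch_one_ratio"),
             FitOptions(n_starts=1, warm_start=fB))
    assert fA.lnL >= fB.lnL - 1e-6
    assert fA.np == fB.np + 1


def test_np_accounting(five_taxon_tree):
    from cetataste.codon_models import n_free_parameters

    nb = five_taxon_tree.n_branches
    assert n_free_parameters(ModelSpec("branch_fixed1"), five_taxon_tree) == nb + 1
    assert n_free_parameters(ModelSpec("branch_one_ratio"), five_taxon_tree) == nb + 2
    assert n_free_parameters(ModelSpec("branch_two_ratio"), five_taxon_tree) == nb + 3
    assert n_free_parameters(ModelSpec("branch_free"), five_taxon_tree) == 2 * nb + 1
    assert n_free_parameters(ModelSpec("site_M1a"), five_taxon_tree) == nb + 3
    assert n_free_parameters(ModelSpec("site_M2a"), five_taxon_tree) == nb + 5
    assert n_free_parameters(ModelSpec("site_M8"), five_taxon_tree) == nb + 5
    assert n_free_parameters(ModelSpec("site_M8a"), five_taxon_tree) == nb + 4
    assert n_free_parameters(ModelSpec("clade_C"), five_taxon_tree) == nb + 6
    assert n_free_parameters(ModelSpec("clade_M2a_rel"), five_taxon_tree) == nb + 5
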