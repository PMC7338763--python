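"""Codon model construction, pruning likelihood, fitting, LRT, BH."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from c4recruit.selection_test import (CODONS, N_CODONS,
                                      BranchSiteParams, CodonAlignment,
                                      _TransitionCache, bh_adjust,
                                      branch_site_loglik, codon_rate_matrix,
                                      codon_alignment_from_strings, fit_alt,
                                      fit_null, lrt, mixture_rate_factor,
                                      parse_foreground_newick,
                                      simulate_codon_alignment,
                                      site_class_posteriors)
from c4recruit.seq_core import read_newick_string


# ---------------------------------------------------------------------------
# rate matrix

def test_codon_universe_is_61_sense_codons():
    assert N_CODONS == 61
    assert "TAA" not in CODONS and "TGA" not in CODONS and "TAG" not in CODONS


def test_rate_matrix_rows_sum_to_zero_and_symmetric():
    q = codon_rate_matrix(kappa=2.5, omega=0.3)
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
    off = q - np.diag(np.diag(q))
    assert np.allclose(off, off.T)  # uniform frequencies -> symmetric
    assert np.allclose(-np.diag(q).mean(), 1.0)  # mean rate 1


def test_rate_matrix_neutral_equal_rates():
    q = codon_rate_matrix(kappa=1.0, omega=1.0)
    vals = np.unique(np.round(q[q > 0], 12))
    assert len(vals) == 1  # all allowed changes share one rate


def test_multi_nucleotide_changes_forbidden():
    q = codon_rate_matrix(kappa=2.0, omega=0.5)
    i = CODONS.index("TTT")
    j = CODONS.index("GGG")
    assert q[i, j] == 0.0


def test_transition_probabilities_match_expm_and_are_stochastic():
    kappa, omega = 2.0, 0.4
    cache = _TransitionCache(kappa, omega)
    q = codon_rate_matrix(kappa, omega)
    for t in (0.0, 0.01, 0.3, 2.0):
        p = cache.prob(t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all()
        assert np.allclose(p, expm(q * t), atol=1e-10)


def test_stationary_distribution_uniform():
    p = _TransitionCache(2.0, 0.5).prob(500.0)
    assert np.allclose(p, 1.0 / 61, atol=1e-8)


# ---------------------------------------------------------------------------
# pruning likelihood

def _brute_force_loglik(ca, params):
    """Sum over all internal-node codon assignments (tiny trees only)."""
    tree = ca.tree
    internals = [n for n in tree.postorder() if not n.is_tip]
    factor = mixture_rate_factor(params)
    caches = {w: _TransitionCache(params.kappa, w, factor)
              for w in {params.omega0, 1.0, params.omega2}}
    props = params.class_proportions()
    n_sites = ca.n_codons
    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for (bg, fg), prop in zip(params.class_omegas(), props):
            if prop == 0:
                continue
            lik = 0.0
            for assign in itertools.product(range(N_CODONS),
                                            repeat=len(internals)):
                labels = {n.id: s for n, s in zip(internals, assign)}
                for tip in tree.postorder():
                    if tip.is_tip:
                        labels[tip.id] = ca.codons[tip.id][site]
                pr = 1.0 / N_CODONS
                for node in tree.postorder():
                    if node.parent is None:
                        continue
                    w = fg if node.id in ca.foreground else bg
                    p = caches[w].prob(node.length * params.scale)
                    pr *= p[labels[node.parent.id], labels[node.id]]
                lik += pr
            site_lik += prop * lik
        total += np.log(site_lik)
    return total


def test_pruning_equals_brute_force_on_two_internal_node_tree():
    tree = read_newick_string("((a:0.3,b:0.2)i1:0.25,c:0.4)r;")
    rng = np.random.default_rng(0)
    ca = CodonAlignment(
        codons={sp: rng.integers(0, 61, size=4) for sp in "abc"},
        tree=tree, foreground=frozenset({"i1", "a"}))
    params = BranchSiteParams(kappa=2.0, omega0=0.3, omega2=4.0,
                              p0=0.5, p1=0.3)
    assert branch_site_loglik(ca, params) == pytest.approx(
        _brute_force_loglik(ca, params), abs=1e-8)


def test_two_identical_codons_zero_branches_give_uniform_probability():
    tree = read_newick_string("(a:0.0,b:0.0)r;")
    idx = CODONS.index("ATG")
    ca = CodonAlignment(codons={"a": np.array([idx]), "b": np.array([idx])},
                        tree=tree, foreground=frozenset())
    params = BranchSiteParams(kappa=1.0, omega0=0.5, omega2=1.0,
                              p0=0.6, p1=0.2)
    assert branch_site_loglik(ca, params) == pytest.approx(np.log(1 / 61))


def test_likelihood_invariant_to_tip_order_and_site_order(eight_taxon_tree):
    rng = np.random.default_rng(5)
    truth = BranchSiteParams(kappa=2.0, omega0=0.2, omega2=1.0,
                             p0=0.6, p1=0.3)
    ca = simulate_codon_alignment(eight_taxon_tree, {"i3", "e", "f"}, truth,
                                  40, rng)
    base = branch_site_loglik(ca, truth)
    perm = rng.permutation(40)
    shuffled = CodonAlignment(
        codons={sp: arr[perm] for sp, arr in ca.codons.items()},
        tree=ca.tree, foreground=ca.foreground)
    assert branch_site_loglik(shuffled, truth) == pytest.approx(base)


# ---------------------------------------------------------------------------
# alignment construction

def test_codon_alignment_drops_gap_and_stop_columns():
    tree = read_newick_string("(a:0.1,b:0.1)r;")
    seqs = {"a": "ATGTAAGCG---", "b": "ATGCCCGCGAAA"}
    ca = codon_alignment_from_strings(seqs, tree, frozenset())
    # column 2 has a stop in a, column 4 has a gap in a -> 2 columns kept
    assert ca.n_codons == 2
    assert [CODONS[i] for i in ca.codons["a"]] == ["ATG", "GCG"]


def test_foreground_newick_hash_tags():
    tree, fg = parse_foreground_newick("((a:1,b:1)n1#1:1,(c:1,d:1)n2:1)r;")
    assert fg == {"n1"}
    assert tree.tips_under("n1") == {"a", "b"}


# ---------------------------------------------------------------------------
# fitting and LRT

def test_alt_never_below_null_and_kappa_recovered(eight_taxon_tree):
    truth = BranchSiteParams(kappa=2.0, omega0=0.2, omega2=1.0,
                             p0=0.55, p1=0.35)
    ca = simulate_codon_alignment(eight_taxon_tree, {"i3", "e", "f"}, truth,
                                  1000, np.random.default_rng(11))
    null = fit_null(ca, n_starts=2)
    alt = fit_alt(ca, null_fit=null, n_starts=2)
    assert alt.lnL >= null.lnL - 1e-6
    assert null.converged
    assert abs(null.params.kappa - truth.kappa) / truth.kappa < 0.2


def test_lrt_chi_square_quantile():
    res = lrt(-1000.0, -1000.0 + 3.841 / 2)
    assert res.statistic == pytest.approx(3.841)
    assert res.p == pytest.approx(0.05, abs=5e-4)
    assert lrt(-10.0, -11.0).statistic == 0.0  # clipped at zero


@pytest.mark.parametrize("ps,expected", [
    ([0.01], [0.01]),
    ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
    ([0.01, 0.04], [0.02, 0.04]),
    ([], []),
])
def test_bh_adjust_hand_computed(ps, expected):
    assert bh_adjust(ps) == pytest.approx(expected)


def test_site_class_posteriors_shape_and_simplex(eight_taxon_tree):
    truth = BranchSiteParams(kappa=2.0, omega0=0.2, omega2=2.0,
                             p0=0.5, p1=0.3)
    ca = simulate_codon_alignment(eight_taxon_tree, {"i3", "e", "f"}, truth,
                                  30, np.random.default_rng(3))
    post = site_class_posteriors(ca, truth)
    assert post.shape == (30, 4)
    assert np.allclose(post.sum(axis=1), 1.0)


def test_simulation_is_seed_deterministic(eight_taxon_tree):
    truth = BranchSiteParams(kappa=2.0, omega0=0.2, omega2=1.0,
                             p0=0.6, p1=0.3)
    a = simulate_codon_alignment(eight_taxon_tree, {"e"}, truth, 25,
                                 np.random.default_rng(7))
    b = simulate_codon_alignment(eight_taxon_tree, {"e"}, truth, 25,
                                 np.random.default_rng(7))
    assert all(np.array_equal(a.codons[sp], b.codons[sp]) for sp in a.codons)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        BranchSiteParams(kappa=-1.0, omega0=0.5, omega2=1.0, p0=0.5, p1=0.3)
    with pytest.raises(ValueError):
        BranchSiteParams(kappa=1.0, omega0=0.5, omega2=0.5, p0=0.5, p1=0.3)
    with pytest.raises(ValueError):
        BranchSiteParams(kappa=1.0, omega0=0.5, omega2=1.0, p0=0.8, p1=0.4)
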