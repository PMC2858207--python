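"""Rho statistic, its Poisson standard error, and age conversion."""

import numpy as np
import pytest

from mitorho.dating import (
    DatingError,
    build_age_table,
    complete_genome_clock,
    compute_rho,
    compute_sigma,
    estimate_clade_age,
    make_selector,
    monotone_correction,
    rho_to_age,
    synonymous_clock,
)
from mitorho.phylogeny import build_mp_tree
from mitorho.variants import TRANSITION_PARTNER, Variant


def _transitions(ref, positions):
    return {Variant(p, "transition", TRANSITION_PARTNER[ref.base(p)]) for p in positions}


def _star_profiles(ref, counts, start=1000, step=10):
    """Disjoint private variant sets of the given sizes (a star genealogy)."""
    profs = []
    pos = start
    for i, k in enumerate(counts):
        profs.append((f"T{i}", _transitions(ref, range(pos, pos + step * k, step))))
        pos += step * (k + 1)
    return profs


def test_rho_zero_for_single_founder_tip(ref):
    tree = build_mp_tree([("A", set())])
    rho, n = compute_rho(tree, tree.root)
    assert (rho, n) == (0.0, 1)
    assert compute_sigma(tree, tree.root) == 0.0


def test_star_rho_and_sigma_hand_computed(ref):
    # 4 tips with 1, 2, 3, 2 private mutations: rho = 2, sigma^2 = 8/16 = 0.5
    tree = build_mp_tree(_star_profiles(ref, [1, 2, 3, 2]))
    rho, n = compute_rho(tree, tree.root)
    sigma = compute_sigma(tree, tree.root)
    assert rho == 2.0 and n == 4
    assert sigma == pytest.approx(np.sqrt(0.5), abs=1e-12)


def test_nested_clade_hand_computed(ref):
    # founder -1 mutation-> internal node with two tips, 1 further mutation each:
    # rho = (2+2)/2 = 2; sigma^2 = (2^2*1 + 1 + 1)/4 = 1.5
    shared = _transitions(ref, [500])
    a = shared | _transitions(ref, [600])
    b = shared | _transitions(ref, [700])
    tree = build_mp_tree([("A", a), ("B", b)])
    rho, n = compute_rho(tree, tree.root)
    sigma = compute_sigma(tree, tree.root)
    assert rho == 2.0 and n == 2
    assert sigma == pytest.approx(np.sqrt(1.5), abs=1e-12)


def test_star_closed_form_sigma_sq_equals_rho_over_n(ref):
    """For any star clade sigma^2 = rho/n exactly (100 random stars)."""
    rng = np.random.default_rng(31)
    for _ in range(100):
        k = int(rng.integers(2, 12))
        counts = [int(rng.integers(0, 7)) for _ in range(k)]
        tree = build_mp_tree(_star_profiles(ref, counts))
        rho, n = compute_rho(tree, tree.root)
        sigma = compute_sigma(tree, tree.root)
        assert sigma**2 == pytest.approx(rho / n, abs=1e-10)


def test_rho_uses_haplotype_multiplicities(ref):
    # two individuals share a haplotype: both count
    profs = [("A", _transitions(ref, [500])), ("B", _transitions(ref, [500])), ("C", set())]
    tree = build_mp_tree(profs)
    rho, n = compute_rho(tree, tree.root)
    assert n == 3
    assert rho == pytest.approx(2.0 / 3.0)


def test_clock_conversions():
    assert rho_to_age(1.0, 0.0, complete_genome_clock())[0] == pytest.approx(3624.0)
    assert rho_to_age(1.0, 0.0, synonymous_clock())[0] == pytest.approx(7884.0)
    assert rho_to_age(0.0, 0.0, complete_genome_clock()) == (0.0, 0.0, 0.0)


def test_ci_floored_at_zero_and_linear():
    age, lo, hi = rho_to_age(0.5, 1.0, complete_genome_clock())
    assert lo == 0.0 and hi > age > 0
    a1 = rho_to_age(1.0, 0.2, complete_genome_clock())
    a3 = rho_to_age(3.0, 0.6, complete_genome_clock())
    assert a3[0] == pytest.approx(3 * a1[0])
    assert a3[2] == pytest.approx(3 * a1[2])


def test_negative_inputs_rejected():
    with pytest.raises(DatingError):
        rho_to_age(-1.0, 0.0, complete_genome_clock())


def test_monotone_correction_applies():
    corr = monotone_correction([(10000, 8000), (20000, 14000)])
    clock = complete_genome_clock(correction=corr)
    assert clock.correct(0.0) == 0.0
    assert clock.correct(10000.0) == pytest.approx(8000.0)
    assert clock.correct(15000.0) == pytest.approx(11000.0)
    with pytest.raises(DatingError):
        monotone_correction([(10, 5), (20, 4)])


def test_sigma_matches_parametric_bootstrap_single_tree(ref):
    """Poisson-resampled edge counts reproduce sigma within 5% (20k reps)."""
    import mitorho as m

    spec = m.SimulationSpec(topology="yule", n_tips=20, founder_age_years=25000, seed=13)
    res = m.simulate_dataset(spec, ref, emit_sequences=False)
    tree = res.truth.tree
    sigma = compute_sigma(tree, tree.root)
    # independent bootstrap: gather (n_e, l_e) by direct traversal
    edges = []

    def walk(node):
        below = node.multiplicity
        for child in node.children:
            below += walk(child)
        if node is not tree.root:
            edges.append((below, len(node.events)))
        return below

    n = walk(tree.root)
    n_e = np.array([e[0] for e in edges])
    l_e = np.array([e[1] for e in edges])
    rng = np.random.default_rng(77)
    draws = rng.poisson(l_e, size=(20000, len(l_e)))
    rhos = draws @ n_e / n
    assert np.std(rhos, ddof=1) == pytest.approx(sigma, rel=0.05)


def test_synonymous_selector_counts_only_synonymous(ref):
    from mitorho.phylogeny import MutationEvent
    from mitorho.scoring import SYNONYMOUS, annotate_synonymous

    sel = make_selector(synonymous_clock(), ref)
    rng = np.random.default_rng(8)
    from conftest import random_variant

    seen = {True: 0, False: 0}
    for _ in range(200):
        v = random_variant(rng, ref)
        got = sel(MutationEvent(v))
        expected = v.is_substitution and annotate_synonymous(ref, v) == SYNONYMOUS
        assert got == expected
        seen[expected] += 1
    assert seen[True] > 0 and seen[False] > 0


def test_age_table_consistent_with_direct_recomputation(ref):
    profs = (
        [(f"A{i}", _transitions(ref, [500]) | _transitions(ref, [600 + 10 * i])) for i in range(3)]
        + [(f"B{i}", _transitions(ref, [2000]) | _transitions(ref, [2100 + 10 * i])) for i in range(4)]
        + [("C0", _transitions(ref, [3000]))]
    )
    tree = build_mp_tree(profs)
    members = {
        "cladeA": [f"A{i}" for i in range(3)],
        "cladeB": [f"B{i}" for i in range(4)],
        "all": [sid for sid, _ in profs],
        "empty": [],
    }
    clocks = [complete_genome_clock(), synonymous_clock()]
    table = build_age_table(tree, members, clocks, ref).set_index("clade")
    assert table.loc["all", "n"] == len(profs)
    assert table.loc["empty", "flag"] == "empty clade"
    for clade, ids in members.items():
        if not ids:
            continue
        tips = [tree.find_tip(s) for s in ids]
        root = tree.mrca(tips)
        for clock in clocks:
            est = estimate_clade_age(tree, root, clock, ref, clade)
            assert table.loc[clade, f"rho_{clock.name}"] == pytest.approx(est.rho)
            assert table.loc[clade, f"age_ky_{clock.name}"] == pytest.approx(est.age_years / 1000)


def test_clade_root_not_in_tree_rejected(ref):
    from mitorho.phylogeny import TreeNode

    tree = build_mp_tree([("A", _transitions(ref, [500]))])
    with pytest.raises(DatingError):
        compute_rho(tree, TreeNode(999))
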