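"""Most-parsimonious tree construction, homoplasy annotation, newick IO."""

import numpy as np
import pytest

import mitorho as m
from mitorho.phylogeny import (
    PhylogenyError,
    annotate_homoplasies,
    build_mp_tree,
    exhaustive_mp_oracle,
    parse_annotated_newick,
    tree_to_newick,
)


def test_perfect_phylogeny_conflict_free(P):
    profs = [("A", {P("73")}), ("B", {P("73"), P("150")}), ("C", {P("263")})]
    tree = build_mp_tree(profs)
    assert tree.n_events() == 3
    assert annotate_homoplasies(tree).is_empty()
    # perfect-phylogeny case: length equals the number of distinct variants
    assert tree.n_events() == 3 == len({v for _, vs in profs for v in vs})


def test_identical_profiles_collapse_with_multiplicity(P):
    profs = [("A", {P("73")}), ("B", {P("73")}), ("C", set())]
    tree = build_mp_tree(profs)
    tip = tree.find_tip("A")
    assert sorted(tip.samples) == ["A", "B"]
    assert tree.n_samples() == 3


def test_oracle_trivial_cases(P):
    assert exhaustive_mp_oracle([("A", {P("73"), P("150")})]) == 2
    assert exhaustive_mp_oracle([("A", {P("73")}), ("B", {P("150")})]) == 2
    triple = [
        ("A", {P("73"), P("150")}),
        ("B", {P("73"), P("263")}),
        ("C", {P("150"), P("263")}),
    ]
    assert build_mp_tree(triple).n_events() == exhaustive_mp_oracle(triple)


def test_oracle_refuses_large_instances(P):
    profs = [(f"S{i}", {P(str(100 + 7 * i))}) for i in range(9)]
    with pytest.raises(PhylogenyError, match="refuses"):
        exhaustive_mp_oracle(profs)


def test_engineered_incompatibility_matches_oracle(P):
    profs = [
        ("A", {P("73"), P("150"), P("263")}),
        ("B", {P("73"), P("150")}),
        ("C", {P("73"), P("263")}),
        ("D", {P("152")}),
        ("E", {P("152"), P("263")}),
        ("F", set()),
    ]
    tree = build_mp_tree(profs)
    assert tree.n_events() == exhaustive_mp_oracle(profs)


def test_parallel_mutation_reported(P):
    # np 16311 acquired independently in two subclades
    profs = [
        ("A", {P("73"), P("16311")}),
        ("B", {P("73")}),
        ("C", {P("263"), P("16311")}),
        ("D", {P("263")}),
    ]
    tree = build_mp_tree(profs)
    report = annotate_homoplasies(tree)
    assert report.origins["16311"] == 2
    assert "16311" in report.parallel_labels


def test_back_mutation_from_root_state(P):
    # founder carries 16192; one lineage reverts it
    root_state = {P("16192")}
    profs = [("A", set()), ("B", {P("16192")}), ("C", {P("16192"), P("73")})]
    tree = build_mp_tree(profs, root_state=root_state)
    report = annotate_homoplasies(tree)
    assert report.reversions.get("16192") == 1
    assert tree.n_events() == 2


def test_homoplasy_counts_equal_edge_occurrences(ref):
    """origins + reversions equals the number of edges carrying the variant."""
    spec = m.SimulationSpec(topology="yule", n_tips=40, founder_age_years=30000,
                            seed=5, n_hotspots=8, hotspot_rate=200)
    res = m.simulate_dataset(spec, ref, emit_sequences=False)
    tree = res.truth.tree
    report = annotate_homoplasies(tree)
    occurrences = {}
    for node in tree.nodes():
        for ev in node.events:
            lab = ev.variant.label
            occurrences[lab] = occurrences.get(lab, 0) + 1
    for lab, n_occ in occurrences.items():
        assert report.origins.get(lab, 0) + report.reversions.get(lab, 0) == n_occ


def test_path_property_on_simulated_data(ref):
    from mitorho.scoring import filter_variants

    spec = m.SimulationSpec(topology="yule", n_tips=30, founder_age_years=20000, seed=9)
    res = m.simulate_dataset(spec, ref, emit_sequences=False)
    profiles = {sid: filter_variants(v) for sid, v in res.truth.tip_variants.items()}
    tree = build_mp_tree(sorted(profiles.items()))
    tree.check_path_property(profiles)  # raises on violation


def _random_instance(rng, ref, n_taxa, n_sites):
    """Profiles from mutations dropped on a random genealogy over few sites."""
    from mitorho.variants import TRANSITION_PARTNER, Variant

    positions = rng.choice(np.arange(1000, 1000 + 40 * n_sites, 40), size=n_sites, replace=False)
    sites = [Variant(int(p), "transition", TRANSITION_PARTNER[ref.base(int(p))]) for p in positions]
    # random rooted binary tree by sequential joins
    nodes = list(range(n_taxa))
    parents = {}
    nxt = n_taxa
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parents[a] = parents[b] = nxt
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    root = nodes[0]
    n_mut = int(rng.integers(n_sites // 2, 2 * n_sites))
    edge_muts = {x: [] for x in range(nxt) if x != root}
    for _ in range(n_mut):
        edge = int(rng.integers(nxt - 1))
        if edge != root and edge in edge_muts:
            edge_muts[edge].append(sites[int(rng.integers(n_sites))])
    profs = []
    for taxon in range(n_taxa):
        state = set()
        x = taxon
        while x in parents:
            for v in edge_muts.get(x, []):
                state.symmetric_difference_update({v})
            x = parents[x]
        profs.append((f"T{taxon}", frozenset(state)))
    return profs


def test_mp_length_matches_oracle_on_random_instances(ref):
    rng = np.random.default_rng(2718)
    for _ in range(10):
        n_taxa = int(rng.integers(4, 8))
        n_sites = int(rng.integers(4, 10))
        profs = _random_instance(rng, ref, n_taxa, n_sites)
        assert build_mp_tree(profs).n_events() == exhaustive_mp_oracle(profs)


def test_determinism_and_permutation_invariance(ref):
    from mitorho.scoring import filter_variants

    spec = m.SimulationSpec(topology="yule", n_tips=20, founder_age_years=20000, seed=3)
    res = m.simulate_dataset(spec, ref, emit_sequences=False)
    profiles = [(sid, filter_variants(v)) for sid, v in sorted(res.truth.tip_variants.items())]
    nwk1 = tree_to_newick(build_mp_tree(profiles))
    nwk2 = tree_to_newick(build_mp_tree(profiles))
    assert nwk1 == nwk2  # byte-identical on identical input
    rng = np.random.default_rng(0)
    shuffled = list(profiles)
    rng.shuffle(shuffled)
    assert tree_to_newick(build_mp_tree(shuffled)) == nwk1


def test_nonpositive_weights_rejected(P):
    with pytest.raises(PhylogenyError, match="weight"):
        build_mp_tree([("A", {P("73")})], weights={"73": 0.0})


def test_empty_input_rejected():
    with pytest.raises(PhylogenyError):
        build_mp_tree([])


# -- newick serialization ---------------------------------------------------


def test_newick_round_trip_three_tips(ref, P):
    profs = [("A", {P("73")}), ("B", {P("73"), P("150")}), ("C", set())]
    tree = build_mp_tree(profs)
    text = tree_to_newick(tree)
    again = parse_annotated_newick(text, ref)
    assert tree_to_newick(again) == text


def test_newick_round_trip_back_mutation_marker(ref, P):
    root_state = {P("16192")}
    profs = [("A", set()), ("B", {P("16192")})]
    tree = build_mp_tree(profs, root_state=root_state)
    text = tree_to_newick(tree)
    assert "16192!" in text
    again = parse_annotated_newick(text, ref)
    assert tree_to_newick(again) == text
    assert again.root_state == frozenset(root_state)


def test_newick_round_trip_zero_length_edges(ref, P):
    # a sampled ancestor sits on a zero-mutation pendant edge
    profs = [("A", {P("73")}), ("B", {P("73"), P("150")})]
    tree = build_mp_tree(profs)
    text = tree_to_newick(tree)
    assert ":0" in text
    assert tree_to_newick(parse_annotated_newick(text, ref)) == text


def test_newick_parseable_by_dendropy(ref, P, tmp_path):
    dendropy = pytest.importorskip("dendropy")
    profs = [("A", {P("73")}), ("B", {P("73"), P("150")}), ("C", {P("263")})]
    tree = build_mp_tree(profs)
    path = tmp_path / "tree.nwk"
    m.write_annotated_newick(tree, path)
    t = dendropy.Tree.get(path=str(path), schema="newick")
    assert len(t.leaf_nodes()) == len(tree.tips())
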