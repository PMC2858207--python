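"""Variant scoring, the exclusion filter, and synonymy annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import random_variant_set
from mitorho.reference import apply_variants
from mitorho.scoring import (
    INDEL,
    NONCODING,
    NONSYNONYMOUS,
    RNA_GENE,
    SYNONYMOUS,
    ScoringConfig,
    ScoringError,
    annotate_synonymous,
    filter_variants,
    score_variants,
)
from mitorho.variants import COMPLEMENT, TRANSITION_PARTNER, Variant


def test_reference_scores_empty_against_itself(ref):
    assert score_variants(ref, ref.sequence) == frozenset()


def test_transversion_classified(ref, P):
    seq = apply_variants(ref, {P("16114A")})
    (v,) = score_variants(ref, seq)
    assert v.kind == "transversion" and v.label == "16114A"


def test_n_is_missing_data_not_variant(ref):
    seq = ref.sequence[:100] + "N" + ref.sequence[101:]
    assert score_variants(ref, seq) == frozenset()


def test_low_identity_rejected(ref):
    rng = np.random.default_rng(0)
    garbage = "".join(rng.choice(list("ACGT"), size=len(ref.sequence)))
    with pytest.raises(ScoringError, match="not homologous"):
        score_variants(ref, garbage)


def test_non_nucleotide_rejected(ref):
    with pytest.raises(ScoringError):
        score_variants(ref, ref.sequence[:-1] + "Z")


# -- filtering --------------------------------------------------------------


def test_filter_default_rule_examples(ref, P):
    # insertion inside 303-315 excluded
    assert filter_variants({P("309.1C")}) == frozenset()
    # transition inside 16180-16193 retained
    assert filter_variants({P("16192")}) == {P("16192")}
    # transversion outside the ranges retained
    assert filter_variants({P("16114A")}) == {P("16114A")}
    # transversion inside 303-315 excluded
    inside = Variant(305, "transversion", [b for b in "ACGT" if b not in (ref.base(305), TRANSITION_PARTNER[ref.base(305)])][0])
    assert filter_variants({inside}) == frozenset()
    # deletion inside 16180-16193 excluded, outside retained
    assert filter_variants({P("16183d")}) == frozenset()
    assert filter_variants({P("249d")}) == {P("249d")}


def test_filter_idempotent_and_preserves_transitions(ref):
    rng = np.random.default_rng(5)
    for _ in range(50):
        variants = random_variant_set(rng, ref, 10, min_spacing=1)
        once = filter_variants(variants)
        assert filter_variants(once) == once
        n_ts = sum(1 for v in variants if v.kind == "transition")
        assert sum(1 for v in once if v.kind == "transition") == n_ts


def test_filter_genome_wide_indel_switch(ref, P):
    cfg = ScoringConfig(exclude_indels_genome_wide=True)
    assert filter_variants({P("249d"), P("16192")}, cfg) == {P("16192")}


def test_filter_extra_excluded_positions(ref, P):
    # user-supplied hotspot exclusions drop every variant kind at those nps
    cfg = ScoringConfig(extra_excluded_positions=frozenset({16114, 16519}))
    assert filter_variants({P("16114A"), P("16519"), P("73")}, cfg) == {P("73")}


# -- synonymy ---------------------------------------------------------------


def test_annotate_control_region_and_indel(ref, P):
    assert annotate_synonymous(ref, P("16311")) == NONCODING
    assert annotate_synonymous(ref, P("249d")) == INDEL
    assert annotate_synonymous(ref, P("309.1C")) == INDEL


def test_annotate_rna_gene(ref):
    # np 700 lies in the small (12S) rRNA gene
    v = Variant(700, "transition", TRANSITION_PARTNER[ref.base(700)])
    assert annotate_synonymous(ref, v) == RNA_GENE


def _protein_oracle(ref, gene, pos, new_base):
    """Translate the whole gene before/after the substitution (table 2)."""
    seq = ref.sequence[gene.start - 1 : gene.end]
    idx = pos - gene.start
    mut = seq[:idx] + new_base + seq[idx + 1 :]
    if gene.strand == "-":
        seq = "".join(COMPLEMENT[b] for b in reversed(seq))
        mut = "".join(COMPLEMENT[b] for b in reversed(mut))
    pad = (3 - len(seq) % 3) % 3
    seq += "A" * pad
    mut += "A" * pad
    return str(Seq(seq).translate(table=2)) == str(Seq(mut).translate(table=2))


def test_synonymy_matches_whole_protein_oracle(ref):
    """500 random coding substitutions vs full-gene translation."""
    rng = np.random.default_rng(11)
    single_cover = []
    for g in ref.coding_table:
        if g.kind != "protein":
            continue
        for pos in range(g.start, g.end + 1):
            if len([h for h in ref.genes_at(pos) if h.kind == "protein"]) == 1:
                single_cover.append((g, pos))
    idx = rng.choice(len(single_cover), size=500, replace=False)
    for i in idx:
        gene, pos = single_cover[int(i)]
        refbase = ref.base(pos)
        options = [b for b in "ACGT" if b != refbase]
        new = options[int(rng.integers(3))]
        kind = "transition" if TRANSITION_PARTNER[refbase] == new else "transversion"
        got = annotate_synonymous(ref, Variant(pos, kind, new))
        expected = SYNONYMOUS if _protein_oracle(ref, gene, pos, new) else NONSYNONYMOUS
        assert got == expected, f"np {pos} in {gene.name}"


def test_overlapping_genes_require_synonymy_in_both_frames(ref):
    # ATP8/ATP6 overlap: synonymous only if synonymous in every frame
    atp8 = next(g for g in ref.coding_table if g.name == "MT-ATP8")
    atp6 = next(g for g in ref.coding_table if g.name == "MT-ATP6")
    rng = np.random.default_rng(3)
    checked = 0
    for pos in range(atp6.start, atp8.end + 1):
        refbase = ref.base(pos)
        for new in "ACGT":
            if new == refbase:
                continue
            kind = "transition" if TRANSITION_PARTNER[refbase] == new else "transversion"
            got = annotate_synonymous(ref, Variant(pos, kind, new))
            expected = (
                SYNONYMOUS
                if _protein_oracle(ref, atp8, pos, new) and _protein_oracle(ref, atp6, pos, new)
                else NONSYNONYMOUS
            )
            assert got == expected
            checked += 1
    assert checked > 100


def test_np_9293_label_computed_from_coding_table(ref):
    # np 9293 lies in MT-CO3; the label must agree with the translation oracle
    gene = next(g for g in ref.coding_table if g.name == "MT-CO3")
    assert gene.start <= 9293 <= gene.end
    v = Variant(9293, "transition", TRANSITION_PARTNER[ref.base(9293)])
    expected = SYNONYMOUS if _protein_oracle(ref, gene, 9293, v.derived) else NONSYNONYMOUS
    assert annotate_synonymous(ref, v) == expected


def test_scored_variants_match_simulator_truth(ref):
    """Apply-then-score is exact on simulated genomes (after filtering both)."""
    import mitorho as m

    spec = m.SimulationSpec(topology="yule", n_tips=25, founder_age_years=25000, seed=42,
                            founder_variants=("3197", "14793"))
    res = m.simulate_dataset(spec, ref)
    for header, seq in res.records:
        sid = header.split("|")[0]
        scored = filter_variants(score_variants(ref, seq))
        truth = filter_variants(res.truth.tip_variants[sid])
        assert scored == truth
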