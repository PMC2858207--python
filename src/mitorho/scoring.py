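"""Score sample genomes against the reference and classify mutations.

Differences are called from a global pairwise alignment (edlib), classified
as transitions/transversions by purine-pyrimidine class, and indels are
normalized to their 3'-most equivalent position (standard forensic mtDNA
practice).  The default filter removes point indels and transversions inside
the two homopolymeric tracts nps 16180-16193 and 303-315, where replication
slippage makes those changes phylogenetically uninformative; transitions are
retained everywhere, and indels/transversions outside the tracts are kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import edlib
import yaml
from Bio.Seq import Seq

from .reference import ReferenceGenome
from .variants import (
    COMPLEMENT,
    DELETION,
    INSERTION,
    TRANSITION,
    TRANSITION_PARTNER,
    TRANSVERSION,
    Variant,
    VariantError,
)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"
RNA_GENE = "rna_gene"
INDEL = "indel"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringConfig:
    """Exclusion rules applied to scored variants.

    Defaults reproduce the rule used throughout this pipeline: insertions,
    deletions and transversions located within nps 16180-16193 and 303-315
    are excluded from phylogenetic analysis; transitions are never excluded.
    Set ``exclude_indels_genome_wide`` to drop all indels regardless of
    position (an alternative, stricter reading of the same rule).
    """

    excluded_ranges: tuple[tuple[int, int], ...] = ((16180, 16193), (303, 315))
    exclusion_kinds: frozenset[str] = frozenset({INSERTION, DELETION, TRANSVERSION})
    extra_excluded_positions: frozenset[int] = frozenset()
    exclude_indels_genome_wide: bool = False
    treat_n_as_missing: bool = True
    min_identity: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "excluded_ranges" in raw:
            kwargs["excluded_ranges"] = tuple((int(a), int(b)) for a, b in raw["excluded_ranges"])
        if "exclusion_kinds" in raw:
            kwargs["exclusion_kinds"] = frozenset(raw["exclusion_kinds"])
        if "extra_excluded_positions" in raw:
            kwargs["extra_excluded_positions"] = frozenset(int(p) for p in raw["extra_excluded_positions"])
        for key in ("exclude_indels_genome_wide", "treat_n_as_missing"):
            if key in raw:
                kwargs[key] = bool(raw[key])
        if "min_identity" in raw:
            kwargs["min_identity"] = float(raw["min_identity"])
        return cls(**kwargs)


def _right_align_deletion(ref: str, a: int, b: int) -> tuple[int, int]:
    # deletion of ref[a..b] (0-based inclusive); shift right while equivalent
    n = len(ref)
    while b + 1 < n and ref[b + 1] == ref[a]:
        a += 1
        b += 1
    return a, b


def _right_align_insertion(ref: str, p: int, ins: str) -> tuple[int, str]:
    # insertion of string `ins` after 0-based ref index p (p = -1 for before start)
    n = len(ref)
    while p + 1 < n and ins and ins[0] == ref[p + 1]:
        ins = ins[1:] + ref[p + 1]
        p += 1
    return p, ins


def score_variants(
    ref: ReferenceGenome,
    sample_sequence: str,
    min_identity: float = 0.95,
) -> frozenset[Variant]:
    """Score one sample sequence against the reference.

    Returns all differences as variants.  ``N`` in the sample is treated as
    missing data, never a variant.  Raises :class:`ScoringError` when the
    alignment identity falls below ``min_identity``.
    """
    sample = sample_sequence.upper()
    for i, b in enumerate(sample):
        if b not in "ACGTN":
            raise ScoringError(f"non-ACGTN character {b!r} at sample position {i + 1}")
    refseq = ref.sequence
    if sample == refseq:
        return frozenset()
    res = edlib.align(sample, refseq, mode="NW", task="path")
    cigar = res["cigar"]
    variants: set[Variant] = set()
    qpos = 0  # sample index
    tpos = 0  # reference index (0-based)
    matches = 0
    aln_len = 0
    for count_s, op in _CIGAR_RE.findall(cigar):
        count = int(count_s)
        aln_len += count
        if op in "=M":
            matches += count
            qpos += count
            tpos += count
        elif op == "X":
            for k in range(count):
                rb = refseq[tpos + k]
                sb = sample[qpos + k]
                if sb == "N":
                    continue  # missing data
                if sb == rb:
                    matches += 1
                    continue
                kind = TRANSITION if TRANSITION_PARTNER[rb] == sb else TRANSVERSION
                variants.add(Variant(tpos + k + 1, kind, sb))
            qpos += count
            tpos += count
        elif op == "D":  # deletion in sample: ref bases absent from sample
            a, b = _right_align_deletion(refseq, tpos, tpos + count - 1)
            for p in range(a, b + 1):
                variants.add(Variant(p + 1, DELETION))
            tpos += count
        elif op == "I":  # insertion in sample
            ins = sample[qpos : qpos + count]
            p, ins = _right_align_insertion(refseq, tpos - 1, ins)
            anchor = p + 1  # 1-based position the insertion follows
            if anchor < 1:
                raise ScoringError("insertion before np 1 is not representable")
            for idx, base in enumerate(ins, start=1):
                if base == "N":
                    continue
                variants.add(Variant(anchor, INSERTION, base, idx))
            qpos += count
    identity = matches / aln_len if aln_len else 0.0
    if identity < min_identity:
        raise ScoringError(
            f"sequence not homologous to reference (identity {identity:.3f} < {min_identity})"
        )
    return frozenset(variants)


def filter_variants(
    variants: Iterable[Variant], config: ScoringConfig | None = None
) -> frozenset[Variant]:
    """Apply the exclusion rules.  Pure and idempotent; the default range rule
    never removes transitions (only user-listed extra positions can)."""
    config = config or ScoringConfig()
    out = set()
    for v in variants:
        if v.position in config.extra_excluded_positions:
            continue
        if v.kind == TRANSITION:
            out.add(v)
            continue
        if config.exclude_indels_genome_wide and v.is_indel:
            continue
        if v.kind in config.exclusion_kinds and any(
            a <= v.position <= b for a, b in config.excluded_ranges
        ):
            continue
        out.add(v)
    return frozenset(out)


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=2))


def _codon_for(ref: ReferenceGenome, gene, pos: int, new_base: str) -> tuple[str, str]:
    """Reference and mutated codon containing np ``pos`` within ``gene``.

    Genes on the light strand are translated from the reverse complement.
    Incomplete terminal codons (completed by polyadenylation in vivo) are
    padded with A.
    """
    seq = ref.sequence[gene.start - 1 : gene.end]
    if gene.strand == "+":
        off = pos - gene.start - gene.frame_offset
        gene_seq = seq
        mut_base = new_base
    else:
        off = gene.end - pos - gene.frame_offset
        gene_seq = "".join(COMPLEMENT[b] for b in reversed(seq))
        mut_base = COMPLEMENT[new_base]
    ci = off // 3
    codon = gene_seq[3 * ci : 3 * ci + 3]
    in_codon = off % 3
    mut = codon[:in_codon] + mut_base + codon[in_codon + 1 :]
    pad = 3 - len(codon)
    if pad:
        codon += "A" * pad
        mut += "A" * pad
    return codon, mut


def annotate_synonymous(ref: ReferenceGenome, variant: Variant) -> str:
    """Classify a variant for the synonymous clock.

    Substitutions in protein-coding genes are translated in context with the
    vertebrate mitochondrial code; a substitution covered by overlapping genes
    is synonymous only if synonymous in every overlapping reading frame.
    Positions in rRNA/tRNA genes are ``rna_gene``; everything outside
    annotated genes (control region included) is ``noncoding``; indels are
    ``indel``.
    """
    if variant.is_indel:
        return INDEL
    genes = ref.genes_at(variant.position)
    proteins = [g for g in genes if g.kind == "protein"]
    if proteins:
        for gene in proteins:
            codon, mut = _codon_for(ref, gene, variant.position, variant.derived)
            if _translate_codon(codon) != _translate_codon(mut):
                return NONSYNONYMOUS
        return SYNONYMOUS
    if genes:
        return RNA_GENE
    return NONCODING


def variant_table(
    profiles_variants: dict[str, Iterable[Variant]],
    ref: ReferenceGenome,
    config: ScoringConfig | None = None,
) -> "pandas.DataFrame":
    """Tab-separated-ready table: sample, label, kind, synonymy, filtered flag."""
    import pandas as pd

    config = config or ScoringConfig()
    rows = []
    for sample_id in sorted(profiles_variants):
        variants = set(profiles_variants[sample_id])
        kept = filter_variants(variants, config)
        for v in sorted(variants, key=Variant.sort_key):
            rows.append(
                {
                    "sample_id": sample_id,
                    "variant": v.label,
                    "kind": v.kind,
                    "synonymy": annotate_synonymous(ref, v),
                    "filtered": v not in kept,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "variant", "kind", "synonymy", "filtered"])
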