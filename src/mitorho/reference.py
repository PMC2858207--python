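"""Reference genome loading, sample input, and variant application.

The coordinate system is 1-based and inclusive, following rCRS convention;
the circular genome is linearized starting at np 1.  The packaged reference
(``data/rcrs_synthetic.fasta``) is a deterministic synthetic stand-in for the
rCRS: real gene coordinates and classic control-region landmark bases, with
pseudo-random sequence elsewhere (see ``scripts/make_synthetic_reference.py``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .variants import (
    DELETION,
    INSERTION,
    MT_LENGTH,
    Variant,
    VariantError,
    parse_variant,
)

logger = logging.getLogger(__name__)

REGIONS = ("eastern_european", "central_european", "mediterranean_western", "other")

# Control region spans the origin: nps 16024-16569 and 1-576.
CONTROL_REGION = ((16024, 16569), (1, 576))


class ReferenceError(ValueError):
    pass


class SampleInputError(ValueError):
    pass


@dataclass(frozen=True)
class GeneInterval:
    name: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    kind: str  # 'protein' | 'trna' | 'rrna'
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_LENGTH):
            raise ReferenceError(f"gene {self.name}: interval outside 1..{MT_LENGTH}")
        if self.strand not in "+-":
            raise ReferenceError(f"gene {self.name}: bad strand {self.strand!r}")
        if self.kind not in ("protein", "trna", "rrna"):
            raise ReferenceError(f"gene {self.name}: bad kind {self.kind!r}")


@dataclass(frozen=True)
class ReferenceGenome:
    sequence: str
    coding_table: tuple[GeneInterval, ...] = ()
    name: str = "reference"

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        if not 1 <= pos <= len(self.sequence):
            raise ReferenceError(f"position {pos} outside 1..{len(self.sequence)}")
        return self.sequence[pos - 1]

    def genes_at(self, pos: int) -> tuple[GeneInterval, ...]:
        return tuple(g for g in self.coding_table if g.start <= pos <= g.end)

    def in_control_region(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in CONTROL_REGION)


@dataclass(frozen=True)
class HaplotypeProfile:
    """A sample's filtered variant set plus metadata."""

    sample_id: str
    variants: frozenset[Variant]
    population: str = ""
    region: str = "other"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SampleInputError(
                f"sample {self.sample_id}: unknown region {self.region!r}"
            )

    def labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.variants)


@dataclass
class SampleStub:
    """Raw sample record prior to scoring: sequence or pre-scored labels."""

    sample_id: str
    population: str = ""
    region: str = "other"
    sequence: str | None = None
    variant_labels: tuple[str, ...] = ()


def _check_sequence(seq: str, where: str) -> str:
    seq = seq.upper()
    for i, b in enumerate(seq):
        if b not in "ACGTN":
            raise ReferenceError(
                f"{where}: non-ACGTN character {b!r} at position {i + 1}"
            )
    return seq


def load_reference(
    path: str | Path,
    coding_table_path: str | Path | None = None,
    permissive: bool = False,
) -> ReferenceGenome:
    """Load the reference genome from a single-record FASTA.

    Records whose length is not 16,569 are rejected unless ``permissive``.
    """
    path = Path(path)
    if not path.exists():
        raise ReferenceError(f"reference FASTA not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ReferenceError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise ReferenceError(f"{path}: expected single reference record, found {len(records)}")
    seq = _check_sequence(str(records[0].seq), str(path))
    if len(seq) != MT_LENGTH and not permissive:
        raise ReferenceError(
            f"{path}: reference length {len(seq)} != {MT_LENGTH} (use permissive to accept)"
        )
    table = load_coding_table(coding_table_path) if coding_table_path else ()
    return ReferenceGenome(seq, table, name=records[0].id)


def load_coding_table(path: str | Path) -> tuple[GeneInterval, ...]:
    """Read a tab-separated gene annotation table (name start end strand kind frame_offset)."""
    out = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                GeneInterval(
                    row["name"],
                    int(row["start"]),
                    int(row["end"]),
                    row["strand"],
                    row["kind"],
                    int(row.get("frame_offset", 0)),
                )
            )
    return tuple(out)


def load_packaged_reference() -> ReferenceGenome:
    """The packaged synthetic rCRS stand-in with its coding-region table."""
    data = resources.files("mitorho.data")
    with resources.as_file(data / "rcrs_synthetic.fasta") as fasta, resources.as_file(
        data / "mt_coding_table.tsv"
    ) as table:
        return load_reference(fasta, table)


def apply_variants(ref: ReferenceGenome, variants: Iterable[Variant]) -> str:
    """Apply a mutually consistent variant set to the reference sequence.

    Applying the empty set returns the reference unchanged; the result differs
    from the reference exactly at the applied variants.
    """
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, dict[int, str]] = {}
    for v in variants:
        if v.position > len(ref.sequence):
            raise VariantError(f"variant {v.label} beyond reference end")
        if v.kind == DELETION:
            if v.position in dels:
                raise VariantError(f"duplicate deletion at {v.position}")
            dels.add(v.position)
        elif v.kind == INSERTION:
            slot = ins.setdefault(v.position, {})
            if v.insertion_index in slot:
                raise VariantError(f"conflicting insertions at {v.label}")
            slot[v.insertion_index] = v.derived
        else:
            if v.position in subs and subs[v.position] != v.derived:
                raise VariantError(f"conflicting substitutions at np {v.position}")
            subs[v.position] = v.derived
    both = dels & set(subs)
    if both:
        raise VariantError(f"substitution and deletion collide at np {sorted(both)[0]}")
    for pos, slot in ins.items():
        if sorted(slot) != list(range(1, len(slot) + 1)):
            raise VariantError(f"insertion indices after np {pos} are not 1..k")
    out: list[str] = []
    for pos in range(1, len(ref.sequence) + 1):
        if pos not in dels:
            out.append(subs.get(pos, ref.sequence[pos - 1]))
        if pos in ins:
            for idx in sorted(ins[pos]):
                out.append(ins[pos][idx])
    return "".join(out)


def _parse_fasta_header(header: str, delimiter: str) -> tuple[str, str, str]:
    parts = header.split(delimiter)
    sample_id = parts[0].strip()
    population = parts[1].strip() if len(parts) > 1 else ""
    region = parts[2].strip() if len(parts) > 2 else ""
    if region not in REGIONS:
        if region:
            logger.warning(
                "sample %s: unknown region token %r mapped to 'other'", sample_id, region
            )
        else:
            logger.warning("sample %s: header lacks region; using 'other'", sample_id)
        region = "other"
    return sample_id, population, region


def read_samples(
    path: str | Path, fmt: str | None = None, delimiter: str = "|"
) -> list[SampleStub]:
    """Read sample sequences (FASTA) or pre-scored haplotype tables (TSV).

    FASTA headers carry ``sample_id|population|region``; haplotype tables have
    columns sample_id, population, region, space-separated variant labels.
    Unknown region tokens map to ``other`` with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise SampleInputError(f"sample file not found: {path}")
    if fmt is None:
        fmt = "table" if path.suffix.lower() in (".tsv", ".txt", ".tab") else "fasta"
    stubs: list[SampleStub] = []
    seen: set[str] = set()
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            sample_id, population, region = _parse_fasta_header(rec.description, delimiter)
            if sample_id in seen:
                raise SampleInputError(f"duplicate sample_id {sample_id!r} in {path}")
            seen.add(sample_id)
            stubs.append(
                SampleStub(
                    sample_id,
                    population,
                    region,
                    sequence=_check_sequence(str(rec.seq), f"{path}:{sample_id}"),
                )
            )
    elif fmt == "table":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise SampleInputError(
                        f"{path}:{lineno}: expected 4 tab-separated columns"
                    )
                sample_id, population, region, labels = (f.strip() for f in fields[:4])
                if sample_id in seen:
                    raise SampleInputError(f"duplicate sample_id {sample_id!r} in {path}")
                seen.add(sample_id)
                if region not in REGIONS:
                    logger.warning(
                        "sample %s: unknown region token %r mapped to 'other'",
                        sample_id,
                        region,
                    )
                    region = "other"
                stubs.append(
                    SampleStub(
                        sample_id,
                        population,
                        region,
                        variant_labels=tuple(labels.split()) if labels else (),
                    )
                )
    else:
        raise SampleInputError(f"unknown sample format {fmt!r}")
    if not stubs:
        raise SampleInputError(f"{path}: no samples found")
    return stubs


def stub_to_profile(stub: SampleStub, ref: ReferenceGenome) -> HaplotypeProfile:
    """Build a profile from a pre-scored stub (haplotype-table input)."""
    variants = frozenset(parse_variant(lab, ref) for lab in stub.variant_labels)
    return HaplotypeProfile(stub.sample_id, variants, stub.population, stub.region)
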