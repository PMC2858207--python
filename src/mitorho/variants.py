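"""rCRS-relative mtDNA variant nomenclature.

Variants are expressed in forensic mtDNA convention relative to the 16,569-bp
reference coordinate system:

* ``16311``   -- transition at np 16311 (derived base is the transition
  partner of the reference base, inferred from the reference);
* ``16114A``  -- transversion to A at np 16114;
* ``249d``    -- deletion of the base at np 249 (multi-base deletions are one
  variant per deleted position);
* ``309.1C``  -- insertion of C after np 309, first inserted base (multi-base
  insertions use sequential indices ``.1``, ``.2``, ...).

Indels are placed at their 3'-most equivalent position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

MT_LENGTH = 16569

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"

_KIND_ORDER = {TRANSITION: 0, TRANSVERSION: 1, DELETION: 2, INSERTION: 3}

_LABEL_RE = re.compile(
    r"^(?P<pos>\d+)"
    r"(?:\.(?P<idx>\d+)(?P<insbase>[ACGT])"
    r"|(?P<tvbase>[ACGT])"
    r"|(?P<del>d(?:el)?))?$"
)


class VariantError(ValueError):
    """Malformed or inconsistent variant label."""


@dataclass(frozen=True)
class Variant:
    """One scored difference from the reference.

    ``derived`` is the observed base for substitutions and the inserted base
    for insertions; it is empty for deletions.  ``insertion_index`` is the
    1-based index among bases inserted after the same position (0 for
    non-insertions).
    """

    position: int
    kind: str
    derived: str = ""
    insertion_index: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise VariantError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.kind not in _KIND_ORDER:
            raise VariantError(f"unknown variant kind {self.kind!r}")
        if self.kind == DELETION and self.derived:
            raise VariantError("deletion carries no derived base")
        if self.kind in (TRANSITION, TRANSVERSION, INSERTION):
            if self.derived not in "ACGT" or len(self.derived) != 1:
                raise VariantError(
                    f"{self.kind} at {self.position} needs a single derived base"
                )
        if self.kind == INSERTION and self.insertion_index < 1:
            raise VariantError("insertion index must be >= 1")
        if self.kind != INSERTION and self.insertion_index != 0:
            raise VariantError("insertion_index only valid for insertions")

    @property
    def is_substitution(self) -> bool:
        return self.kind in (TRANSITION, TRANSVERSION)

    @property
    def is_indel(self) -> bool:
        return self.kind in (INSERTION, DELETION)

    @property
    def label(self) -> str:
        return format_variant(self)

    def sort_key(self) -> tuple:
        return (self.position, self.insertion_index, _KIND_ORDER[self.kind], self.derived)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def is_transition_pair(a: str, b: str) -> bool:
    return TRANSITION_PARTNER.get(a) == b


def format_variant(v: Variant) -> str:
    """Canonical text form of a variant (the codec's encode direction)."""
    if v.kind == TRANSITION:
        return str(v.position)
    if v.kind == TRANSVERSION:
        return f"{v.position}{v.derived}"
    if v.kind == DELETION:
        return f"{v.position}d"
    return f"{v.position}.{v.insertion_index}{v.derived}"


def parse_variant(label: str, ref) -> Variant:
    """Parse a canonical label into a :class:`Variant`.

    ``ref`` is a :class:`mitorho.reference.ReferenceGenome`; it is required to
    infer the derived base of a transition and to reject transversion labels
    that are inconsistent with the reference base at that position.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise VariantError(f"malformed variant label {label!r}")
    pos = int(m.group("pos"))
    if not 1 <= pos <= MT_LENGTH:
        raise VariantError(f"variant {label!r}: position out of range 1..{MT_LENGTH}")
    if m.group("insbase"):
        idx = int(m.group("idx"))
        if idx < 1:
            raise VariantError(f"variant {label!r}: insertion index must be >= 1")
        return Variant(pos, INSERTION, m.group("insbase"), idx)
    if m.group("del"):
        return Variant(pos, DELETION)
    refbase = ref.base(pos)
    if m.group("tvbase"):
        base = m.group("tvbase")
        if base == refbase:
            raise VariantError(
                f"variant {label!r}: derived base equals reference base {refbase}"
            )
        if base == TRANSITION_PARTNER.get(refbase):
            raise VariantError(
                f"variant {label!r}: base {base} is the transition partner of "
                f"reference {refbase}; write it as the bare position"
            )
        return Variant(pos, TRANSVERSION, base)
    if refbase not in TRANSITION_PARTNER:
        raise VariantError(
            f"variant {label!r}: reference base {refbase!r} has no transition partner"
        )
    return Variant(pos, TRANSITION, TRANSITION_PARTNER[refbase])


def parse_variant_set(labels: Iterable[str], ref) -> frozenset[Variant]:
    out = set()
    for lab in labels:
        v = parse_variant(lab, ref)
        out.add(v)
    return frozenset(out)


def sorted_variants(variants: Iterable[Variant]) -> list[Variant]:
    return sorted(variants, key=Variant.sort_key)


def label_position(label: str) -> int:
    """Nucleotide position of a canonical label without full parsing."""
    m = re.match(r"^(\d+)", label.strip())
    if m is None:
        raise VariantError(f"malformed variant label {label!r}")
    return int(m.group(1))
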