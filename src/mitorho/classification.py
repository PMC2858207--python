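"""Motif-rule haplogroup classification.

A clade is defined by a motif: the set of diagnostic variants acquired on the
branch leading to it.  A profile is assigned to the deepest clade whose motif
and all ancestral motifs are subsets of its variants.  Profiles consisting
only of HVS-I positions (np >= 16024) are matched against the HVS-I part of
each motif, and the resulting assignment is flagged tentative because the
coding-region part of the motif chain cannot be verified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .reference import HaplotypeProfile, ReferenceGenome
from .variants import label_position, parse_variant

logger = logging.getLogger(__name__)

HVS1_START = 16024
UNCLASSIFIED = "unclassified"


class MotifRuleError(ValueError):
    pass


@dataclass(frozen=True)
class MotifRule:
    clade_name: str
    required_variants: frozenset[str]
    parent_clade: str | None = None

    def __post_init__(self) -> None:
        if not self.required_variants:
            raise MotifRuleError(f"clade {self.clade_name}: empty motif")


class MotifHierarchy:
    """A rooted tree of motif rules."""

    def __init__(self, rules: Iterable[MotifRule]):
        self.rules: dict[str, MotifRule] = {}
        for rule in rules:
            if rule.clade_name in self.rules:
                raise MotifRuleError(f"duplicate clade name {rule.clade_name!r}")
            self.rules[rule.clade_name] = rule
        roots = [r.clade_name for r in self.rules.values() if r.parent_clade is None]
        if len(roots) != 1:
            raise MotifRuleError(f"hierarchy must have exactly one root, found {roots}")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {name: [] for name in self.rules}
        for rule in self.rules.values():
            if rule.parent_clade is not None:
                if rule.parent_clade not in self.rules:
                    raise MotifRuleError(
                        f"clade {rule.clade_name}: unknown parent {rule.parent_clade!r}"
                    )
                self.children[rule.parent_clade].append(rule.clade_name)
        for kids in self.children.values():
            kids.sort()
        # cycle / reachability check
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise MotifRuleError(f"cyclic parent links at {name!r}")
            seen.add(name)
            stack.extend(self.children[name])
        if seen != set(self.rules):
            raise MotifRuleError(
                f"clades unreachable from root: {sorted(set(self.rules) - seen)}"
            )

    def chain(self, clade: str) -> list[str]:
        """Clade names on the path root -> clade."""
        out = []
        cur: str | None = clade
        while cur is not None:
            out.append(cur)
            cur = self.rules[cur].parent_clade
        return out[::-1]

    def depth(self, clade: str) -> int:
        return len(self.chain(clade)) - 1

    def chain_motif(self, clade: str) -> frozenset[str]:
        """Union of motifs along the path root -> clade."""
        out: set[str] = set()
        for name in self.chain(clade):
            out |= self.rules[name].required_variants
        return frozenset(out)

    def ancestors(self, clade: str) -> list[str]:
        return self.chain(clade)[:-1]

    def descendants(self, clade: str) -> list[str]:
        out = []
        stack = list(self.children[clade])
        while stack:
            name = stack.pop()
            out.append(name)
            stack.extend(self.children[name])
        return sorted(out)


def load_motif_rules(path: str | Path, ref: ReferenceGenome) -> MotifHierarchy:
    """Load and validate a motif rule file (YAML list of clade/parent/motif).

    Every motif label must parse under the variant codec; labels are
    re-canonicalized so later comparisons are textual.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise MotifRuleError(f"{path}: expected a list of clade entries")
    rules = []
    for entry in raw:
        name = entry["clade"]
        parent = entry.get("parent")
        motif_raw = entry.get("motif", [])
        canonical = []
        for lab in motif_raw:
            try:
                canonical.append(parse_variant(str(lab), ref).label)
            except Exception as exc:
                raise MotifRuleError(
                    f"clade {name}: malformed motif label {lab!r}: {exc}"
                ) from exc
        rules.append(MotifRule(name, frozenset(canonical), parent))
    return MotifHierarchy(rules)


def load_packaged_motif_rules(ref: ReferenceGenome) -> MotifHierarchy:
    from importlib import resources

    with resources.as_file(resources.files("mitorho.data") / "u5_motifs.yaml") as p:
        return load_motif_rules(p, ref)


@dataclass(frozen=True)
class AssignmentResult:
    clade: str
    tentative: bool = False
    notes: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover
        return self.clade + (" (tentative)" if self.tentative else "")


def _restrict(motif: frozenset[str], hvs1_only: bool) -> frozenset[str]:
    if not hvs1_only:
        return motif
    return frozenset(lab for lab in motif if label_position(lab) >= HVS1_START)


def assign_haplogroup(
    profile: HaplotypeProfile | Iterable[str],
    hierarchy: MotifHierarchy,
    hvs1_only: bool | None = None,
) -> AssignmentResult:
    """Assign a profile to the deepest matching clade.

    Deterministic under any input ordering; ties between sibling clades are
    broken by larger own-motif size, then lexicographic clade name, and
    logged.  ``hvs1_only`` defaults to auto-detection: a profile whose
    variants all lie at np >= 16024 is matched against HVS-I motif positions
    only and flagged tentative when coding motif variants went unchecked.
    """
    if isinstance(profile, HaplotypeProfile):
        labels = profile.labels()
    else:
        labels = frozenset(str(x) if isinstance(x, str) else x.label for x in profile)
    if hvs1_only is None:
        hvs1_only = bool(labels) and all(label_position(l) >= HVS1_START for l in labels)

    def matches(clade: str) -> bool:
        return _restrict(hierarchy.chain_motif(clade), hvs1_only) <= labels

    matching = [c for c in hierarchy.rules if matches(c)]
    if not matching or hierarchy.root not in matching:
        return AssignmentResult(UNCLASSIFIED)
    best = min(
        matching,
        key=lambda c: (
            -hierarchy.depth(c),
            -len(_restrict(hierarchy.rules[c].required_variants, hvs1_only)),
            c,
        ),
    )
    notes: list[str] = []
    ties = [
        c
        for c in matching
        if c != best
        and hierarchy.depth(c) == hierarchy.depth(best)
        and len(_restrict(hierarchy.rules[c].required_variants, hvs1_only))
        == len(_restrict(hierarchy.rules[best].required_variants, hvs1_only))
    ]
    if ties:
        logger.warning("classification tie between %s and %s", best, sorted(ties))
        notes.append(f"tie with {','.join(sorted(ties))}")
    tentative = False
    if hvs1_only:
        unchecked = hierarchy.chain_motif(best) - _restrict(
            hierarchy.chain_motif(best), True
        )
        if unchecked:
            tentative = True
            notes.append("hvs1_only: coding-region motif variants unchecked")
    # possible back mutation: a descendant's own motif is fully present even
    # though its chain is broken at an intermediate level
    for desc in hierarchy.descendants(best):
        own = _restrict(hierarchy.rules[desc].required_variants, hvs1_only)
        if own and own <= labels:
            notes.append(f"possible back mutation: {desc} motif present below {best}")
            break
    return AssignmentResult(best, tentative, tuple(notes))


def classify_all(
    profiles: Iterable[HaplotypeProfile],
    hierarchy: MotifHierarchy,
    hvs1_only: bool | None = None,
) -> dict[str, AssignmentResult]:
    return {
        p.sample_id: assign_haplogroup(p, hierarchy, hvs1_only=hvs1_only)
        for p in profiles
    }
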