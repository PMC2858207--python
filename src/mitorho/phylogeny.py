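"""Most-parsimonious mutation-labeled haplotype trees.

Haplotypes are binary character vectors over the variants observed in the
sample (presence/absence relative to a designated ancestral state).  When all
characters are pairwise compatible the unique perfect phylogeny is emitted;
otherwise conflicts are resolved by letting a subset of characters recur on
the tree (homoplasy): mutually compatible characters form a backbone tree and
each remaining character is overlaid by exact small-parsimony dynamic
programming on that topology, with recurrent origins grouped under inserted
nodes where that shortens the tree.  For instances with few conflicting
characters the backbone subset is chosen by exact search; above that, by the
deterministic greedy order (low weight first, i.e. homoplasy is accepted at
the fastest sites).

Edges carry ordered mutation events; a back mutation is a second, inverted
occurrence of a variant on a root-to-tip path and serializes with a ``!``
suffix.  Replaying the events along the path from the root to any tip yields
exactly that tip's (filtered) variant set.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .reference import HaplotypeProfile
from .variants import Variant, label_position, parse_variant, sorted_variants

INF = float("inf")


class PhylogenyError(ValueError):
    pass


@dataclass(frozen=True)
class MutationEvent:
    variant: Variant
    is_back: bool = False

    @property
    def label(self) -> str:
        return self.variant.label + ("!" if self.is_back else "")

    def sort_key(self) -> tuple:
        return (*self.variant.sort_key(), self.is_back)


class TreeNode:
    __slots__ = ("node_id", "parent", "children", "events", "samples")

    def __init__(self, node_id: int):
        self.node_id = node_id
        self.parent: "TreeNode | None" = None
        self.children: list["TreeNode"] = []
        self.events: list[MutationEvent] = []  # on the edge to the parent
        self.samples: list[str] = []  # non-empty => sampled haplotype node (tip)

    @property
    def multiplicity(self) -> int:
        return len(self.samples)

    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class MutationTree:
    """Rooted tree whose edges carry mutation events and tips carry samples."""

    def __init__(self, root: TreeNode, root_state: frozenset[Variant] = frozenset()):
        self.root = root
        self.root_state = frozenset(root_state)

    # -- traversal ---------------------------------------------------------
    def nodes(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.samples]

    def n_samples(self, node: TreeNode | None = None) -> int:
        node = node or self.root
        return sum(n.multiplicity for n in self.subtree(node) if n.samples)

    def subtree(self, node: TreeNode) -> list[TreeNode]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def path_from_root(self, node: TreeNode) -> list[TreeNode]:
        out = []
        cur: TreeNode | None = node
        while cur is not None:
            out.append(cur)
            cur = cur.parent
        return out[::-1]

    def path_events(self, node: TreeNode, below: TreeNode | None = None) -> list[MutationEvent]:
        """Events on the path from ``below`` (default root) down to ``node``."""
        below = below or self.root
        out: list[MutationEvent] = []
        path = self.path_from_root(node)
        if below not in path:
            raise PhylogenyError("node is not below the requested ancestor")
        start = path.index(below)
        for n in path[start + 1 :]:
            out.extend(n.events)
        return out

    def node_state(self, node: TreeNode) -> frozenset[Variant]:
        state = set(self.root_state)
        for ev in self.path_events(node):
            state.symmetric_difference_update({ev.variant})
        return frozenset(state)

    def find_tip(self, sample_id: str) -> TreeNode:
        for tip in self.tips():
            if sample_id in tip.samples:
                return tip
        raise PhylogenyError(f"sample {sample_id!r} not in tree")

    def mrca(self, nodes: Sequence[TreeNode]) -> TreeNode:
        if not nodes:
            raise PhylogenyError("mrca of empty node set")
        paths = [self.path_from_root(n) for n in nodes]
        mrca = None
        for group in zip(*paths):
            if all(n is group[0] for n in group):
                mrca = group[0]
            else:
                break
        assert mrca is not None
        return mrca

    def total_mutations(self, weights: Mapping[str, float] | None = None) -> float:
        total = 0.0
        for node in self.nodes():
            for ev in node.events:
                total += (weights or {}).get(ev.variant.label, 1.0)
        return total

    def n_events(self) -> int:
        return sum(len(n.events) for n in self.nodes())

    # -- invariant check ---------------------------------------------------
    def check_path_property(self, profiles: Mapping[str, frozenset[Variant]]) -> None:
        for tip in self.tips():
            state = self.node_state(tip)
            for sid in tip.samples:
                if profiles[sid] != state:
                    raise PhylogenyError(
                        f"path property violated for sample {sid}: "
                        f"replayed {sorted(v.label for v in state)} != "
                        f"profile {sorted(v.label for v in profiles[sid])}"
                    )


@dataclass
class HomoplasyReport:
    """Independent origins and reversions per variant, plus per-edge flags."""

    origins: dict[str, int]
    reversions: dict[str, int]
    parallel_labels: frozenset[str]
    edge_flags: dict[int, tuple[str, ...]]  # node_id of child end -> flagged labels

    def is_empty(self) -> bool:
        return not any(v > 1 for v in self.origins.values()) and not any(
            self.reversions.values()
        )

    def to_frame(self):
        import pandas as pd

        labels = sorted(set(self.origins) | set(self.reversions), key=label_position)
        return pd.DataFrame(
            {
                "variant": labels,
                "origins": [self.origins.get(l, 0) for l in labels],
                "reversions": [self.reversions.get(l, 0) for l in labels],
                "parallel": [l in self.parallel_labels for l in labels],
            }
        )


# ---------------------------------------------------------------------------
# construction


def _canonical_profiles(
    profiles: Sequence[HaplotypeProfile | tuple[str, Iterable[Variant]]],
) -> list[tuple[str, frozenset[Variant]]]:
    out = []
    for p in profiles:
        if isinstance(p, HaplotypeProfile):
            out.append((p.sample_id, frozenset(p.variants)))
        else:
            sid, variants = p
            out.append((sid, frozenset(variants)))
    return out


def build_mp_tree(
    profiles: Sequence[HaplotypeProfile | tuple[str, Iterable[Variant]]],
    root_state: Iterable[Variant] = (),
    weights: Mapping[str, float] | None = None,
    exact_limit: int = 12,
) -> MutationTree:
    """Build a most-parsimonious mutation tree from haplotype profiles.

    ``root_state`` is the ancestral variant set (empty = the reference / clade
    founder is the reference haplotype).  ``weights`` maps variant labels to
    positive per-site weights (default uniform); lower-weight sites are the
    first to accept homoplasy when characters conflict.  Identical profiles
    collapse to a single tip with multiplicity.
    """
    pairs = _canonical_profiles(profiles)
    if not pairs:
        raise PhylogenyError("no profiles given")
    root_state = frozenset(root_state)
    weights = dict(weights or {})
    for lab, w in weights.items():
        if w <= 0:
            raise PhylogenyError(f"non-positive weight for {lab!r}")

    # collapse identical profiles (character sets relative to the root state)
    hap_samples: dict[frozenset[Variant], list[str]] = {}
    for sid, variants in pairs:
        hap_samples.setdefault(frozenset(variants ^ root_state), []).append(sid)
    haplotypes = sorted(
        hap_samples, key=lambda h: (len(h), sorted(v.label for v in h))
    )
    for h in haplotypes:
        hap_samples[h].sort()

    # characters: variant -> carrier haplotype index set
    chars: dict[Variant, frozenset[int]] = {}
    for i, h in enumerate(haplotypes):
        for v in h:
            chars[v] = chars.get(v, frozenset()) | {i}

    def compatible(a: frozenset[int], b: frozenset[int]) -> bool:
        return a <= b or b <= a or not (a & b)

    variants_sorted = sorted(chars, key=Variant.sort_key)
    conflict_involved: set[Variant] = set()
    for va, vb in itertools.combinations(variants_sorted, 2):
        if not compatible(chars[va], chars[vb]):
            conflict_involved.add(va)
            conflict_involved.add(vb)

    def keep_priority(v: Variant) -> tuple:
        # backbone preference: heavy (slow) sites, widely shared, low position
        return (-weights.get(v.label, 1.0), -len(chars[v]), *v.sort_key())

    def overlay_order(v: Variant) -> tuple:
        # homoplasy acceptance: fast sites first, then rarest, then position
        return (weights.get(v.label, 1.0), len(chars[v]), *v.sort_key())

    always_kept = [v for v in variants_sorted if v not in conflict_involved]

    def assemble(kept: list[Variant], overlay: list[Variant]) -> MutationTree:
        return _assemble_tree(
            haplotypes, hap_samples, chars, kept, list(overlay), root_state, weights
        )

    if not conflict_involved:
        tree = assemble(variants_sorted, [])
    elif len(conflict_involved) <= exact_limit and len(haplotypes) <= 32:
        tree = _exact_conflict_resolution(
            sorted(conflict_involved, key=keep_priority), always_kept, chars,
            compatible, assemble, weights, overlay_order,
        )
    else:
        kept: list[Variant] = list(always_kept)
        overlay: list[Variant] = []
        for v in sorted(conflict_involved, key=keep_priority):
            if all(compatible(chars[v], chars[k]) for k in kept):
                kept.append(v)
            else:
                overlay.append(v)
        tree = assemble(kept, sorted(overlay, key=overlay_order))

    profile_map = {sid: variants for sid, variants in pairs}
    tree.check_path_property(profile_map)
    return tree


def _exact_conflict_resolution(
    conflict_chars, always_kept, chars, compatible, assemble, weights, overlay_order
) -> MutationTree:
    """Search over compatible subsets of the conflict-involved characters.

    For each candidate backbone subset the remaining characters are overlaid
    in several orders (all permutations when few, otherwise ascending and
    descending carrier count): overlaying widely shared characters first lets
    the grouped nodes they insert be reused by later characters.  Ties between
    equally parsimonious resolutions prefer fewer distinct homoplasious sites,
    then the greedy-preferred subset (enumeration order).
    """
    best = None
    best_key = None
    m = len(conflict_chars)
    candidates = []
    # enumerate subsets, largest first so the greedy-preferred full-keep
    # candidates come early; subset bit i set => conflict_chars[i] kept
    for mask in sorted(range(1 << m), key=lambda s: (-bin(s).count("1"), -s)):
        subset = [conflict_chars[i] for i in range(m) if mask >> i & 1]
        ok = True
        for i, va in enumerate(subset):
            if any(not compatible(chars[va], chars[vb]) for vb in subset[i + 1 :]):
                ok = False
                break
            if any(not compatible(chars[va], chars[k]) for k in always_kept):
                ok = False
                break
        if ok:
            candidates.append(subset)
    for subset in candidates:
        overlay = sorted(
            (v for v in conflict_chars if v not in subset), key=overlay_order
        )
        if len(overlay) <= 5 and len(candidates) * max(
            1, _factorial(len(overlay))
        ) <= 4096:
            orders = list(itertools.permutations(overlay))
        else:
            orders = [tuple(overlay), tuple(reversed(overlay))]
        seen_orders = set()
        for order in orders:
            if order in seen_orders:
                continue
            seen_orders.add(order)
            tree = assemble(always_kept + subset, list(order))
            report = annotate_homoplasies(tree)
            n_homoplasious = sum(
                1
                for lab in set(report.origins)
                if report.origins[lab] + report.reversions.get(lab, 0) > 1
            )
            key = (tree.total_mutations(weights), n_homoplasious)
            if best_key is None or key < best_key:
                best, best_key = tree, key
    assert best is not None
    return best


def _factorial(n: int) -> int:
    out = 1
    for i in range(2, n + 1):
        out *= i
    return out


def _assemble_tree(
    haplotypes: list[frozenset[Variant]],
    hap_samples: dict[frozenset[Variant], list[str]],
    chars: dict[Variant, frozenset[int]],
    kept: list[Variant],
    overlay: list[Variant],
    root_state: frozenset[Variant],
    weights: Mapping[str, float],
) -> MutationTree:
    counter = itertools.count()
    root = TreeNode(next(counter))
    n_h = len(haplotypes)

    # backbone: laminar family of carrier sets of kept characters
    set_chars: dict[frozenset[int], list[Variant]] = {}
    for v in kept:
        set_chars.setdefault(chars[v], []).append(v)
    laminar = sorted(set_chars, key=lambda s: (-len(s), sorted(s)))
    set_node: dict[frozenset[int], TreeNode] = {}
    for s in laminar:
        parent = root
        best_size = n_h + 1
        for t, node in set_node.items():
            if s < t and len(t) < best_size:
                parent, best_size = node, len(t)
        node = TreeNode(next(counter))
        parent.add_child(node)
        for v in sorted(set_chars[s], key=Variant.sort_key):
            node.events.append(MutationEvent(v, is_back=v in root_state))
        set_node[s] = node

    # pendant tips: each haplotype attaches at the node of the smallest kept
    # carrier set containing it
    hap_tip: dict[int, TreeNode] = {}
    for i in range(n_h):
        attach = root
        best_size = n_h + 1
        for s, node in set_node.items():
            if i in s and len(s) < best_size:
                attach, best_size = node, len(s)
        tip = TreeNode(next(counter))
        tip.samples = list(hap_samples[haplotypes[i]])
        attach.add_child(tip)
        hap_tip[i] = tip

    tree = MutationTree(root, root_state)

    # overlay conflicting characters one at a time (small-parsimony DP on the
    # current topology, root fixed at state 0, then group recurrent origins)
    for v in overlay:
        carriers = chars[v]
        _overlay_character(tree, v, carriers, hap_tip, root_state, counter)

    _sort_tree(tree)
    return tree


def _overlay_character(tree, v, carriers, hap_tip, root_state, counter) -> None:
    """Overlay one binary character by grouping-aware small parsimony.

    The cost of a node in state ``s`` lets any number of children flip to the
    opposite state for a single shared mutation (they are gathered under one
    inserted node), so recurrent origins are priced the way the final tree
    will actually carry them.
    """
    tip_state = {tip.node_id: (1 if i in carriers else 0) for i, tip in hap_tip.items()}

    cost: dict[int, list[float]] = {}

    def down(node: TreeNode) -> None:
        if node.node_id in tip_state and node.is_tip():
            s = tip_state[node.node_id]
            cost[node.node_id] = [0 if s == 0 else INF, 0 if s == 1 else INF]
            return
        for child in node.children:
            down(child)
        out = []
        for s in (0, 1):
            keep_total = 0.0
            flip_total = 0.0
            any_flip = False
            for child in node.children:
                k = cost[child.node_id][s]
                d = cost[child.node_id][1 - s]
                keep_total += k
                if d < k:
                    flip_total += d
                    any_flip = True
                else:
                    flip_total += k
            grouped = flip_total + 1 if any_flip else keep_total
            out.append(min(keep_total, grouped))
        cost[node.node_id] = out

    down(tree.root)

    def realize(node: TreeNode, state: int) -> None:
        if node.is_tip() and node.node_id in tip_state:
            return
        flips = []
        keep_total = 0.0
        for child in node.children:
            k = cost[child.node_id][state]
            d = cost[child.node_id][1 - state]
            keep_total += k
            if d < k:
                flips.append(child)
        if flips:
            grouped = (
                sum(cost[c.node_id][1 - state] for c in flips)
                + sum(cost[c.node_id][state] for c in node.children if c not in flips)
                + 1
            )
            if not grouped < keep_total:  # tie -> no events on this level
                flips = []
        if len(flips) >= 2:
            mid = TreeNode(next(counter))
            mid.parent = node
            node.children = [c for c in node.children if c not in flips] + [mid]
            for c in flips:
                c.parent = mid
                mid.children.append(c)
            mid.events.append(_event_for(v, state, root_state))
            for c in list(mid.children):
                realize(c, 1 - state)
            return_children = [c for c in node.children if c is not mid]
            for c in return_children:
                realize(c, state)
            return
        if len(flips) == 1:
            flips[0].events.append(_event_for(v, state, root_state))
        for child in node.children:
            realize(child, 1 - state if child in flips else state)

    realize(tree.root, 0)


def _event_for(v: Variant, parent_char_state: int, root_state: frozenset[Variant]) -> MutationEvent:
    present_before = (v in root_state) != (parent_char_state == 1)
    # presence before event: char state XOR root membership; toggling a
    # present variant restores the ancestral base => back mutation
    return MutationEvent(v, is_back=present_before)


def _sort_tree(tree: MutationTree) -> None:
    """Deterministic child and event ordering (smallest sample id below)."""

    def min_sample(node: TreeNode) -> str:
        best = min(node.samples) if node.samples else "￿"
        for c in node.children:
            best = min(best, min_sample(c))
        return best

    for node in tree.nodes():
        node.events.sort(key=MutationEvent.sort_key)
        node.children.sort(key=lambda c: (min_sample(c), c.node_id))


# ---------------------------------------------------------------------------
# homoplasy annotation


def annotate_homoplasies(tree: MutationTree) -> HomoplasyReport:
    """Count independent origins and reversions of every variant in the tree.

    Directions are recomputed by replaying edge events from the root, so the
    report is trustworthy even if edge flags were lost in serialization.
    """
    origins: dict[str, int] = {}
    reversions: dict[str, int] = {}
    edge_flags: dict[int, list[str]] = {}

    def walk(node: TreeNode, state: set[Variant]) -> None:
        for child in node.children:
            child_state = set(state)
            for ev in child.events:
                lab = ev.variant.label
                if ev.variant in child_state:
                    reversions[lab] = reversions.get(lab, 0) + 1
                    child_state.discard(ev.variant)
                    edge_flags.setdefault(child.node_id, []).append(lab + "!")
                else:
                    origins[lab] = origins.get(lab, 0) + 1
                    child_state.add(ev.variant)
            walk(child, child_state)

    walk(tree.root, set(tree.root_state))
    parallel = frozenset(lab for lab, n in origins.items() if n > 1)
    for node in tree.nodes():
        for ev in node.events:
            lab = ev.variant.label
            if lab in parallel:
                flags = edge_flags.setdefault(node.node_id, [])
                if lab + "<" not in flags:
                    flags.append(lab + "<")
    return HomoplasyReport(
        origins, reversions, parallel, {k: tuple(v) for k, v in edge_flags.items()}
    )


# ---------------------------------------------------------------------------
# exhaustive oracle (independent of build_mp_tree)


def exhaustive_mp_oracle(
    profiles: Sequence[HaplotypeProfile | tuple[str, Iterable[Variant]]],
    root_state: Iterable[Variant] = (),
    max_taxa: int = 8,
    max_sites: int = 12,
) -> int:
    """Exact minimum mutation count by exhaustive topology enumeration.

    The ancestral state joins the leaf set, so rooted maximum parsimony
    reduces to unrooted Fitch parsimony over distinct haplotypes.  Refuses
    instances above ``max_taxa`` distinct profiles or ``max_sites`` variable
    sites.
    """
    pairs = _canonical_profiles(profiles)
    if not pairs:
        raise PhylogenyError("no profiles given")
    root_state = frozenset(root_state)
    charsets = sorted(
        {frozenset(variants ^ root_state) for _, variants in pairs},
        key=lambda h: (len(h), sorted(v.label for v in h)),
    )
    sites = sorted({v for h in charsets for v in h}, key=Variant.sort_key)
    if len(charsets) > max_taxa:
        raise PhylogenyError(f"oracle refuses > {max_taxa} distinct profiles")
    if len(sites) > max_sites:
        raise PhylogenyError(f"oracle refuses > {max_sites} variable sites")
    k = len(sites)
    if k == 0:
        return 0
    site_index = {v: i for i, v in enumerate(sites)}

    def encode(h: frozenset[Variant]) -> int:
        x = 0
        for i in range(k):
            x |= (2 if sites[i] in h else 1) << (2 * i)
        return x

    leaves = [encode(frozenset())] + [encode(h) for h in charsets]
    unit = sum(1 << (2 * i) for i in range(k))

    def combine(a: int, b: int) -> tuple[int, int]:
        inter = a & b
        nz = (inter | (inter >> 1)) & unit
        zero = (~nz) & unit
        added = bin(zero).count("1")
        sel = zero | (zero << 1)
        return (inter & ~sel) | ((a | b) & sel), added

    def fitch(tree) -> tuple[int, int]:
        if isinstance(tree, int):
            return leaves[tree], 0
        (sa, ca) = fitch(tree[0])
        (sb, cb) = fitch(tree[1])
        s, add = combine(sa, sb)
        return s, ca + cb + add

    n = len(leaves)
    if n == 1:
        return 0
    if n == 2:
        _, c = fitch((0, 1))
        return c

    best = [INF]

    def cost_with_root(rest) -> int:
        _, c = fitch((0, rest))
        return c

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if not isinstance(tree, int):
            for sub in insert_everywhere(tree[0], leaf):
                yield (sub, tree[1])
            for sub in insert_everywhere(tree[1], leaf):
                yield (tree[0], sub)

    def search(rest, next_leaf: int) -> None:
        c = cost_with_root(rest)
        if c >= best[0]:
            return
        if next_leaf == n:
            best[0] = c
            return
        for candidate in insert_everywhere(rest, next_leaf):
            search(candidate, next_leaf + 1)

    search(1, 2)
    return int(best[0])


# ---------------------------------------------------------------------------
# annotated newick serialization


def _quote(label: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9_.+|-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def tree_to_newick(tree: MutationTree) -> str:
    def fmt(node: TreeNode) -> str:
        inner = ""
        if node.children:
            inner = "(" + ",".join(fmt(c) for c in node.children) + ")"
        label = _quote("+".join(node.samples)) if node.samples else ""
        if node is tree.root:
            comment = ""
            if tree.root_state:
                comment = "[&root=" + "/".join(
                    v.label for v in sorted_variants(tree.root_state)
                ) + "]"
            return f"{inner}{label}{comment}"
        comment = ""
        if node.events:
            comment = "[&muts=" + "/".join(ev.label for ev in node.events) + "]"
        return f"{inner}{label}:{len(node.events)}{comment}"

    return fmt(tree.root) + ";"


def write_annotated_newick(tree: MutationTree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def parse_annotated_newick(text: str, ref) -> MutationTree:
    """Re-read an annotated newick string into a :class:`MutationTree`.

    ``ref`` is needed to re-parse transition labels (their derived base is
    inferred from the reference).  Round-trips topology, edge mutation lists
    (including back-mutation markers) and tip sample lists.
    """
    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    counter = itertools.count()
    pos = [0]

    def error(msg: str):
        raise PhylogenyError(f"newick parse error at {pos[0]}: {msg}")

    def parse_label() -> str:
        i = pos[0]
        if i < len(text) and text[i] == "'":
            j = i + 1
            out = []
            while j < len(text):
                if text[j] == "'":
                    if j + 1 < len(text) and text[j + 1] == "'":
                        out.append("'")
                        j += 2
                        continue
                    break
                out.append(text[j])
                j += 1
            pos[0] = j + 1
            return "".join(out)
        m = re.match(r"[A-Za-z0-9_.+|-]*", text[i:])
        pos[0] = i + m.end()
        return m.group(0)

    def parse_comment() -> str:
        if pos[0] < len(text) and text[pos[0]] == "[":
            j = text.index("]", pos[0])
            out = text[pos[0] + 1 : j]
            pos[0] = j + 1
            return out
        return ""

    def events_from(comment: str) -> list[MutationEvent]:
        m = re.match(r"&muts=(.*)$", comment)
        if not m:
            return []
        out = []
        for lab in m.group(1).split("/"):
            is_back = lab.endswith("!")
            out.append(MutationEvent(parse_variant(lab.rstrip("!"), ref), is_back))
        return out

    def parse_node() -> TreeNode:
        node = TreeNode(next(counter))
        if text[pos[0] : pos[0] + 1] == "(":
            pos[0] += 1
            while True:
                node.add_child(parse_node())
                ch = text[pos[0] : pos[0] + 1]
                if ch == ",":
                    pos[0] += 1
                    continue
                if ch == ")":
                    pos[0] += 1
                    break
                error("expected ',' or ')'")
        label = parse_label()
        if label:
            node.samples = label.split("+")
        comment = parse_comment()
        if text[pos[0] : pos[0] + 1] == ":":
            pos[0] += 1
            m = re.match(r"\d+(\.\d+)?", text[pos[0] :])
            pos[0] += m.end()
            comment = parse_comment() or comment
        node.events = events_from(comment)
        return node

    root = parse_node()
    root_state: frozenset[Variant] = frozenset()
    # root comment may carry the ancestral state
    m = re.search(r"\[&root=([^\]]*)\]$", text)
    if m:
        root_state = frozenset(
            parse_variant(lab, ref) for lab in m.group(1).split("/") if lab
        )
    tree = MutationTree(root, root_state)
    return tree
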