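"""Synthetic mtDNA genome datasets with known genealogy and founder age.

The generator emulates the statistical structure the rho-dating machinery
assumes: a clade of complete mitochondrial genomes descending from a single
founder of known age, with mutations accruing along each lineage as a Poisson
process at a fixed clock rate, site-rate heterogeneity (a configurable set of
hotspot positions at elevated relative rate) producing occasional parallel
and back mutations, and the reference's coding/control-region structure
carried through so the synonymous clock has something to count.

Default parameters describe the emulated study: 150 complete genomes from a
founder 20,000 years old at one mutation per 3,624 years, with a strong
transition bias (5% transversions, 1% indels) and 15 mutational hotspots at
30x the background rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .phylogeny import MutationEvent, MutationTree, TreeNode, tree_to_newick, parse_annotated_newick
from .reference import ReferenceGenome, apply_variants
from .scoring import annotate_synonymous
from .variants import (
    DELETION,
    INSERTION,
    MT_LENGTH,
    TRANSITION,
    TRANSITION_PARTNER,
    TRANSVERSION,
    Variant,
    parse_variant,
)

_REGION_POPULATIONS = {
    "eastern_european": ("Russians", "Belorussians", "Poles"),
    "central_european": ("Czechs", "Slovaks"),
    "mediterranean_western": ("Italians", "Spaniards"),
    "other": ("unknown",),
}
_REGION_WEIGHTS = (0.4, 0.3, 0.2, 0.1)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationSpec:
    topology: str = "star"  # 'star' | 'yule' | 'fixed_newick'
    n_tips: int = 150
    founder_age_years: float = 20000.0
    years_per_mutation: float = 3624.0
    n_hotspots: int = 15
    hotspot_rate: float = 30.0
    hotspot_positions: tuple[int, ...] | None = None
    transversion_fraction: float = 0.05
    indel_fraction: float = 0.01
    founder_variants: tuple[str, ...] = ()
    fixed_newick: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise SimulationError("n_tips must be >= 1")
        if self.founder_age_years <= 0:
            raise SimulationError("founder_age_years must be positive")
        if self.years_per_mutation <= 0:
            raise SimulationError("years_per_mutation must be positive")
        if self.hotspot_rate <= 0:
            raise SimulationError("hotspot_rate must be positive")
        if self.topology not in ("star", "yule", "fixed_newick"):
            raise SimulationError(f"unknown topology {self.topology!r}")
        if self.topology == "fixed_newick" and not self.fixed_newick:
            raise SimulationError("fixed_newick topology needs a newick string")
        if not 0 <= self.transversion_fraction <= 1 or not 0 <= self.indel_fraction <= 1:
            raise SimulationError("kind fractions must lie in [0, 1]")


@dataclass
class SimulationTruth:
    tree: MutationTree
    tip_variants: dict[str, frozenset[Variant]]
    tip_metadata: dict[str, tuple[str, str]]  # sample -> (population, region)
    founder_age_years: float
    years_per_mutation: float
    founder_variants: frozenset[Variant]
    synonymy: dict[str, str]  # variant label -> annotation


@dataclass
class SimulationResult:
    records: list[tuple[str, str]]  # (fasta header, sequence)
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# genealogy shapes: (children branch lengths in years)


def _star_branches(n: int, age: float) -> list[tuple[int, float, int | None]]:
    # node list: (node_index, branch_length_from_parent, parent_index); root=0
    out = [(0, 0.0, None)]
    for i in range(n):
        out.append((i + 1, age, 0))
    return out


def _yule_branches(n: int, age: float, rng: np.random.Generator):
    """Pure-birth genealogy rescaled so every tip sits at the founder age.

    Forward simulation: one lineage splits at unit birth rate per lineage;
    split times are rescaled so the root-to-tip depth equals ``age``.
    """
    if n == 1:
        return _star_branches(1, age)
    t = 0.0
    split_times = []
    for k in range(1, n):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    t_end = split_times[-1] + rng.exponential(1.0 / n)
    scale = age / t_end
    nodes: list[tuple[int, float, int | None]] = [(0, 0.0, None)]
    next_id = 1
    # active lineage = (parent node id, time the lineage started)
    active: list[tuple[int, float]] = [(0, 0.0)]
    for st in split_times:
        idx = int(rng.integers(len(active)))
        parent_id, birth = active.pop(idx)
        nodes.append((next_id, (st - birth) * scale, parent_id))
        split_node = next_id
        next_id += 1
        active.append((split_node, st))
        active.append((split_node, st))
    for parent_id, birth in active:
        nodes.append((next_id, (t_end - birth) * scale, parent_id))
        next_id += 1
    return nodes


def _branches_from_newick(newick: str, age: float):
    """Topology and relative branch lengths from a plain newick string."""
    import re as _re

    pos = [0]
    text = newick.strip().rstrip(";")
    nodes = []
    next_id = [0]

    def parse(parent, depth_in):
        nid = next_id[0]
        next_id[0] += 1
        children = []
        if text[pos[0] : pos[0] + 1] == "(":
            pos[0] += 1
            while True:
                children.append(nid)
                parse(nid, 0.0)
                ch = text[pos[0] : pos[0] + 1]
                if ch == ",":
                    pos[0] += 1
                    continue
                pos[0] += 1
                break
        m = _re.match(r"[^:,()\[\];]*", text[pos[0] :])
        pos[0] += m.end()
        length = 0.0
        if text[pos[0] : pos[0] + 1] == ":":
            pos[0] += 1
            m = _re.match(r"[0-9.eE+-]+", text[pos[0] :])
            length = float(m.group(0))
            pos[0] += m.end()
        nodes.append((nid, length, parent))
        return nid

    parse(None, 0.0)
    # rescale so max root-tip depth equals `age`
    length_of = {nid: l for nid, l, _ in nodes}
    parent_of = {nid: p for nid, _, p in nodes}

    def depth(nid):
        d = 0.0
        while nid is not None:
            d += length_of[nid]
            nid = parent_of[nid]
        return d

    children_count: dict[int, int] = {}
    for nid, _, p in nodes:
        if p is not None:
            children_count[p] = children_count.get(p, 0) + 1
    tips = [nid for nid, _, _ in nodes if children_count.get(nid, 0) == 0]
    maxdepth = max(depth(t) for t in tips)
    if maxdepth <= 0:
        raise SimulationError("fixed newick has zero depth")
    scale = age / maxdepth
    return [(nid, l * scale, p) for nid, l, p in nodes]


# ---------------------------------------------------------------------------


def _site_rates(spec: SimulationSpec, rng: np.random.Generator) -> tuple[np.ndarray, tuple[int, ...]]:
    rates = np.ones(MT_LENGTH - 1)  # positions 1..16568 (last np excluded for indel safety)
    if spec.hotspot_positions is not None:
        hotspots = tuple(spec.hotspot_positions)
    else:
        hotspots = tuple(
            int(p) + 1 for p in rng.choice(MT_LENGTH - 1, size=spec.n_hotspots, replace=False)
        )
    for p in hotspots:
        if not 1 <= p <= MT_LENGTH - 1:
            raise SimulationError(f"hotspot position {p} out of range")
        rates[p - 1] = spec.hotspot_rate
    return rates / rates.sum(), hotspots


def _new_variant_at(
    pos: int, ref: ReferenceGenome, spec: SimulationSpec, rng: np.random.Generator
) -> Variant | None:
    """Draw a fresh variant at a reference position, or None to resample.

    Indels are only placed where their 3'-most normal form is the position
    itself, so scoring recovers exactly the simulated label.
    """
    u = rng.random()
    refbase = ref.base(pos)
    if u < spec.indel_fraction:
        if rng.random() < 0.5:
            # deletion must be 3'-most: next base differs
            if pos + 1 <= len(ref.sequence) and ref.base(pos + 1) != refbase:
                return Variant(pos, DELETION)
            return None
        nxt = ref.base(pos + 1) if pos + 1 <= len(ref.sequence) else ""
        options = [b for b in "ACGT" if b != nxt]
        base = options[int(rng.integers(len(options)))]
        return Variant(pos, INSERTION, base, 1)
    if u < spec.indel_fraction + spec.transversion_fraction:
        partner = TRANSITION_PARTNER[refbase]
        options = [b for b in "ACGT" if b not in (refbase, partner)]
        return Variant(pos, TRANSVERSION, options[int(rng.integers(len(options)))])
    return Variant(pos, TRANSITION, TRANSITION_PARTNER[refbase])


def simulate_dataset(
    spec: SimulationSpec, ref: ReferenceGenome, emit_sequences: bool = True
) -> SimulationResult:
    """Generate sequences plus full truth, reproducibly from ``spec.seed``.

    Mutation counts per branch are Poisson(branch_years / years_per_mutation);
    each mutation hits a site drawn proportionally to the site-rate profile.
    A repeat hit at an already-derived site reverts it (a back mutation); hits
    at the same site on different lineages are parallel mutations.  With
    ``emit_sequences`` off only the truth is produced (cheap, for
    replicate-heavy validation studies); the truth is identical either way.
    """
    rng = np.random.default_rng(spec.seed)
    founder = frozenset(parse_variant(lab, ref) for lab in spec.founder_variants)

    if spec.topology == "star":
        branches = _star_branches(spec.n_tips, spec.founder_age_years)
    elif spec.topology == "yule":
        branches = _yule_branches(spec.n_tips, spec.founder_age_years, rng)
    else:
        branches = _branches_from_newick(spec.fixed_newick, spec.founder_age_years)

    probs, _hotspots = _site_rates(spec, rng)
    cum = np.cumsum(probs)

    def draw_pos() -> int:
        return int(np.searchsorted(cum, rng.random(), side="right")) + 1

    nodes: dict[int, TreeNode] = {}
    lengths: dict[int, float] = {}
    children: dict[int, list[int]] = {}
    root_sim_id = None
    for nid, length, parent in branches:
        nodes[nid] = TreeNode(nid)
        lengths[nid] = length
        if parent is None:
            root_sim_id = nid
        else:
            children.setdefault(parent, []).append(nid)
    for parent, kids in children.items():
        for kid in sorted(kids):
            nodes[parent].add_child(nodes[kid])
    root = nodes[root_sim_id]

    # drop mutations down the tree, tracking per-lineage site states
    tip_nodes = [nodes[nid] for nid in sorted(nodes) if not nodes[nid].children]
    width = max(3, len(str(len(tip_nodes))))
    tip_ids = {}
    for i, tip in enumerate(tip_nodes):
        tip_ids[tip.node_id] = f"S{i:0{width}d}"
        tip.samples = [tip_ids[tip.node_id]]

    def descend(node: TreeNode, state: dict[int, Variant]) -> None:
        for child in node.children:
            child_state = dict(state)
            n_mut = int(rng.poisson(lengths[child.node_id] / spec.years_per_mutation))
            events: list[MutationEvent] = []
            for _ in range(n_mut):
                for _attempt in range(64):
                    pos = draw_pos()
                    if pos in child_state:
                        # repeat hit at a derived site reverts it
                        prev = child_state.pop(pos)
                        events.append(MutationEvent(prev, is_back=True))
                        break
                    v = _new_variant_at(pos, ref, spec, rng)
                    if v is None:
                        continue
                    # keep indels clear of other derived sites on the same
                    # lineage: adjacent edits have ambiguous alignments, so
                    # their scored representation would not be unique
                    near = [
                        child_state[p]
                        for p in range(pos - 3, pos + 4)
                        if p in child_state
                    ]
                    if any(w.is_indel for w in near) or (v.is_indel and near):
                        continue
                    # substitutions and indels occupy the site exclusively
                    child_state[pos] = v
                    events.append(MutationEvent(v, is_back=False))
                    break
            child.events = sorted(events, key=MutationEvent.sort_key)
            descend(child, child_state)

    founder_state = {v.position: v for v in founder}
    descend(root, founder_state)

    tree = MutationTree(root, root_state=founder)

    tip_variants: dict[str, frozenset[Variant]] = {}
    tip_metadata: dict[str, tuple[str, str]] = {}
    records: list[tuple[str, str]] = []
    regions = list(_REGION_POPULATIONS)
    for tip in tip_nodes:
        sid = tip_ids[tip.node_id]
        variants = tree.node_state(tip)
        tip_variants[sid] = variants
        region = regions[int(rng.choice(len(regions), p=_REGION_WEIGHTS))]
        pops = _REGION_POPULATIONS[region]
        population = pops[int(rng.integers(len(pops)))]
        tip_metadata[sid] = (population, region)
        if emit_sequences:
            seq = apply_variants(ref, variants)
            records.append((f"{sid}|{population}|{region}", seq))

    synonymy = {}
    for variants in tip_variants.values():
        for v in variants:
            if v.label not in synonymy:
                synonymy[v.label] = annotate_synonymous(ref, v)
    for v in founder:
        synonymy.setdefault(v.label, annotate_synonymous(ref, v))

    truth = SimulationTruth(
        tree=tree,
        tip_variants=tip_variants,
        tip_metadata=tip_metadata,
        founder_age_years=spec.founder_age_years,
        years_per_mutation=spec.years_per_mutation,
        founder_variants=founder,
        synonymy=synonymy,
    )
    return SimulationResult(records, truth)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Structured-text (JSON) serialization of the simulation truth."""
    payload = {
        "founder_age_years": truth.founder_age_years,
        "years_per_mutation": truth.years_per_mutation,
        "founder_variants": sorted(v.label for v in truth.founder_variants),
        "tree_newick": tree_to_newick(truth.tree),
        "tips": {
            sid: sorted(v.label for v in variants)
            for sid, variants in sorted(truth.tip_variants.items())
        },
        "metadata": {sid: list(meta) for sid, meta in sorted(truth.tip_metadata.items())},
        "synonymy": dict(sorted(truth.synonymy.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path, ref: ReferenceGenome) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    tree = parse_annotated_newick(payload["tree_newick"], ref)
    return SimulationTruth(
        tree=tree,
        tip_variants={
            sid: frozenset(parse_variant(lab, ref) for lab in labs)
            for sid, labs in payload["tips"].items()
        },
        tip_metadata={sid: tuple(meta) for sid, meta in payload["metadata"].items()},
        founder_age_years=float(payload["founder_age_years"]),
        years_per_mutation=float(payload["years_per_mutation"]),
        founder_variants=frozenset(
            parse_variant(lab, ref) for lab in payload["founder_variants"]
        ),
        synonymy=dict(payload["synonymy"]),
    )
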