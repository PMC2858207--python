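"""End-to-end orchestration: score, classify, tree, date, tabulate.

Outputs are deterministic for a fixed configuration: a variant table, a
classification table, an annotated newick tree, a homoplasy report, a
Table-1-style age table, a frequency table, and a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .classification import (
    UNCLASSIFIED,
    AssignmentResult,
    MotifHierarchy,
    assign_haplogroup,
    load_motif_rules,
    load_packaged_motif_rules,
)
from .dating import (
    ClockModel,
    build_age_table,
    complete_genome_clock,
    format_age_table,
    synonymous_clock,
)
from .phylogeny import annotate_homoplasies, build_mp_tree, write_annotated_newick
from .reference import (
    HaplotypeProfile,
    ReferenceGenome,
    load_packaged_reference,
    load_reference,
    read_samples,
    stub_to_profile,
)
from .scoring import ScoringConfig, filter_variants, score_variants, variant_table
from .summary import tabulate_subclade_frequencies
from .variants import parse_variant

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    samples_path: str
    output_dir: str
    reference_path: str | None = None
    coding_table_path: str | None = None
    motif_rules_path: str | None = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    clade_list: tuple[str, ...] | None = None  # None = every assigned clade + ancestors
    include_indels_in_rho: bool = False
    root_clade: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scoring = ScoringConfig()
        if "scoring" in raw:
            sc = raw.pop("scoring")
            kwargs = {}
            if "excluded_ranges" in sc:
                kwargs["excluded_ranges"] = tuple((int(a), int(b)) for a, b in sc["excluded_ranges"])
            if "exclude_indels_genome_wide" in sc:
                kwargs["exclude_indels_genome_wide"] = bool(sc["exclude_indels_genome_wide"])
            if "min_identity" in sc:
                kwargs["min_identity"] = float(sc["min_identity"])
            scoring = ScoringConfig(**kwargs)
        if "clade_list" in raw and raw["clade_list"] is not None:
            raw["clade_list"] = tuple(raw["clade_list"])
        return cls(scoring=scoring, **raw)

    def validate(self) -> None:
        if not Path(self.samples_path).exists():
            raise PipelineError("config", f"samples file not found: {self.samples_path}")
        for label, path in (
            ("reference", self.reference_path),
            ("coding table", self.coding_table_path),
            ("motif rules", self.motif_rules_path),
        ):
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"{label} file not found: {path}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the output bundle; returns output paths."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # stage: reference
    try:
        if config.reference_path:
            ref = load_reference(config.reference_path, config.coding_table_path)
        else:
            ref = load_packaged_reference()
    except Exception as exc:
        raise PipelineError("reference", str(exc)) from exc

    # stage: motif rules
    try:
        if config.motif_rules_path:
            hierarchy = load_motif_rules(config.motif_rules_path, ref)
        else:
            hierarchy = load_packaged_motif_rules(ref)
    except Exception as exc:
        raise PipelineError("motif_rules", str(exc)) from exc

    # stage: read + score samples
    profiles: list[HaplotypeProfile] = []
    raw_variants: dict[str, set] = {}
    try:
        stubs = read_samples(config.samples_path)
    except Exception as exc:
        raise PipelineError("read_samples", str(exc)) from exc
    for stub in stubs:
        try:
            if stub.sequence is not None:
                variants = score_variants(ref, stub.sequence, config.scoring.min_identity)
            else:
                variants = stub_to_profile(stub, ref).variants
            raw_variants[stub.sample_id] = set(variants)
            profiles.append(
                HaplotypeProfile(
                    stub.sample_id,
                    filter_variants(variants, config.scoring),
                    stub.population,
                    stub.region,
                )
            )
        except Exception as exc:
            raise PipelineError("score", f"sample {stub.sample_id}: {exc}") from exc

    outputs: dict[str, Path] = {}

    # stage: variant table
    vt = variant_table(raw_variants, ref, config.scoring)
    outputs["variants"] = outdir / "variants.tsv"
    vt.to_csv(outputs["variants"], sep="\t", index=False)

    # stage: classification
    assignments: dict[str, AssignmentResult] = {}
    for p in profiles:
        assignments[p.sample_id] = assign_haplogroup(p, hierarchy)
    outputs["classifications"] = outdir / "classifications.tsv"
    with open(outputs["classifications"], "w") as fh:
        fh.write("sample_id\tclade\ttentative\tnotes\n")
        for sid in sorted(assignments):
            a = assignments[sid]
            fh.write(f"{sid}\t{a.clade}\t{a.tentative}\t{'; '.join(a.notes)}\n")

    # stage: tree
    try:
        root_state = ()
        if config.root_clade:
            root_state = tuple(
                parse_variant(lab, ref) for lab in hierarchy.chain_motif(config.root_clade)
            )
        tree = build_mp_tree(profiles, root_state=root_state)
    except Exception as exc:
        raise PipelineError("tree", str(exc)) from exc
    outputs["tree"] = outdir / "tree.nwk"
    write_annotated_newick(tree, outputs["tree"])

    # stage: homoplasy
    report = annotate_homoplasies(tree)
    outputs["homoplasy"] = outdir / "homoplasy.tsv"
    report.to_frame().to_csv(outputs["homoplasy"], sep="\t", index=False)

    # stage: age table
    clade_members: dict[str, list[str]] = {}
    if config.clade_list is not None:
        clades = list(config.clade_list)
    else:
        assigned = {a.clade for a in assignments.values() if a.clade != UNCLASSIFIED}
        clades = sorted(
            {c for clade in assigned for c in hierarchy.chain(clade)},
            key=lambda c: (hierarchy.depth(c), c),
        )
    for clade in clades:
        if clade not in hierarchy.rules:
            raise PipelineError("date", f"clade {clade!r} not in the motif hierarchy")
        in_clade = {clade, *hierarchy.descendants(clade)}
        clade_members[clade] = sorted(
            sid for sid, a in assignments.items() if a.clade in in_clade
        )
    try:
        ages = build_age_table(
            tree,
            clade_members,
            [complete_genome_clock(), synonymous_clock()],
            ref,
            include_indels=config.include_indels_in_rho,
        )
    except Exception as exc:
        raise PipelineError("date", str(exc)) from exc
    outputs["ages"] = outdir / "ages.tsv"
    ages.to_csv(outputs["ages"], sep="\t", index=False, float_format="%.6g")
    outputs["ages_formatted"] = outdir / "ages_formatted.tsv"
    outputs["ages_formatted"].write_text(format_age_table(ages))

    # stage: frequencies
    metadata = {p.sample_id: (p.population, p.region) for p in profiles}
    freq = tabulate_subclade_frequencies(assignments, metadata, hierarchy, by="region")
    outputs["frequencies"] = outdir / "frequencies.tsv"
    freq.to_csv(outputs["frequencies"], sep="\t", index=False, float_format="%.6g")

    # manifest
    manifest = {
        "package": "mitorho",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "samples_path": str(config.samples_path),
            "reference": str(config.reference_path or "packaged synthetic rCRS stand-in"),
            "motif_rules": str(config.motif_rules_path or "packaged"),
            "excluded_ranges": list(map(list, config.scoring.excluded_ranges)),
            "exclude_indels_genome_wide": config.scoring.exclude_indels_genome_wide,
            "include_indels_in_rho": config.include_indels_in_rho,
            "clade_list": list(config.clade_list) if config.clade_list else None,
            "root_clade": config.root_clade,
        },
        "n_samples": len(profiles),
        "tree_mutations": tree.n_events(),
    }
    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return outputs
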