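"""Rho-statistic coalescence dating.

The rho statistic is the average number of mutations separating the sampled
sequences of a clade from the clade's founder haplotype; multiplied by the
molecular-clock calibration (years per mutation) it estimates the clade's
coalescence age.  Its standard error sigma follows from treating per-branch
mutation counts as independent Poisson draws:

    sigma^2 = (1/n^2) * sum over clade edges e of  n_e^2 * l_e

where n_e is the number of sampled individuals below edge e and l_e the
number of counted mutations on e.  Two clock calibrations are provided:
the complete-genome clock (one mutation every 3,624 years, counting all
retained substitutions) and the synonymous clock (one mutation every 7,884
years, counting synonymous coding substitutions only).  An optional monotone
correction curve (age-calculator style, supplied as interpolation knots) can
be plugged into either clock; the default is the identity (strictly linear
clock).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylogeny import MutationEvent, MutationTree, TreeNode
from .reference import ReferenceGenome
from .scoring import SYNONYMOUS, annotate_synonymous

COMPLETE_GENOME_YEARS_PER_MUTATION = 3624.0
SYNONYMOUS_YEARS_PER_MUTATION = 7884.0

Selector = Callable[[MutationEvent], bool]


class DatingError(ValueError):
    pass


@dataclass(frozen=True)
class ClockModel:
    """A molecular clock: calibration, variant selector, optional correction."""

    name: str
    years_per_mutation: float
    selector: str = "substitutions"  # 'substitutions' | 'synonymous' | 'all'
    correction: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.years_per_mutation <= 0:
            raise DatingError("years_per_mutation must be positive")

    def correct(self, years: float) -> float:
        if self.correction is None:
            return years
        return float(self.correction(years))


def complete_genome_clock(**kw) -> ClockModel:
    return ClockModel("complete_genome", COMPLETE_GENOME_YEARS_PER_MUTATION, "substitutions", **kw)


def synonymous_clock(**kw) -> ClockModel:
    return ClockModel("synonymous", SYNONYMOUS_YEARS_PER_MUTATION, "synonymous", **kw)


def make_selector(
    clock: ClockModel,
    ref: ReferenceGenome | None = None,
    include_indels: bool = False,
) -> Selector:
    """Build the event filter for a clock.

    ``substitutions`` counts retained transitions and transversions (back
    mutations included: they are observed mutation events on the path);
    ``synonymous`` additionally requires a synonymous coding annotation and
    needs the reference; ``all`` counts every event, or substitutions only
    unless ``include_indels``.
    """
    if clock.selector == "substitutions":
        if include_indels:
            return lambda ev: True
        return lambda ev: ev.variant.is_substitution
    if clock.selector == "synonymous":
        if ref is None:
            raise DatingError("synonymous selector requires a reference genome")
        cache: dict = {}

        def select(ev: MutationEvent) -> bool:
            v = ev.variant
            if not v.is_substitution:
                return False
            if v not in cache:
                cache[v] = annotate_synonymous(ref, v)
            return cache[v] == SYNONYMOUS

        return select
    if clock.selector == "all":
        return lambda ev: True
    raise DatingError(f"unknown selector {clock.selector!r}")


@dataclass(frozen=True)
class CladeAgeEstimate:
    clade_name: str
    n: int
    rho: float
    sigma: float
    age_years: float
    ci_low: float
    ci_high: float
    clock_name: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DatingError("clade must contain at least one sample")
        if self.rho < 0 or self.sigma < 0:
            raise DatingError("rho and sigma must be non-negative")


def _edge_stats(
    tree: MutationTree, clade_root: TreeNode, selector: Selector | None
) -> tuple[list[tuple[int, int]], int]:
    """(n_e, l_e) for every edge strictly below the clade root, and n."""
    if clade_root not in tree.nodes():
        raise DatingError("clade root is not a node of the tree")
    selector = selector or (lambda ev: True)

    stats: list[tuple[int, int]] = []

    def walk(node: TreeNode) -> int:
        below = node.multiplicity
        for child in node.children:
            below += walk(child)
        if node is not clade_root:
            l_e = sum(1 for ev in node.events if selector(ev))
            stats.append((below, l_e))
        return below

    n = walk(clade_root)
    if n < 1:
        raise DatingError("clade has no sampled tips")
    return stats, n


def compute_rho(
    tree: MutationTree, clade_root: TreeNode, selector: Selector | None = None
) -> tuple[float, int]:
    """Average selector-passing mutation count from the clade root to its tips.

    Tips are weighted by haplotype multiplicity (one term per sampled
    individual).  Exact rational arithmetic internally.
    """
    stats, n = _edge_stats(tree, clade_root, selector)
    total = sum(Fraction(n_e * l_e) for n_e, l_e in stats)
    return float(total / n), n


def compute_sigma(
    tree: MutationTree, clade_root: TreeNode, selector: Selector | None = None
) -> float:
    """Poisson standard error of rho from the clade's edge structure."""
    stats, n = _edge_stats(tree, clade_root, selector)
    var = sum(Fraction(n_e * n_e * l_e) for n_e, l_e in stats) / (n * n)
    return float(np.sqrt(float(var)))


def rho_to_age(
    rho: float, sigma: float, clock: ClockModel
) -> tuple[float, float, float]:
    """Convert rho to years with a 95% CI (normal approximation).

    age = correction(rho * years_per_mutation); CI bounds transform the
    endpoints rho +/- 1.96 sigma, with the lower bound floored at zero.
    """
    if rho < 0 or sigma < 0:
        raise DatingError("rho and sigma must be non-negative")
    age = clock.correct(rho * clock.years_per_mutation)
    lo = clock.correct(max(0.0, rho - 1.96 * sigma) * clock.years_per_mutation)
    hi = clock.correct((rho + 1.96 * sigma) * clock.years_per_mutation)
    return age, lo, hi


def estimate_clade_age(
    tree: MutationTree,
    clade_root: TreeNode,
    clock: ClockModel,
    ref: ReferenceGenome | None = None,
    clade_name: str = "",
    include_indels: bool = False,
) -> CladeAgeEstimate:
    selector = make_selector(clock, ref, include_indels)
    rho, n = compute_rho(tree, clade_root, selector)
    sigma = compute_sigma(tree, clade_root, selector)
    age, lo, hi = rho_to_age(rho, sigma, clock)
    return CladeAgeEstimate(clade_name or "clade", n, rho, sigma, age, lo, hi, clock.name)


def monotone_correction(knots: Sequence[tuple[float, float]]) -> Callable[[float], float]:
    """Piecewise-linear monotone age correction from (raw_years, corrected_years) knots.

    Knots must be strictly increasing in both coordinates; (0, 0) is implied.
    Beyond the last knot the final slope is extrapolated.
    """
    pts = sorted({(float(a), float(b)) for a, b in knots})
    if not pts or pts[0] != (0.0, 0.0):
        pts = [(0.0, 0.0)] + pts
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) < 0):
        raise DatingError("correction knots must be monotone non-decreasing")

    def correct(y: float) -> float:
        if y <= xs[-1]:
            return float(np.interp(y, xs, ys))
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2]) if len(xs) > 1 else 1.0
        return float(ys[-1] + slope * (y - xs[-1]))

    return correct


def build_age_table(
    tree: MutationTree,
    clade_members: Mapping[str, Sequence[str]],
    clocks: Sequence[ClockModel],
    ref: ReferenceGenome | None = None,
    include_indels: bool = False,
) -> pd.DataFrame:
    """One row per clade with ages (in ky) under every clock.

    ``clade_members`` maps clade name to the sample ids in it; the clade root
    is the most recent common ancestor of those tips.  Clades with zero
    members are flagged, never dropped.
    """
    rows = []
    for clade in clade_members:
        members = list(clade_members[clade])
        row: dict = {"clade": clade, "n": len(members), "flag": ""}
        if not members:
            row["flag"] = "empty clade"
            rows.append(row)
            continue
        tips = [tree.find_tip(sid) for sid in members]
        clade_root = tree.mrca(tips)
        n_below = tree.n_samples(clade_root)
        row["n"] = len(members)
        if n_below != len(members):
            row["flag"] = f"mrca spans {n_below} samples"
        for clock in clocks:
            est = estimate_clade_age(
                tree, clade_root, clock, ref, clade, include_indels=include_indels
            )
            # rho is over everything below the MRCA, so report that n
            row["n"] = est.n
            p = clock.name
            row[f"rho_{p}"] = est.rho
            row[f"sigma_{p}"] = est.sigma
            row[f"age_ky_{p}"] = est.age_years / 1000.0
            row[f"ci_low_ky_{p}"] = est.ci_low / 1000.0
            row[f"ci_high_ky_{p}"] = est.ci_high / 1000.0
            row[f"se_ky_{p}"] = est.sigma * clock.years_per_mutation / 1000.0
        rows.append(row)
    return pd.DataFrame(rows)


def format_age_table(table: pd.DataFrame) -> str:
    """Human-readable table: ky to one decimal, CI for the complete-genome
    clock, +/- s.e. for the synonymous clock (when those clocks are present)."""
    lines = ["clade\tn\tcomplete_genome_ky_95CI\tsynonymous_ky_se\tflag"]
    for _, row in table.iterrows():
        cg = syn = "-"
        if "age_ky_complete_genome" in row and pd.notna(row.get("age_ky_complete_genome")):
            cg = (
                f"{row['age_ky_complete_genome']:.1f} "
                f"({row['ci_low_ky_complete_genome']:.1f}; {row['ci_high_ky_complete_genome']:.1f})"
            )
        if "age_ky_synonymous" in row and pd.notna(row.get("age_ky_synonymous")):
            syn = f"{row['age_ky_synonymous']:.1f}±{row['se_ky_synonymous']:.1f}"
        lines.append(f"{row['clade']}\t{row['n']}\t{cg}\t{syn}\t{row.get('flag', '')}")
    return "\n".join(lines) + "\n"
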