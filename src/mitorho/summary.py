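"""Subclade frequency tabulation by population or region."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .classification import UNCLASSIFIED, AssignmentResult, MotifHierarchy


def tabulate_subclade_frequencies(
    assignments: Mapping[str, "AssignmentResult | str"],
    metadata: Mapping[str, tuple[str, str]],
    hierarchy: MotifHierarchy | None = None,
    level: str | None = None,
    by: str = "population",
) -> pd.DataFrame:
    """Counts and within-stratum fractions of clade assignments.

    ``metadata`` maps sample id to (population, region); ``by`` selects the
    stratum.  Samples lacking metadata land in an ``unknown`` stratum, never
    silently dropped.  With ``level`` set (and a hierarchy), assignments are
    aggregated up to the named clade or its siblings at the same depth:
    each assignment is replaced by its ancestor at the depth of ``level``
    (assignments above that depth keep their own name).
    """
    if by not in ("population", "region"):
        raise ValueError("by must be 'population' or 'region'")
    rows = []
    for sample_id in sorted(assignments):
        result = assignments[sample_id]
        clade = result.clade if isinstance(result, AssignmentResult) else str(result)
        if level is not None and hierarchy is not None and clade != UNCLASSIFIED:
            depth = hierarchy.depth(level)
            chain = hierarchy.chain(clade)
            if len(chain) > depth:
                clade = chain[depth]
        meta = metadata.get(sample_id)
        stratum = meta[0 if by == "population" else 1] if meta else "unknown"
        stratum = stratum or "unknown"
        rows.append({"sample_id": sample_id, "clade": clade, by: stratum})
    df = pd.DataFrame(rows)
    counts = (
        df.groupby([by, "clade"], sort=True).size().rename("count").reset_index()
    )
    totals = df.groupby(by, sort=True).size().rename("stratum_total")
    counts = counts.merge(totals, on=by)
    counts["fraction"] = counts["count"] / counts["stratum_total"]
    return counts[[by, "clade", "count", "stratum_total", "fraction"]]
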