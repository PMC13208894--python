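"""Pathway over-representation analysis (ORA) of differential metabolites.

Plain hypergeometric upper-tail test of the overlap between a hit list and
each pathway's member set, both restricted to an explicit metabolite
universe. No topology/impact weighting and no multiple-testing correction on
the pathway p values; pathways with p < cutoff (default 0.05) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom


@dataclass
class PathwaySet:
    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)


def read_pathways(path) -> list[PathwaySet]:
    """Read a tab-separated pathway file: id <TAB> name <TAB> m1,m2,..."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 3 tab-separated fields at line {lineno}")
        pid, name, members = parts
        out.append(PathwaySet(pid, name, frozenset(
            m.strip() for m in members.split(",") if m.strip())))
    return out


def pathways_from_database(database: pd.DataFrame) -> list[PathwaySet]:
    """Build pathway sets from the ``pathways`` column of a metabolite database."""
    mapping: dict[str, set[str]] = {}
    for _, row in database.iterrows():
        for pid in str(row["pathways"]).split(";"):
            pid = pid.strip()
            if pid:
                mapping.setdefault(pid, set()).add(row["name"])
    return [PathwaySet(pid, pid, frozenset(members))
            for pid, members in sorted(mapping.items())]


def ora_enrich(
    hits,
    universe,
    pathways: list[PathwaySet],
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each pathway.

    p = P(X >= observed overlap) with X hypergeometric on (universe size,
    pathway size within universe, hit-list size). Rows sorted ascending by p.
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise ValueError(f"hits not in universe: {sorted(stray)}")
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")

    M, n_hits = len(universe), len(hits)
    rows = []
    for pw in pathways:
        members = pw.members & universe
        k = len(members & hits)
        K = len(members)
        # upper tail P(X >= k); k = 0 gives p = 1
        p = float(hypergeom.sf(k - 1, M, K, n_hits)) if K else 1.0
        rows.append({
            "pathway_id": pw.pathway_id,
            "name": pw.name,
            "overlap": k,
            "pathway_size": K,
            "universe_size": M,
            "n_hits": n_hits,
            "p": min(p, 1.0),
            "significant": bool(K and min(p, 1.0) < cutoff),
        })
    out = pd.DataFrame(rows, columns=[
        "pathway_id", "name", "overlap", "pathway_size", "universe_size",
        "n_hits", "p", "significant",
    ])
    return out.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)
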