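"""Pathway over-representation and topology-impact analysis.

Two complementary scores per pathway, following the MetaboAnalyst-style
recipe used for metabolite hit lists:

* **enrichment** — upper-tail hypergeometric probability that at least the
  observed number of differentially expressed metabolites (DEMs) fall in the
  pathway, given the mapped universe;
* **impact** — the sum of the DEM members' relative betweenness centralities
  in the pathway's metabolic network, divided by the sum over all members.

A pathway is called significant when raw P < .05 and impact > 0; FDR q-values
(Benjamini–Hochberg) are reported alongside.  Only metabolites confidently
identified (id level 1) and carrying a database id present in the library
universe enter the analysis, and the analysis refuses to run on fewer than
three DEMs.

The packaged library (``data/synthetic_library.gmt``/``.sif``) is a small
synthetic fixture — named pathways with invented member ids — not real KEGG
content.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Pathway",
    "PathwayLibrary",
    "InsufficientDEMsError",
    "load_library",
    "load_default_library",
    "map_to_library",
    "ora_pvalue",
    "impact_score",
    "bh_fdr",
    "run_pathway_analysis",
    "MIN_DEMS",
]

#: Minimum number of mapped DEMs required to run a pathway analysis.
MIN_DEMS = 3


class InsufficientDEMsError(ValueError):
    """Raised when fewer metabolites map than a pathway analysis requires."""


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: frozenset[str]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.members or b not in self.members:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge ({a}, {b}) touches a non-member"
                )


@dataclass(frozen=True)
class PathwayLibrary:
    """Pathway membership + within-pathway edges; universe = union of members."""

    pathways: Mapping[str, Pathway]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(m for p in self.pathways.values() for m in p.members)

    def __len__(self) -> int:
        return len(self.pathways)


def load_library(gmt_path, sif_path=None) -> PathwayLibrary:
    """Load a library from a GMT membership file and an optional SIF edge TSV.

    GMT lines: ``pathway_id<TAB>name<TAB>member1<TAB>member2...``.
    SIF TSV columns: ``pathway_id, node_a, node_b`` (undirected edges).
    """
    entries: dict[str, tuple[str, list[str]]] = {}
    with open(gmt_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            pid, name, members = parts[0], parts[1], parts[2:]
            if pid in entries:
                raise ValueError(f"duplicate pathway id {pid}")
            entries[pid] = (name, members)
    edges: dict[str, list[tuple[str, str]]] = {pid: [] for pid in entries}
    if sif_path is not None:
        sif = pd.read_csv(sif_path, sep="\t")
        for pid, a, b in sif[["pathway_id", "node_a", "node_b"]].itertuples(index=False):
            if pid not in edges:
                raise ValueError(f"SIF references unknown pathway {pid}")
            edges[pid].append((str(a), str(b)))
    pathways = {
        pid: Pathway(pid, name, frozenset(members), tuple(edges[pid]))
        for pid, (name, members) in entries.items()
    }
    return PathwayLibrary(pathways=pathways)


def load_default_library() -> PathwayLibrary:
    """The packaged synthetic 12-pathway fixture library."""
    data = resources.files("cortidyn.data")
    with resources.as_file(data / "synthetic_library.gmt") as gmt, resources.as_file(
        data / "synthetic_library.sif"
    ) as sif:
        return load_library(gmt, sif)


def map_to_library(
    classified: pd.DataFrame,
    library: PathwayLibrary,
    class_filter: str | Iterable[str],
    *,
    id_level_filter: int = 1,
) -> set[str]:
    """Map classified features of the requested class(es) onto the library.

    Keeps features whose identification level is at most ``id_level_filter``
    (1 = confidently identified) and whose hmdb_id is present in the library
    universe; duplicates across platforms collapse to one DEM per id.

    ``classified`` needs columns ``class``, ``id_level`` and ``hmdb_id``.
    """
    if len(library) == 0:
        raise ValueError("empty pathway library")
    classes = {class_filter} if isinstance(class_filter, str) else set(class_filter)
    sub = classified[classified["class"].isin(classes)]
    sub = sub[sub["id_level"].le(id_level_filter) & sub["hmdb_id"].notna()]
    return set(sub["hmdb_id"]) & set(library.universe)


def ora_pvalue(n_universe: int, n_pathway: int, n_dems: int, n_hits: int) -> float:
    """Upper-tail hypergeometric probability P(X >= n_hits).

    X counts how many of ``n_dems`` metabolites drawn without replacement
    from a universe of ``n_universe`` land among the pathway's ``n_pathway``
    members in that universe.
    """
    if not 0 <= n_pathway <= n_universe or not 0 <= n_dems <= n_universe:
        raise ValueError("inconsistent counts: pathway/DEM sizes exceed universe")
    if n_hits < 0 or n_hits > min(n_pathway, n_dems):
        raise ValueError("n_hits must lie in [0, min(n_pathway, n_dems)]")
    return float(hypergeom.sf(n_hits - 1, n_universe, n_pathway, n_dems))


def impact_score(pathway: Pathway, dems: Iterable[str]) -> float:
    """Topology impact: DEM share of total relative betweenness centrality.

    Each member's importance is its betweenness centrality in the pathway
    graph, normalised by (n-1)(n-2)/2 (0 by convention for graphs with fewer
    than 3 nodes).  Impact = sum over DEM members / sum over all members, and
    0 when no member has positive centrality (e.g. edgeless pathways).
    """
    dems = set(dems)
    unknown = dems - set(pathway.members)
    if unknown:
        raise ValueError(f"DEMs not members of pathway {pathway.pathway_id}: {sorted(unknown)}")
    g = nx.Graph()
    g.add_nodes_from(pathway.members)
    g.add_edges_from(pathway.edges)
    bc = nx.betweenness_centrality(g, normalized=True)
    total = sum(bc.values())
    if total == 0:
        return 0.0
    return float(sum(bc[m] for m in dems) / total)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, q in [p, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_pathway_analysis(
    classified: pd.DataFrame,
    library: PathwayLibrary,
    class_filter: str | Iterable[str],
    *,
    id_level_filter: int = 1,
    alpha: float = 0.05,
    universe: str = "library",
) -> pd.DataFrame:
    """Enrichment + topology analysis of one DEM class against the library.

    Parameters
    ----------
    classified : DataFrame
        Feature classification with ``class``, ``id_level``, ``hmdb_id``.
    class_filter : str or iterable of str
        Which class(es) form the DEM list (e.g. ``"unique_AUC"``).
    universe : {"library", "detected"}
        Reference set for the hypergeometric test: the whole library universe
        (default, the web-tool behaviour) or only library metabolites that
        were detected and mapped in ``classified``.

    Returns
    -------
    DataFrame sorted by raw p: pathway_id, name, n_members, n_hits, p_raw,
    q_fdr, impact, neg_log10_p, significant (p_raw < alpha and impact > 0).
    Pathways with no member in the universe are omitted.

    Raises
    ------
    InsufficientDEMsError
        With fewer than three mapped DEMs (no analysis is meaningful).
    """
    dems = map_to_library(classified, library, class_filter, id_level_filter=id_level_filter)
    if len(dems) < MIN_DEMS:
        raise InsufficientDEMsError(
            f"only {len(dems)} metabolite(s) mapped; three or more are needed for pathway analysis"
        )
    if universe == "library":
        uni = set(library.universe)
    elif universe == "detected":
        detected = set(classified.loc[classified["hmdb_id"].notna(), "hmdb_id"])
        uni = detected & set(library.universe)
    else:
        raise ValueError("universe must be 'library' or 'detected'")
    dems &= uni
    rows = []
    for pid in sorted(library.pathways):
        pw = library.pathways[pid]
        members_in_uni = set(pw.members) & uni
        if not members_in_uni:
            continue
        hits = dems & members_in_uni
        p = ora_pvalue(len(uni), len(members_in_uni), len(dems), len(hits))
        imp = impact_score(pw, hits)
        rows.append(
            {
                "pathway_id": pid,
                "name": pw.name,
                "n_members": len(members_in_uni),
                "n_hits": len(hits),
                "p_raw": p,
                "impact": imp,
            }
        )
    res = pd.DataFrame(rows)
    res["q_fdr"] = bh_fdr(res["p_raw"].to_numpy())
    res["neg_log10_p"] = -np.log10(res["p_raw"].clip(lower=np.finfo(float).tiny))
    res["significant"] = (res["p_raw"] < alpha) & (res["impact"] > 0)
    res = res.sort_values(["p_raw", "pathway_id"], kind="stable").reset_index(drop=True)
    return res[
        ["pathway_id", "name", "n_members", "n_hits", "p_raw", "q_fdr", "impact",
         "neg_log10_p", "significant"]
    ]
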