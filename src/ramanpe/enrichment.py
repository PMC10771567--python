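"""Pathway over-representation analysis (ORA) for significant bands.

Significant bands are mapped to compounds (strongest band per metabolite
only; class-level generic bands such as the amides, DNA backbone, and bulk
carbohydrate bands are dropped), then each pathway in a bundled KEGG-style
map is scored with the upper-tail hypergeometric test and an enrichment
ratio of observed over expected hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .spectra import PeakDefinition


@dataclass
class PathwayMap:
    """pathway_id -> (name, member compound ids); universe = union of members."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    @property
    def universe(self) -> frozenset[str]:
        members: set[str] = set()
        for _, compounds in self.pathways.values():
            members |= compounds
        return frozenset(members)


def load_pathway_map(path: str | Path | None = None) -> PathwayMap:
    """Load a pathway map TSV (pathway_id, pathway_name, compound_id);
    default is the bundled plasma-metabolite map."""
    if path is None:
        with resources.files("ramanpe.data").joinpath("pathway_map.tsv").open("rb") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"pathway_id", "pathway_name", "compound_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"pathway map missing columns: {sorted(missing)}")
    pathways = {}
    for pid, sub in df.groupby("pathway_id"):
        members = frozenset(sub["compound_id"])
        if not members:
            raise ValueError(f"pathway {pid} has no members")
        pathways[str(pid)] = (str(sub["pathway_name"].iloc[0]), members)
    return PathwayMap(pathways=pathways)


def map_peaks_to_compounds(
    peak_list: list[float], peak_table: list[PeakDefinition]
) -> frozenset[str]:
    """Compound ids of the strongest (primary) bands among ``peak_list``;
    generic class-level bands are excluded, duplicates collapse."""
    by_wavenumber = {p.nominal_wavenumber: p for p in peak_table}
    compounds = set()
    for w in peak_list:
        peak = by_wavenumber.get(float(w))
        if peak is None or peak.is_generic or not peak.primary_peak:
            continue
        compounds.add(peak.compound_id)
    return frozenset(compounds)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    pathway_size: int  # K
    query_size: int  # n
    hits: int  # k
    expected: float  # n·K/N
    enrichment_ratio: float  # k / expected
    p_value: float  # P(X >= k), X ~ Hypergeom(N, K, n)


def ora_hypergeometric(query: frozenset[str], pathway_map: PathwayMap) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric ORA of a compound query against every pathway.

    Compounds outside the map's universe are dropped (with no effect on N).
    Results are sorted by ascending p-value.
    """
    universe = pathway_map.universe
    if not universe:
        raise ValueError("empty pathway universe")
    query_in = frozenset(query) & universe
    n_universe = len(universe)
    n_query = len(query_in)
    results = []
    for pid, (name, members) in pathway_map.pathways.items():
        k_hits = len(query_in & members)
        size = len(members)
        expected = n_query * size / n_universe
        ratio = k_hits / expected if expected > 0 else 0.0
        # sf(k-1) = P(X >= k); equals 1 for k = 0
        p = float(hypergeom.sf(k_hits - 1, n_universe, size, n_query))
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_name=name,
                pathway_size=size,
                query_size=n_query,
                hits=k_hits,
                expected=expected,
                enrichment_ratio=ratio,
                p_value=min(p, 1.0),
            )
        )
    return sorted(results, key=lambda r: (r.p_value, r.pathway_id))


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
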