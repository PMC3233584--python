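"""Areas of endemism and cross-area divergence pattern tables.

Specimens are mapped to areas of endemism / ecoregions through a declarative
locality -> area table (no geospatial computation); per-species divergences
between clusters occupying different areas are then aggregated into an
area-pair ranking ("most common patterns of geographic distribution").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .delimit import ClusterPartition
from .distance import DistanceMatrix
from .errors import DatasetError
from .seqio import Dataset

logger = logging.getLogger(__name__)

#: controlled vocabulary of area codes (Amazonian + Atlantic Forest areas of
#: endemism and surrounding ecoregions)
DEFAULT_AREA_VOCABULARY: dict[str, str] = {
    "N": "Napo",
    "Ron": "Rondonian",
    "Be": "Belem",
    "Gu": "Guyanian",
    "Im": "Imeri",
    "In": "Inambari",
    "Pa1": "Para 1",
    "Pa2": "Para 2",
    "SEAF": "Southeast Atlantic Forest",
    "SWAF": "Southwest Atlantic Forest",
    "NAF": "North Atlantic Forest",
    "Caa": "Caatinga",
    "Ch": "Chaco",
    "Pu": "Puna",
    "Pt": "Patagonia",
    "Pm": "Pampas",
}

#: starter locality -> area assignments for localities named in the survey
DEFAULT_LOCALITY_AREAS: dict[str, str] = {
    "Juruena": "Ron",
    "Aripuana": "Ron",
    "Aripuanã": "Ron",
}


@dataclass
class AreaTable:
    """Locality -> area mapping over a controlled area-code vocabulary."""

    locality_to_area: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LOCALITY_AREAS))
    vocabulary: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_AREA_VOCABULARY))

    def __post_init__(self):
        bad = sorted(set(self.locality_to_area.values()) - set(self.vocabulary))
        if bad:
            raise DatasetError(f"area codes outside vocabulary: {bad}")

    @classmethod
    def from_tsv(cls, path: str | Path, vocabulary: dict[str, str] | None = None
                 ) -> "AreaTable":
        """Load a two-column TSV (locality, area)."""
        df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
        if not {"locality", "area"} <= set(df.columns):
            raise DatasetError("area table needs 'locality' and 'area' columns")
        mapping = dict(zip(df["locality"], df["area"]))
        return cls(mapping, vocabulary or dict(DEFAULT_AREA_VOCABULARY))


def assign_areas(dataset: Dataset, table: AreaTable) -> Dataset:
    """Resolve per-specimen areas: an explicit area wins over locality lookup.

    Unmapped localities leave the area missing, with a logged list; such
    records still flow through distances and delimitation but are excluded
    from sympatry calls and area-pair tables.
    """
    resolved: dict[str, str | None] = {}
    unmapped: list[str] = []
    for r in dataset.records:
        if r.area:
            if r.area not in table.vocabulary:
                raise DatasetError(
                    f"record {r.specimen_id!r}: area code {r.area!r} "
                    "outside vocabulary")
            continue
        area = table.locality_to_area.get(r.locality)
        if area is None:
            if r.locality:
                unmapped.append(r.locality)
            continue
        resolved[r.specimen_id] = area
    if unmapped:
        logger.warning("unmapped localities left without area: %s",
                       sorted(set(unmapped)))
    return dataset.with_areas(resolved) if resolved else dataset


@dataclass
class AreaPairPattern:
    """One unordered area pair with the species divergent across it."""

    area_a: str
    area_b: str
    #: species -> (min, max) K2P between specimens straddling the pair
    species_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species_ranges)

    @property
    def pair_label(self) -> str:
        return f"{self.area_a}-{self.area_b}"


def area_pair_patterns(
    partitions: list[ClusterPartition],
    matrix: DistanceMatrix,
    dataset: Dataset,
) -> list[AreaPairPattern]:
    """Aggregate cross-area divergences of multi-cluster species per area pair.

    For each species with >= 2 clusters, every unordered pair of areas
    represented by *distinct* clusters contributes that species with the
    (min, max) K2P over specimen pairs drawn from the two areas in different
    clusters. Multi-area clusters credit all their areas (cross-product
    rule). Patterns are ranked by species count descending, ties broken
    alphabetically by pair label.
    """
    acc: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    for part in partitions:
        if part.n_clusters < 2:
            continue
        members_with_area = [
            m for c in part.clusters for m in c.members if dataset[m].area
        ]
        if not members_with_area:
            logger.info("species %s lacks area data; skipped in area pairs",
                        part.species)
            continue
        cluster_of = {m: c.label for c in part.clusters for m in c.members}
        area_pairs: set[tuple[str, str]] = set()
        for x in range(len(part.clusters)):
            for y in range(x + 1, len(part.clusters)):
                for a1 in part.clusters[x].areas:
                    for a2 in part.clusters[y].areas:
                        if a1 != a2:
                            area_pairs.add(tuple(sorted((a1, a2))))
        for a1, a2 in area_pairs:
            vals = []
            for m1 in members_with_area:
                for m2 in members_with_area:
                    if m1 >= m2 or cluster_of[m1] == cluster_of[m2]:
                        continue
                    pa, pb = dataset[m1].area, dataset[m2].area
                    if {pa, pb} != {a1, a2}:
                        continue
                    d = matrix.get(m1, m2)
                    if not math.isnan(d):
                        vals.append(d)
            if not vals:
                continue
            acc.setdefault((a1, a2), {})[part.species] = (
                float(min(vals)), float(max(vals)))
    patterns = [AreaPairPattern(a, b, ranges) for (a, b), ranges in acc.items()]
    patterns.sort(key=lambda p: (-p.n_species, p.pair_label))
    return patterns
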