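"""Divergent-cluster detection, barcode sharing and species identifiability.

A species is called *not distinguishable* by its barcodes when any of three
rules fires: (a) it is not monophyletic on the analysis tree; (b) it shares
barcodes with another species; (c) its intraspecific variation overlaps the
lowest 5% of among-species variation (or its sister sits closer than 1% K2P)
while reciprocal monophyly cannot be told from random branching at p = 0.05.
Non-identifiable species fall into non-exclusive categories: I sharing with
a sympatric species, II sharing with an allopatric species, III monophyletic
but very close to the sister species, IV paraphyletic with lineages more
than 1.5% divergent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix
from .errors import DatasetError
from .phylo import MonophylyResult, is_monophyletic, reciprocal_monophyly_p
from .seqio import Dataset

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_THRESHOLD = 0.015  # 1.5% K2P
DEFAULT_CLOSE_SISTER_CUT = 0.01   # 1% K2P
DEFAULT_ALPHA = 0.05


@dataclass
class Cluster:
    label: str
    members: list[str]
    within_min: float | None  # None for singletons
    within_max: float | None
    areas: set[str] = field(default_factory=set)
    modal_areas: list[str] = field(default_factory=list)


@dataclass
class ClusterPartition:
    """Single-linkage partition of one species' specimens at a K2P threshold."""

    species: str
    threshold: float
    clusters: list[Cluster]
    #: (label_a, label_b) -> (min, max) K2P between the two clusters
    between: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def max_between(self) -> float | None:
        if not self.between:
            return None
        return max(v[1] for v in self.between.values())


def detect_clusters(
    matrix: DistanceMatrix,
    members,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    species: str = "",
    dataset: Dataset | None = None,
) -> ClusterPartition:
    """Single-linkage clusters: connected components of the d <= threshold graph.

    Between-cluster minimum distances are then guaranteed > threshold, making
    the "clusters with minimum pairwise distances higher than the threshold"
    reading literally true. Clusters are labelled a, b, c, ... by decreasing
    size, ties by smallest member id.
    """
    members = list(members)
    if not members:
        raise ValueError("members must be nonempty")
    sub = matrix.require_complete(members)
    n = len(members)
    adj = csr_matrix((sub <= threshold) & ~np.eye(n, dtype=bool))
    n_comp, assign = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for idx, comp in enumerate(assign):
        groups.setdefault(int(comp), []).append(idx)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(members[i] for i in g)))

    def _areas(idxs: list[int]) -> tuple[set[str], list[str]]:
        if dataset is None:
            return set(), []
        codes = [dataset[members[i]].area for i in idxs]
        codes = [c for c in codes if c]
        if not codes:
            return set(), []
        freq: dict[str, int] = {}
        for c in codes:
            freq[c] = freq.get(c, 0) + 1
        top = max(freq.values())
        return set(freq), sorted(c for c, k in freq.items() if k == top)

    clusters: list[Cluster] = []
    for rank, idxs in enumerate(ordered):
        label = chr(ord("a") + rank) if rank < 26 else f"c{rank}"
        if len(idxs) > 1:
            vals = [sub[i, j] for i in idxs for j in idxs if i < j]
            wmin, wmax = float(min(vals)), float(max(vals))
        else:
            wmin = wmax = None
        areas, modal = _areas(idxs)
        clusters.append(Cluster(label, [members[i] for i in idxs], wmin, wmax,
                                areas, modal))
    between: dict[tuple[str, str], tuple[float, float]] = {}
    for x in range(len(ordered)):
        for y in range(x + 1, len(ordered)):
            vals = [sub[i, j] for i in ordered[x] for j in ordered[y]]
            between[(clusters[x].label, clusters[y].label)] = (
                float(min(vals)), float(max(vals)))
    return ClusterPartition(species, threshold, clusters, between)


@dataclass(frozen=True)
class SharingVerdict:
    species_a: str
    species_b: str
    shared: bool
    zero_distance: bool
    interdigitated: bool
    geography: str  # "sympatric" | "allopatric" | "undetermined"


def barcode_sharing(
    matrix: DistanceMatrix,
    dataset: Dataset,
    species_a: str,
    species_b: str,
    tree: dendropy.Tree | None = None,
) -> SharingVerdict:
    """Do two congeneric species share barcodes?

    "Shared" means either some cross-species pair is at distance zero over
    the compared sites, or the two species are mutually non-monophyletic
    with interdigitated tips on the analysis tree. The verdict is annotated
    sympatric when the species have at least one area code in common,
    allopatric when both have area data but no overlap, undetermined
    otherwise.
    """
    if dataset.genus_of(species_a) != dataset.genus_of(species_b):
        raise DatasetError(
            f"{species_a!r} and {species_b!r} are not congeners; "
            "sharing is only assessed within genera"
        )
    mem_a = dataset.species_members(species_a)
    mem_b = dataset.species_members(species_b)
    zero = False
    for x in mem_a:
        for y in mem_b:
            d = matrix.get(x, y)
            if not math.isnan(d) and d == 0.0:
                zero = True
                break
        if zero:
            break
    interdig = False
    if tree is not None:
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        ta = [x for x in mem_a if x in tips]
        tb = [x for x in mem_b if x in tips]
        if ta and tb:
            ra = is_monophyletic(tree, ta)
            rb = is_monophyletic(tree, tb)
            if (ra.status == "non-monophyletic" and rb.status == "non-monophyletic"):
                interdig = bool(ra.intruders & set(tb)) or bool(rb.intruders & set(ta))
    areas_a = {dataset[x].area for x in mem_a if dataset[x].area}
    areas_b = {dataset[x].area for x in mem_b if dataset[x].area}
    if not areas_a or not areas_b:
        geography = "undetermined"
    elif areas_a & areas_b:
        geography = "sympatric"
    else:
        geography = "allopatric"
    return SharingVerdict(species_a, species_b, zero or interdig, zero, interdig,
                          geography)


@dataclass
class SpeciesAssessment:
    species: str
    n_samples: int
    monophyly_status: str
    monophyly: MonophylyResult | None
    shares_with: list[tuple[str, str]]  # (partner species, geography)
    categories: set[str]
    identifiable: bool
    rule_a: bool
    rule_b: bool
    rule_c: bool
    sister_species: str | None
    monophyly_test_p: float | None
    max_intraspecific: float | None
    min_to_nearest_congener: float | None
    n_clusters: int
    rule_c_overlap_trigger: bool = False
    rule_c_close_sister_trigger: bool = False


def _species_max_intra(matrix: DistanceMatrix, members: list[str]) -> float | None:
    if len(members) < 2:
        return None
    sub = matrix.submatrix(members)
    iu = np.triu_indices(len(members), 1)
    vals = sub[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.max()) if vals.size else None


def _nearest_congener(
    matrix: DistanceMatrix, dataset: Dataset, species: str
) -> tuple[str | None, float | None]:
    """Congener with minimum inter-specific distance; ties alphabetical."""
    members = dataset.species_members(species)
    best: tuple[float, str] | None = None
    for other in sorted(dataset.congeners(species)):
        vals = []
        for x in members:
            for y in dataset.species_members(other):
                d = matrix.get(x, y)
                if not math.isnan(d):
                    vals.append(d)
        if not vals:
            continue
        dmin = min(vals)
        if best is None or dmin < best[0]:
            best = (dmin, other)
    if best is None:
        return None, None
    return best[1], best[0]


def assess_species(
    species: str,
    tree: dendropy.Tree,
    matrix: DistanceMatrix,
    dataset: Dataset,
    q5: float | None,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    close_sister_cut: float = DEFAULT_CLOSE_SISTER_CUT,
    alpha: float = DEFAULT_ALPHA,
    rule_c_mode: str = "or",
    partition: ClusterPartition | None = None,
) -> SpeciesAssessment:
    """Apply the identifiability rules (a)-(c) and categories I-IV to one species.

    Singletons are trivially monophyletic and cannot fail rule (a); they can
    still fail (b) and (c). The sister for the reciprocal-monophyly test is
    the congener at minimum inter-specific distance; the test is computed
    only when both species are monophyletic (or trivial) on the tree.
    ``rule_c_mode`` combines the two rule-(c) triggers with "or" (default)
    or "and".
    """
    members = dataset.species_members(species)
    if not members:
        raise DatasetError(f"species {species!r} not in dataset")
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    on_tree = [x for x in members if x in tips]
    mono = is_monophyletic(tree, on_tree) if on_tree else None
    rule_a = bool(mono and mono.status == "non-monophyletic")

    shares_with: list[tuple[str, str]] = []
    for other in sorted(dataset.congeners(species)):
        verdict = barcode_sharing(matrix, dataset, species, other, tree=tree)
        if verdict.shared:
            shares_with.append((other, verdict.geography))
    rule_b = bool(shares_with)

    sister, sister_d = _nearest_congener(matrix, dataset, species)
    max_intra = _species_max_intra(matrix, members)
    overlap_trigger = bool(q5 is not None and max_intra is not None and max_intra >= q5)
    close_trigger = bool(sister_d is not None and sister_d < close_sister_cut)
    if rule_c_mode == "and":
        triggered = overlap_trigger and close_trigger
    else:
        triggered = overlap_trigger or close_trigger

    p_value: float | None = None
    rule_c = False
    if sister is not None and triggered:
        sister_members = [x for x in dataset.species_members(sister) if x in tips]
        sister_mono = is_monophyletic(tree, sister_members) if sister_members else None
        pair_reciprocal = (
            mono is not None and mono.is_monophyletic_or_trivial
            and sister_mono is not None and sister_mono.is_monophyletic_or_trivial
        )
        if pair_reciprocal:
            p_value = reciprocal_monophyly_p(len(members), len(sister_members)).p
            rule_c = p_value > alpha

    if partition is None:
        partition = detect_clusters(matrix, members, cluster_threshold,
                                    species=species, dataset=dataset)

    categories: set[str] = set()
    for _, geo in shares_with:
        if geo == "sympatric":
            categories.add("I")
        elif geo == "allopatric":
            categories.add("II")
    mono_ok = mono is not None and mono.is_monophyletic_or_trivial
    if mono_ok and rule_c:
        categories.add("III")
    if partition.n_clusters >= 2 and rule_a:
        categories.add("IV")

    identifiable = not (rule_a or rule_b or rule_c)
    return SpeciesAssessment(
        species=species,
        n_samples=len(members),
        monophyly_status=mono.status if mono else "absent",
        monophyly=mono,
        shares_with=shares_with,
        categories=categories,
        identifiable=identifiable,
        rule_a=rule_a,
        rule_b=rule_b,
        rule_c=rule_c,
        sister_species=sister,
        monophyly_test_p=p_value,
        max_intraspecific=max_intra,
        min_to_nearest_congener=sister_d,
        n_clusters=partition.n_clusters,
        rule_c_overlap_trigger=overlap_trigger,
        rule_c_close_sister_trigger=close_trigger,
    )


def deep_divergence_table(
    assessments: dict[str, SpeciesAssessment],
    partitions: dict[str, ClusterPartition],
    report_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> list[dict]:
    """Monophyletic species with deep intraspecific divergence.

    Rows are species that are monophyletic (or trivial) yet either split into
    two or more clusters above the cluster threshold, or whose maximum
    intraspecific distance is at or above the report threshold. Paraphyletic
    deep species are excluded here (they belong to the category-IV table).
    """
    rows: list[dict] = []
    for species in sorted(assessments):
        a = assessments[species]
        if a.monophyly_status == "non-monophyletic" or a.monophyly_status == "absent":
            continue
        part = partitions.get(species)
        deep_clusters = part is not None and part.n_clusters >= 2
        deep_distance = (a.max_intraspecific is not None
                         and a.max_intraspecific >= report_threshold)
        if not (deep_clusters or deep_distance):
            continue
        areas = ("; ".join(
            f"{c.label}. {'/'.join(sorted(c.areas)) or '-'} ({len(c.members)})"
            for c in part.clusters) if part else "")
        rows.append({
            "species": species,
            "n_clusters": part.n_clusters if part else 1,
            "cluster_areas": areas,
            "max_within": a.max_intraspecific,
        })
    return rows
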