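"""Kimura two-parameter (K2P) pairwise distances and survey summaries.

The K2P model corrects observed differences for multiple hits while
distinguishing transitions (A<->G, C<->T; proportion P of compared sites)
from transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence carries a gap, N or any IUPAC ambiguity are
excluded pair by pair (pairwise deletion). Distances are stored as
proportions; report columns multiply by 100 ("% K2P").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientOverlapError, MissingDistanceError, SaturationError
from .seqio import Dataset

logger = logging.getLogger(__name__)

#: minimum jointly unambiguous sites for a pair to yield a distance
DEFAULT_SITE_FLOOR = 100

# A=0 G=1 C=2 T=3: transition iff codes differ within the same code//2 class
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("AGCT"):
    _CODE[ord(_c)] = _i


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Encode aligned sequences as an (n, L) uint8 matrix; 255 = not A/C/G/T."""
    n, length = len(seqs), len(seqs[0])
    out = np.empty((n, length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        out[i] = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return out


@dataclass(frozen=True)
class SitePatternCount:
    """Per-pair compared-site, transition and transversion counts."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("more differences than compared sites")


def _counts_from_codes(a: np.ndarray, b: np.ndarray) -> SitePatternCount:
    ok = (a != 255) & (b != 255)
    av, bv = a[ok], b[ok]
    diff = av != bv
    ts = int(np.count_nonzero(diff & ((av >> 1) == (bv >> 1))))
    tv = int(np.count_nonzero(diff)) - ts
    return SitePatternCount(int(ok.sum()), ts, tv)


def count_site_patterns(seq_a: str, seq_b: str) -> SitePatternCount:
    """Count compared sites, transitions and transversions under pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    codes = encode_sequences([seq_a.upper(), seq_b.upper()])
    return _counts_from_codes(codes[0], codes[1])


def k2p(counts: SitePatternCount, site_floor: int = DEFAULT_SITE_FLOOR) -> float:
    """K2P distance (substitutions/site) from site-pattern counts.

    Raises InsufficientOverlapError below the compared-site floor and
    SaturationError when the log arguments are non-positive.
    """
    if counts.n_compared < site_floor:
        raise InsufficientOverlapError(
            f"{counts.n_compared} compared sites < floor {site_floor}"
        )
    p = counts.n_transitions / counts.n_compared
    q = counts.n_transversions / counts.n_compared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(p, q)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # avoid -0.0


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair compared-site counts.

    Missing entries (saturation or insufficient overlap) are NaN, never 0.
    """

    labels: list[str]
    d: np.ndarray
    sites: np.ndarray
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self._pos = {lab: i for i, lab in enumerate(self.labels)}

    def index(self, label: str) -> int:
        return self._pos[label]

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._pos[a], self._pos[b]])

    def submatrix(self, labels: list[str]) -> np.ndarray:
        idx = [self._pos[x] for x in labels]
        return self.d[np.ix_(idx, idx)]

    def require_complete(self, labels: list[str]) -> np.ndarray:
        sub = self.submatrix(labels)
        if np.isnan(sub).any():
            ii, jj = np.where(np.isnan(np.triu(sub, 1)))
            pairs = [(labels[i], labels[j]) for i, j in zip(ii, jj)
                     if np.isnan(sub[i, j])]
            raise MissingDistanceError(pairs)
        return sub

    def to_phylip(self) -> str:
        """PHYLIP square distance format (missing entries as -1)."""
        lines = [f"{len(self.labels)}"]
        filled = np.where(np.isnan(self.d), -1.0, self.d)
        for lab, row in zip(self.labels, filled):
            lines.append(
                f"{lab:<10}" + "  ".join(f"{x:.6f}" for x in row)
            )
        return "\n".join(lines) + "\n"


def pairwise_matrix(dataset: Dataset, site_floor: int = DEFAULT_SITE_FLOOR) -> DistanceMatrix:
    """All-pairs K2P distances; failed pairs stored as NaN with a logged list."""
    labels = dataset.specimen_ids
    if len(labels) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    codes = encode_sequences([r.sequence for r in dataset.records])
    n = len(labels)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    missing: list[tuple[str, str]] = []
    for i in range(n):
        sites[i, i] = int(np.count_nonzero(codes[i] != 255))
        for j in range(i + 1, n):
            c = _counts_from_codes(codes[i], codes[j])
            sites[i, j] = sites[j, i] = c.n_compared
            try:
                dij = k2p(c, site_floor=site_floor)
            except (SaturationError, InsufficientOverlapError):
                dij = math.nan
                missing.append((labels[i], labels[j]))
            d[i, j] = d[j, i] = dij
    if missing:
        logger.warning("%d pairwise distances missing (saturation/overlap)", len(missing))
    return DistanceMatrix(labels, d, sites, missing)


@dataclass(frozen=True)
class DistanceSummary:
    """Mean/variance/min/max of K2P distances for one species or genus."""

    scope: str  # "within-species" | "among-congener"
    group: str
    mean: float
    variance: float
    min: float
    max: float
    n_pairs: int


@dataclass
class DistanceSummaryResult:
    within: list[DistanceSummary]
    among: list[DistanceSummary]
    within_values: np.ndarray
    among_values: np.ndarray
    within_hist: tuple[np.ndarray, np.ndarray]
    among_hist: tuple[np.ndarray, np.ndarray]
    n_dropped: int = 0


def _summaries(values_by_group: dict[str, list[float]], scope: str) -> list[DistanceSummary]:
    out = []
    for group in sorted(values_by_group):
        v = np.asarray(values_by_group[group])
        if v.size == 0:
            continue
        out.append(DistanceSummary(
            scope, group, float(v.mean()),
            float(v.var(ddof=1)) if v.size > 1 else 0.0,
            float(v.min()), float(v.max()), int(v.size),
        ))
    return out


def _hist(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    top = max(bin_width, float(values.max()) if values.size else bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def summarize_distances(
    matrix: DistanceMatrix, dataset: Dataset, bin_width: float = 0.01
) -> DistanceSummaryResult:
    """Within-species and among-congener distance sets, summaries and histograms.

    Within-species pairs share a species label; among-congener pairs share a
    genus but not a species. Cross-genus pairs are not summarized. Missing
    distances are excluded with a logged count.
    """
    recs = dataset.records
    within: dict[str, list[float]] = {}
    among: dict[str, list[float]] = {}
    w_all: list[float] = []
    a_all: list[float] = []
    dropped = 0
    n = len(recs)
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = recs[i], recs[j]
            same_sp = ri.species == rj.species
            same_gen = ri.genus == rj.genus
            if not same_gen:
                continue
            dij = matrix.d[matrix.index(ri.specimen_id), matrix.index(rj.specimen_id)]
            if math.isnan(dij):
                dropped += 1
                continue
            if same_sp:
                within.setdefault(ri.species, []).append(dij)
                w_all.append(dij)
            else:
                among.setdefault(ri.genus, []).append(dij)
                a_all.append(dij)
    if dropped:
        logger.info("%d within-genus pairs dropped (missing distances)", dropped)
    wv = np.asarray(w_all)
    av = np.asarray(a_all)
    return DistanceSummaryResult(
        within=_summaries(within, "within-species"),
        among=_summaries(among, "among-congener"),
        within_values=wv,
        among_values=av,
        within_hist=_hist(wv, bin_width),
        among_hist=_hist(av, bin_width),
        n_dropped=dropped,
    )


def among_species_lower_quantile(among_values, q: float = 0.05) -> float:
    """q-quantile (linear interpolation, type 7) of among-congener distances."""
    v = np.asarray(list(among_values), dtype=float)
    if v.size == 0:
        raise ValueError("empty among-species distance collection")
    return float(np.quantile(v, q))
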