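"""Trees and monophyly: neighbor-joining, bootstrap support, and the exact
test of chance reciprocal monophyly.

The reciprocal-monophyly test asks: given two sister groups sampled with
n_a and n_b individuals, what is the probability that a neutral coalescent
genealogy ("random branching") makes both groups monophyletic purely by
chance? The null is the uniform distribution over labeled coalescent
histories (sequences of pairwise merges). A small p rejects chance as the
explanation of observed reciprocal monophyly; with few samples the test has
little power and p stays above 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import dendropy
import numpy as np

from . import distance as _dist
from .errors import MissingDistanceError, TreeError
from .seqio import Dataset

logger = logging.getLogger(__name__)

#: switch from exact rational to floating-point DP above this total sample size
EXACT_LIMIT = 40
#: brute-force enumeration cap (number of histories is prod_{k<=n} C(k,2))
ENUMERATION_CAP = 10


# ---------------------------------------------------------------------------
# neighbor-joining


def nj_tree(matrix: _dist.DistanceMatrix, labels: list[str] | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining on a complete distance (sub)matrix.

    Deterministic: ties in the Q-criterion are broken by the lowest
    (row, column) index pair in the current working matrix. Negative branch
    lengths are clamped to 0; the clamp count is stored on the returned tree
    as ``n_clamped``. The result is unrooted with a trifurcating seed node.
    """
    labels = list(matrix.labels if labels is None else labels)
    n = len(labels)
    if n < 3:
        raise TreeError(f"neighbor-joining needs >= 3 taxa, got {n}")
    D = matrix.require_complete(labels).astype(float).copy()

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    n_clamped = 0

    def _clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0.0:
            n_clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        qvals = Q[iu]
        # np.argmin returns the first minimum in row-major order, which is
        # exactly the lowest (row, column) tie-break
        k = int(np.argmin(qvals))
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = D[i, j]
        vi = _clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        vj = _clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        last = np.append(dnew[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    # final three-point join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    for nd, ln in zip(nodes, (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )):
        nd.edge.length = _clamp(ln)
        center.add_child(nd)
    tree.seed_node = center
    tree.is_rooted = False
    tree.n_clamped = n_clamped
    return tree


def tip_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets of tip labels.

    Each internal edge splits the tips in two; the side not containing the
    alphabetically first tip is the canonical representative. Suitable for
    unrooted topology comparison and bootstrap counting.
    """
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_tips)
    out: set[frozenset[str]] = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(all_tips) - len(side) < 2:
            continue
        if ref in side:
            side = all_tips - side
        out.add(side)
    return out


def bootstrap_support(
    dataset: Dataset,
    n_reps: int = 100,
    seed: int = 0,
    site_floor: int = _dist.DEFAULT_SITE_FLOOR,
) -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap support on internal edges.

    Alignment columns are resampled with replacement (seeded); each replicate
    rebuilds the NJ tree and the point-estimate tree's internal bipartitions
    are annotated with their replicate frequency x 100 (node ``support``
    attribute and label). Replicates in which some pair saturates are
    skipped; if any pair fails in more than half the replicates an error
    recommends subsetting.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point_matrix = _dist.pairwise_matrix(dataset, site_floor=site_floor)
    point = nj_tree(point_matrix)
    labels = dataset.specimen_ids
    codes = _dist.encode_sequences([r.sequence for r in dataset.records])
    n, L = codes.shape
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tip_bipartitions(point)}
    pair_failures: dict[tuple[str, str], int] = {}
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rcodes = codes[:, cols]
        d = np.zeros((n, n))
        failed: list[tuple[str, str]] = []
        for i in range(n):
            for j in range(i + 1, n):
                c = _dist._counts_from_codes(rcodes[i], rcodes[j])
                try:
                    d[i, j] = d[j, i] = _dist.k2p(c, site_floor=site_floor)
                except Exception:
                    d[i, j] = d[j, i] = math.nan
                    failed.append((labels[i], labels[j]))
        if failed:
            for pr in failed:
                pair_failures[pr] = pair_failures.get(pr, 0) + 1
            continue
        n_ok += 1
        rep_tree = nj_tree(_dist.DistanceMatrix(labels, d, np.zeros((n, n), dtype=int)))
        for bp in tip_bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    bad = [pr for pr, k in pair_failures.items() if k > n_reps / 2]
    if bad:
        raise MissingDistanceError(bad)
    if n_ok == 0:
        raise TreeError("all bootstrap replicates failed")
    all_tips = frozenset(labels)
    ref = min(all_tips)
    for nd in point.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(all_tips) - len(side) < 2:
            continue
        key = all_tips - side if ref in side else side
        support = 100.0 * counts[key] / n_ok
        nd.support = support
        nd.label = str(int(round(support)))
    point.bootstrap_replicates = n_ok
    return point


# ---------------------------------------------------------------------------
# monophyly


@dataclass(frozen=True)
class MonophylyResult:
    target: frozenset[str]
    status: str  # "monophyletic" | "non-monophyletic" | "trivial"
    intruders: frozenset[str]

    @property
    def is_monophyletic_or_trivial(self) -> bool:
        return self.status in ("monophyletic", "trivial")


def is_monophyletic(
    tree: dendropy.Tree, target, rooted: bool | None = None
) -> MonophylyResult:
    """Monophyly of a tip-label set on a rooted or unrooted tree.

    Unrooted trees: monophyletic iff some edge bipartition separates the
    target exactly from its complement. Rooted trees: iff some node's tip set
    equals the target. Intruders come from the smallest clade (rooted) or
    smallest edge side (unrooted) containing the target. Singleton and
    whole-tree targets are trivial.
    """
    target = frozenset(target)
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    unknown = target - all_tips
    if unknown:
        raise TreeError(f"unknown tips: {sorted(unknown)}")
    if len(target) <= 1 or target == all_tips:
        return MonophylyResult(target, "trivial", frozenset())
    rooted = tree.is_rooted if rooted is None else rooted

    best_side: frozenset[str] | None = None
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() and rooted:
            continue
        if nd.parent_node is None and not rooted:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        candidates = [side] if rooted else [side, all_tips - side]
        for cand in candidates:
            if cand == target:
                return MonophylyResult(target, "monophyletic", frozenset())
            if target <= cand and (best_side is None or len(cand) < len(best_side)):
                best_side = cand
    intruders = (best_side - target) if best_side is not None else (all_tips - target)
    return MonophylyResult(target, "non-monophyletic", frozenset(intruders))


# ---------------------------------------------------------------------------
# exact test of chance reciprocal monophyly


@dataclass(frozen=True)
class MonophylyTestResult:
    n_a: int
    n_b: int
    p: float
    method: str  # "recursion" | "enumeration"
    p_exact: Fraction | None = None
    n_histories: int | None = None

    @property
    def p_published(self) -> float:
        """p rounded to 2 decimals, the precision used in published tables."""
        return round(self.p, 2)


def reciprocal_monophyly_p(n_a: int, n_b: int) -> MonophylyTestResult:
    """P(both groups monophyletic) under uniform labeled coalescent histories.

    Recursion over within-group coalescences:

        P(i, j) = [C(i,2) P(i-1, j) + C(j,2) P(i, j-1)] / C(i+j, 2),  P(1,1) = 1

    Exact rational arithmetic up to n_a + n_b <= 40, floating point above.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    total = n_a + n_b
    if total > 500:
        raise ValueError("n_a + n_b must be <= 500")
    if total < 2:
        raise ValueError("n_a + n_b must be >= 2")
    exact = total <= EXACT_LIMIT
    zero = Fraction(0) if exact else 0.0
    one = Fraction(1) if exact else 1.0
    # table[i][j] for 1 <= i <= n_a, 1 <= j <= n_b
    table = [[zero] * (n_b + 1) for _ in range(n_a + 1)]
    table[1][1] = one
    for i in range(1, n_a + 1):
        for j in range(1, n_b + 1):
            if i == j == 1:
                continue
            num = zero
            if i > 1:
                c = i * (i - 1) // 2
                num += (Fraction(c) if exact else c) * table[i - 1][j]
            if j > 1:
                c = j * (j - 1) // 2
                num += (Fraction(c) if exact else c) * table[i][j - 1]
            tot = (i + j) * (i + j - 1) // 2
            table[i][j] = num / (Fraction(tot) if exact else tot)
    p = table[n_a][n_b]
    if exact:
        return MonophylyTestResult(n_a, n_b, float(p), "recursion", p_exact=p)
    return MonophylyTestResult(n_a, n_b, float(p), "recursion")


def enumerate_histories_p(n_a: int, n_b: int) -> MonophylyTestResult:
    """Brute-force oracle: enumerate every labeled coalescent history.

    A history is a sequence of pairwise lineage merges from n_a + n_b
    lineages down to one; there are prod_{k=2..n} C(k,2) of them. Both
    groups end up monophyletic iff every merge is within-group until each
    group is a single lineage (the final cross merge then joins the two
    group clades). Returns the exact counted fraction.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    n = n_a + n_b
    if n > ENUMERATION_CAP:
        raise ValueError(f"n_a + n_b must be <= {ENUMERATION_CAP} for enumeration")
    # lineage state: ('A'|'B'|'M', size); identity of lineages distinguishes
    # merge choices, so iterating over index pairs enumerates labeled histories
    total = 0
    good = 0

    def _merge_ok(x, y) -> bool:
        # a merge keeps monophyly achievable iff within-group, or it is the
        # final cross merge of the two complete group clades
        if x[0] == y[0] and x[0] != "M":
            return True
        return {x, y} == {("A", n_a), ("B", n_b)}

    def rec(lins: tuple, ok: bool):
        nonlocal total, good
        k = len(lins)
        if k == 2:
            total += 1
            if ok and _merge_ok(lins[0], lins[1]):
                good += 1
            return
        for i, j in itertools.combinations(range(k), 2):
            x, y = lins[i], lins[j]
            merged = (x[0] if x[0] == y[0] else "M", x[1] + y[1])
            rest = tuple(lins[m] for m in range(k) if m != i and m != j)
            rec(rest + (merged,), ok and _merge_ok(x, y))

    start = tuple(("A", 1) for _ in range(n_a)) + tuple(("B", 1) for _ in range(n_b))
    if n == 2:
        total, good = 1, 1 if _merge_ok(start[0], start[1]) else 0
    else:
        rec(start, True)
    expected_total = math.prod(k * (k - 1) // 2 for k in range(2, n + 1))
    assert total == expected_total, "enumeration incomplete"
    frac = Fraction(good, total)
    return MonophylyTestResult(
        n_a, n_b, float(frac), "enumeration", p_exact=frac, n_histories=total
    )
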