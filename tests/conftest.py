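"""Shared fixtures: hand-built datasets, distance matrices and trees."""

import dendropy
import numpy as np
import pytest

from barcodesurvey.distance import DistanceMatrix
from barcodesurvey.seqio import BarcodeRecord, Dataset

BASE_SEQ = ("ACGT" * 50)  # 200 bp, enough for the default 100-site floor


def mutate(seq: str, positions, base_cycle="GTAC") -> str:
    """Deterministically substitute the given positions of a sequence."""
    s = list(seq)
    for k, pos in enumerate(positions):
        cur = s[pos]
        repl = next(b for b in base_cycle if b != cur)
        s[pos] = repl
    return "".join(s)


def make_dataset(specs) -> Dataset:
    """Build a Dataset from (specimen_id, species, sequence[, area]) tuples."""
    records = []
    for spec in specs:
        sid, species, seq = spec[:3]
        area = spec[3] if len(spec) > 3 else None
        records.append(BarcodeRecord(specimen_id=sid, species=species,
                                     sequence=seq, area=area))
    return Dataset(records)


def make_matrix(labels, pairs, default=np.nan) -> DistanceMatrix:
    """Build a DistanceMatrix from a {(a, b): d} dict of unordered pairs."""
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    d = np.full((n, n), default, dtype=float)
    np.fill_diagonal(d, 0.0)
    for (a, b), val in pairs.items():
        d[pos[a], pos[b]] = d[pos[b], pos[a]] = val
    sites = np.full((n, n), 500, dtype=int)
    return DistanceMatrix(list(labels), d, sites)


def tree_from_newick(newick: str, rooted: bool = False) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = rooted
    return tree


@pytest.fixture
def four_tip_dataset() -> Dataset:
    """Two species x two specimens; conspecifics near, heterospecifics far."""
    a1 = BASE_SEQ
    a2 = mutate(BASE_SEQ, [0])
    b1 = mutate(BASE_SEQ, range(20, 40))
    b2 = mutate(BASE_SEQ, list(range(20, 40)) + [1])
    return make_dataset([
        ("A1", "Genus alpha", a1, "N"),
        ("A2", "Genus alpha", a2, "N"),
        ("B1", "Genus beta", b1, "Ron"),
        ("B2", "Genus beta", b2, "Ron"),
    ])
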