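"""Dataset IO: aligned FASTA + specimen metadata TSV, newick trees, report tables.

A survey dataset couples one aligned COI sequence per specimen with the
taxonomy (species, genus) and geography (locality, area-of-endemism code)
needed downstream. Metadata is a tab-delimited table with a header row,
BOLD-flat-export style; extra columns are preserved on read but ignored by
the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO as _BioSeqIO

from .errors import AlignmentError, DatasetError, TreeError

logger = logging.getLogger(__name__)

#: characters accepted in aligned sequences (IUPAC nucleotides + gap)
_VALID_CHARS = frozenset("ACGTRYSWKMBDHVN-")


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen: aligned sequence plus taxonomy and geography labels."""

    specimen_id: str
    species: str
    sequence: str
    genus: str = ""
    locality: str = ""
    area: str | None = None

    def __post_init__(self):
        if not self.specimen_id:
            raise DatasetError("specimen_id must be nonempty")
        if not self.species:
            raise DatasetError(f"record {self.specimen_id!r}: species must be nonempty")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise DatasetError(
                f"record {self.specimen_id!r}: invalid sequence characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if not self.genus:
            object.__setattr__(self, "genus", self.species.split()[0])


@dataclass
class Dataset:
    """Ordered collection of BarcodeRecords over one alignment."""

    records: list[BarcodeRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise DatasetError("empty dataset")
        seen: set[str] = set()
        for r in self.records:
            if r.specimen_id in seen:
                raise DatasetError(f"duplicate specimen_id {r.specimen_id!r}")
            seen.add(r.specimen_id)
        length = len(self.records[0].sequence)
        offenders = [r.specimen_id for r in self.records if len(r.sequence) != length]
        if offenders:
            raise AlignmentError(
                f"unequal aligned lengths (expected {length}): {offenders}"
            )
        genus_of: dict[str, str] = {}
        for r in self.records:
            prev = genus_of.setdefault(r.species, r.genus)
            if prev != r.genus:
                raise DatasetError(
                    f"species {r.species!r} mapped to two genera: {prev!r}, {r.genus!r}"
                )
        self._index = {r.specimen_id: r for r in self.records}

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, specimen_id: str) -> BarcodeRecord:
        return self._index[specimen_id]

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self._index

    def species_members(self, species: str) -> list[str]:
        return [r.specimen_id for r in self.records if r.species == species]

    @property
    def species_list(self) -> list[str]:
        """Distinct species in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.species not in seen:
                seen.add(r.species)
                out.append(r.species)
        return out

    def genus_of(self, species: str) -> str:
        for r in self.records:
            if r.species == species:
                return r.genus
        raise DatasetError(f"species {species!r} not in dataset")

    def congeners(self, species: str) -> list[str]:
        """Other species of the same genus, in first-appearance order."""
        g = self.genus_of(species)
        return [s for s in self.species_list if s != species and self.genus_of(s) == g]

    def with_areas(self, areas: dict[str, str | None]) -> "Dataset":
        """Return a copy with per-specimen area codes replaced where given."""
        new = [
            replace(r, area=areas.get(r.specimen_id, r.area)) for r in self.records
        ]
        return Dataset(new)


def read_dataset(fasta_path: str | Path, metadata_path: str | Path) -> Dataset:
    """Build a Dataset from an aligned FASTA and a metadata TSV.

    Metadata must carry ``specimen_id`` and ``species`` columns; ``genus``,
    ``locality`` and ``area`` are optional. Every metadata row must have a
    FASTA sequence; FASTA entries absent from the metadata are ignored with
    a logged count. Record order follows metadata row order.
    """
    seqs: dict[str, str] = {}
    for rec in _BioSeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise DatasetError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, na_filter=False)
    required = {"specimen_id", "species"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise DatasetError(f"metadata missing required columns: {sorted(missing_cols)}")

    records: list[BarcodeRecord] = []
    for _, row in meta.iterrows():
        sid = row["specimen_id"]
        if sid not in seqs:
            raise DatasetError(f"no FASTA sequence for specimen {sid!r}")
        records.append(
            BarcodeRecord(
                specimen_id=sid,
                species=row["species"],
                sequence=seqs[sid],
                genus=row.get("genus", ""),
                locality=row.get("locality", ""),
                area=(row.get("area") or None) if "area" in meta.columns else None,
            )
        )
    unmatched = set(seqs) - {r.specimen_id for r in records}
    if unmatched:
        logger.warning("%d FASTA entries not in metadata; ignored", len(unmatched))
    dataset = Dataset(records)
    n_no_area = sum(1 for r in dataset.records if r.area is None)
    if n_no_area:
        logger.info("%d records lack an area code", n_no_area)
    return dataset


def write_dataset(dataset: Dataset, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write a Dataset back to FASTA + metadata TSV (round-trip inverse of read)."""
    with open(fasta_path, "w") as fh:
        for r in dataset.records:
            fh.write(f">{r.specimen_id}\n{r.sequence}\n")
    rows = [
        {
            "specimen_id": r.specimen_id,
            "species": r.species,
            "genus": r.genus,
            "locality": r.locality,
            "area": r.area or "",
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def read_newick(path: str | Path, dataset: Dataset) -> dendropy.Tree:
    """Load an externally built newick tree and bind its tips to the dataset.

    Tip labels must be a subset of the dataset's specimen ids. Polytomies
    are permitted but flagged via the ``has_polytomies`` annotation.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick in {path}: {exc}") from exc
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unknown = [t for t in tips if t not in dataset]
    if unknown:
        raise TreeError(f"unknown tip {unknown[0]!r} (and {len(unknown) - 1} more)"
                        if len(unknown) > 1 else f"unknown tip {unknown[0]!r}")
    if len(set(tips)) != len(tips):
        raise TreeError("duplicate tip labels in newick")
    poly = any(
        len(nd.child_nodes()) > 2
        for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None
    )
    tree.has_polytomies = poly
    if poly:
        logger.warning("tree in %s contains polytomies", path)
    return tree


# ---------------------------------------------------------------------------
# report tables


def _fmt(x, nd: int) -> str:
    if x is None or (isinstance(x, float) and x != x):  # NaN
        return ""
    return f"{x:.{nd}f}"


def write_report_tables(results, out_dir: str | Path) -> dict[str, Path]:
    """Write the survey report TSVs with deterministic ordering and formatting.

    Emits species_summary, nonidentifiable (Table 1 analog), clusters
    (Table 2 analog), deep_divergence (Table 3 analog) and area_pairs
    (Table 4 analog). Proportions are printed with 4 decimals; the
    "as-published" percent columns with 2 decimals.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, header: list[str], rows: list[list[str]]) -> None:
        p = out / f"{name}.tsv"
        with open(p, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths[name] = p

    # species_summary: per-species distance + assessment overview
    header = [
        "species", "n_samples", "monophyly", "identifiable", "categories",
        "sister_species", "monophyly_test_p", "within_mean", "within_var",
        "within_min", "within_max", "min_to_nearest_congener_pct",
        "max_intraspecific_pct",
    ]
    within_by_species = {s.group: s for s in results.summaries.within}
    rows = []
    for a in sorted(results.assessments.values(), key=lambda a: a.species):
        w = within_by_species.get(a.species)
        rows.append([
            a.species, str(a.n_samples), a.monophyly_status,
            str(a.identifiable).lower(), "+".join(sorted(a.categories)) or "-",
            a.sister_species or "-",
            _fmt(a.monophyly_test_p, 2) if a.monophyly_test_p is not None else "-",
            _fmt(w.mean, 4) if w else "", _fmt(w.variance, 6) if w else "",
            _fmt(w.min, 4) if w else "", _fmt(w.max, 4) if w else "",
            _fmt(100 * a.min_to_nearest_congener, 2)
            if a.min_to_nearest_congener is not None else "",
            _fmt(100 * a.max_intraspecific, 2)
            if a.max_intraspecific is not None else "",
        ])
    _write("species_summary", header, rows)

    # nonidentifiable: Table 1 analog
    header = ["species", "sampling", "categories", "partner_species",
              "geography", "monophyly_test_p"]
    rows = []
    for a in sorted(results.assessments.values(), key=lambda a: a.species):
        if a.identifiable:
            continue
        partners = "; ".join(s for s, _ in a.shares_with) or (a.sister_species or "-")
        geo = "; ".join(g for _, g in a.shares_with) or "-"
        rows.append([
            a.species, str(a.n_samples), "+".join(sorted(a.categories)) or "-",
            partners, geo,
            _fmt(a.monophyly_test_p, 2) if a.monophyly_test_p is not None else "-",
        ])
    _write("nonidentifiable", header, rows)

    # clusters: Table 2 analog, one row per cluster
    header = ["species", "cluster", "n_samples", "areas",
              "within_range_pct", "between_min_pct", "between_max_pct"]
    rows = []
    for part in sorted(results.partitions.values(), key=lambda p: p.species):
        if len(part.clusters) < 2:
            continue
        for cl in part.clusters:
            within = ("-" if cl.within_min is None
                      else f"{100 * cl.within_min:.2f}-{100 * cl.within_max:.2f}")
            others = [p for p in part.between
                      if cl.label in p]
            bmin = min(part.between[p][0] for p in others) if others else None
            bmax = max(part.between[p][1] for p in others) if others else None
            rows.append([
                part.species, cl.label, str(len(cl.members)),
                "/".join(sorted(cl.areas)) or "-", within,
                _fmt(100 * bmin, 2) if bmin is not None else "",
                _fmt(100 * bmax, 2) if bmax is not None else "",
            ])
    _write("clusters", header, rows)

    # deep_divergence: Table 3 analog
    header = ["species", "n_clusters", "cluster_areas", "max_within_species_pct"]
    rows = [
        [r["species"], str(r["n_clusters"]), r["cluster_areas"],
         _fmt(100 * r["max_within"], 2)]
        for r in results.deep_divergence
    ]
    _write("deep_divergence", header, rows)

    # area_pairs: Table 4 analog
    header = ["area_pair", "n_species", "species_ranges"]
    rows = []
    for pat in results.area_patterns:
        entries = "; ".join(
            f"{sp} ({100 * lo:.2f}-{100 * hi:.2f})" if lo != hi
            else f"{sp} ({100 * lo:.2f})"
            for sp, (lo, hi) in sorted(pat.species_ranges.items())
        )
        rows.append([f"{pat.area_a}-{pat.area_b}", str(pat.n_species), entries])
    _write("area_pairs", header, rows)

    return paths
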