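"""The survey model: one object that runs the whole barcode analysis.

``BarcodeSurvey`` is built from a dataset (plus optional external tree and
area table); ``fit()`` executes the pipeline — pairwise K2P distances,
within/among summaries and the among-species 5% quantile, tree construction
(internal NJ or the supplied newick), per-species identifiability
assessment, divergent-cluster partitions, deep-divergence and
non-identifiable tables, and area-pair patterns — and returns a
``SurveyResults`` carrying every intermediate, a text ``summary()`` and
table writers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy

from . import __version__
from . import delimit as _delimit
from . import distance as _distance
from . import geopattern as _geo
from . import phylo as _phylo
from . import seqio as _seqio
from .errors import ConfigError
from .seqio import Dataset

logger = logging.getLogger(__name__)


@dataclass
class SurveyConfig:
    """Thresholds and run controls, with survey-standard defaults."""

    cluster_threshold: float = _delimit.DEFAULT_CLUSTER_THRESHOLD  # 1.5% K2P
    close_sister_cut: float = _delimit.DEFAULT_CLOSE_SISTER_CUT    # 1% K2P
    quantile: float = 0.05
    alpha: float = 0.05
    site_floor: int = _distance.DEFAULT_SITE_FLOOR
    area_report_threshold: float = 0.01  # clusters for the area-pair table
    deep_report_threshold: float = 0.015
    rule_c_mode: str = "or"
    bootstrap_reps: int = 0
    seed: int = 0
    report_precision: int = 2

    def validate(self) -> None:
        for name in ("cluster_threshold", "close_sister_cut",
                     "area_report_threshold", "deep_report_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        for name in ("quantile", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.rule_c_mode not in ("or", "and"):
            raise ConfigError("rule_c_mode must be 'or' or 'and'")
        if self.bootstrap_reps < 0:
            raise ConfigError("bootstrap_reps must be >= 0")


class BarcodeSurvey:
    """Barcode survey model over an aligned dataset.

    Parameters
    ----------
    dataset : Dataset
        Aligned sequences plus specimen metadata.
    tree : dendropy.Tree, optional
        Externally built tree; when absent, fit() builds a NJ tree from the
        K2P matrix (with bootstrap support if configured).
    area_table : geopattern.AreaTable, optional
        Locality -> area mapping applied before geographic analyses.
    config : SurveyConfig, optional
    """

    def __init__(self, dataset: Dataset, tree: dendropy.Tree | None = None,
                 area_table: _geo.AreaTable | None = None,
                 config: SurveyConfig | None = None):
        self.config = config or SurveyConfig()
        self.config.validate()
        if area_table is not None:
            dataset = _geo.assign_areas(dataset, area_table)
        self.dataset = dataset
        self.tree = tree

    @classmethod
    def from_files(cls, fasta: str | Path, metadata: str | Path,
                   tree: str | Path | None = None,
                   area_table: str | Path | None = None,
                   config: SurveyConfig | None = None) -> "BarcodeSurvey":
        dataset = _seqio.read_dataset(fasta, metadata)
        tr = _seqio.read_newick(tree, dataset) if tree else None
        at = _geo.AreaTable.from_tsv(area_table) if area_table else None
        model = cls(dataset, tree=tr, area_table=at, config=config)
        model._input_paths = {"fasta": str(fasta), "metadata": str(metadata),
                              "tree": str(tree) if tree else None}
        return model

    def fit(self) -> "SurveyResults":
        cfg = self.config
        dataset = self.dataset
        logger.info("survey: %d specimens, %d species", len(dataset),
                    len(dataset.species_list))
        matrix = _distance.pairwise_matrix(dataset, site_floor=cfg.site_floor)
        summaries = _distance.summarize_distances(matrix, dataset)
        q5 = (_distance.among_species_lower_quantile(
            summaries.among_values, cfg.quantile)
            if summaries.among_values.size else None)

        if self.tree is not None:
            tree = self.tree
            tree_source = "external"
        elif cfg.bootstrap_reps > 0:
            tree = _phylo.bootstrap_support(
                dataset, n_reps=cfg.bootstrap_reps, seed=cfg.seed,
                site_floor=cfg.site_floor)
            tree_source = f"nj+bootstrap({cfg.bootstrap_reps})"
        else:
            tree = _phylo.nj_tree(matrix)
            tree_source = "nj"

        partitions: dict[str, _delimit.ClusterPartition] = {}
        area_partitions: list[_delimit.ClusterPartition] = []
        assessments: dict[str, _delimit.SpeciesAssessment] = {}
        for species in dataset.species_list:
            members = dataset.species_members(species)
            part = _delimit.detect_clusters(
                matrix, members, cfg.cluster_threshold, species=species,
                dataset=dataset)
            partitions[species] = part
            area_partitions.append(_delimit.detect_clusters(
                matrix, members, cfg.area_report_threshold, species=species,
                dataset=dataset))
            assessments[species] = _delimit.assess_species(
                species, tree, matrix, dataset, q5,
                cluster_threshold=cfg.cluster_threshold,
                close_sister_cut=cfg.close_sister_cut,
                alpha=cfg.alpha, rule_c_mode=cfg.rule_c_mode,
                partition=part)

        deep = _delimit.deep_divergence_table(
            assessments, partitions, report_threshold=cfg.deep_report_threshold)
        patterns = _geo.area_pair_patterns(area_partitions, matrix, dataset)
        return SurveyResults(
            model=self, dataset=dataset, distance_matrix=matrix,
            summaries=summaries, q5=q5, tree=tree, tree_source=tree_source,
            partitions=partitions, area_partitions=area_partitions,
            assessments=assessments, deep_divergence=deep,
            area_patterns=patterns, config=cfg,
        )


@dataclass
class SurveyResults:
    """Everything the fitted survey produced."""

    model: BarcodeSurvey
    dataset: Dataset
    distance_matrix: _distance.DistanceMatrix
    summaries: _distance.DistanceSummaryResult
    q5: float | None
    tree: dendropy.Tree
    tree_source: str
    partitions: dict[str, _delimit.ClusterPartition]
    area_partitions: list[_delimit.ClusterPartition]
    assessments: dict[str, _delimit.SpeciesAssessment]
    deep_divergence: list[dict]
    area_patterns: list[_geo.AreaPairPattern]
    config: SurveyConfig
    _written: dict = field(default_factory=dict)

    @property
    def n_identifiable(self) -> int:
        return sum(a.identifiable for a in self.assessments.values())

    @property
    def nonidentifiable_species(self) -> list[str]:
        return sorted(s for s, a in self.assessments.items() if not a.identifiable)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in "I II III IV".split()}
        for a in self.assessments.values():
            for c in a.categories:
                counts[c] += 1
        return counts

    def summary(self) -> str:
        n_species = len(self.assessments)
        lines = [
            "Barcode survey summary",
            "======================",
            f"specimens: {len(self.dataset)}   species: {n_species}   "
            f"alignment: {self.dataset.alignment_length} bp",
            f"tree: {self.tree_source}",
        ]
        wv, av = self.summaries.within_values, self.summaries.among_values
        if wv.size:
            lines.append(
                f"within-species K2P: n={wv.size} pairs, "
                f"range {100 * wv.min():.2f}-{100 * wv.max():.2f}%")
        if av.size:
            lines.append(
                f"among-congener K2P: n={av.size} pairs, "
                f"range {100 * av.min():.2f}-{100 * av.max():.2f}%")
        if self.q5 is not None:
            lines.append(
                f"lowest {100 * self.config.quantile:.0f}% of among-species "
                f"variation: {100 * self.q5:.2f}% K2P")
        pct = 100.0 * self.n_identifiable / n_species if n_species else 0.0
        lines.append(
            f"identifiable species: {self.n_identifiable}/{n_species} ({pct:.0f}%)")
        cats = self.category_counts()
        lines.append("categories: " + "  ".join(
            f"{k}={v}" for k, v in cats.items()))
        lines.append(f"deep-divergence species: {len(self.deep_divergence)}")
        lines.append(f"area-pair patterns: {len(self.area_patterns)}")
        return "\n".join(lines)

    def write_tables(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the report TSVs plus the run manifest; deterministic bytes."""
        paths = _seqio.write_report_tables(self, out_dir)
        manifest = self._manifest()
        mpath = Path(out_dir) / "MANIFEST.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = mpath
        self._written = paths
        return paths

    def _manifest(self) -> dict:
        cfg = asdict(self.config)
        checksums = {}
        input_paths = getattr(self.model, "_input_paths", None)
        if input_paths:
            for key, p in input_paths.items():
                if p and Path(p).exists():
                    checksums[key] = hashlib.sha256(
                        Path(p).read_bytes()).hexdigest()
        return {
            "package": "barcodesurvey",
            "version": __version__,
            "config": cfg,
            "tree_source": self.tree_source,
            "n_specimens": len(self.dataset),
            "n_species": len(self.assessments),
            "n_identifiable": self.n_identifiable,
            "n_missing_distance_pairs": len(self.distance_matrix.missing_pairs),
            "n_dropped_summary_pairs": self.summaries.n_dropped,
            "input_checksums": checksums,
        }
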