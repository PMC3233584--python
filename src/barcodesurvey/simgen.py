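"""Coalescent barcode-survey simulator with known truth.

Generates a genus of species under an isolation model (no migration):
standard coalescent genealogies within populations, optional two-population
splits within species, species joins at configurable times, and sequence
evolution under the continuous-time Kimura two-parameter substitution
process with transition/transversion rate ratio kappa. The generator's
mutation model deliberately matches the K2P distance estimator so that
estimator-consistency tests have an exact closed-form expectation:

    E[divergence between two populations split t generations ago]
        = 2 mu t + 2 * (2 N_e mu)

Times are in generations, rates per site per generation; a seed fixes the
full output byte for byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .seqio import BarcodeRecord, Dataset, write_dataset

logger = logging.getLogger(__name__)

_ALPHABET = "AGCT"  # code order matches the distance module (A=0,G=1,C=2,T=3)

DEFAULT_AREA_CODES = ["N", "Ron", "Be", "Gu", "Im", "In", "Pa1", "Pa2", "SEAF", "Caa"]


@dataclass
class SimConfig:
    """Stated world of a synthetic survey.

    Defaults emulate a congeneric barcode panel: species radiating at an
    expected 2*mu*t = 10% K2P (among-congener distances concentrate between
    5 and 15%), within-species diversity theta = 4*N_e*mu = 0.5%, ~700 bp
    gap-free COI-length alignment, transition bias kappa = 5.
    """

    seed: int = 0
    n_species: int = 5
    samples_per_population: int = 4
    populations_per_species: int | list[int] = 1
    species_split_times: float | list[float] = 1_000_000.0
    within_split_time: float = 200_000.0
    effective_size: float = 25_000.0
    mutation_rate: float = 5e-8
    kappa: float = 5.0
    seq_length: int = 700
    genus: str = "Simulornis"
    area_codes: list[str] = field(default_factory=lambda: list(DEFAULT_AREA_CODES))

    def pops_of(self, s: int) -> int:
        if isinstance(self.populations_per_species, int):
            return self.populations_per_species
        return self.populations_per_species[s]

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.samples_per_population < 1:
            raise ConfigError("samples_per_population must be >= 1")
        pops = ([self.populations_per_species] * self.n_species
                if isinstance(self.populations_per_species, int)
                else list(self.populations_per_species))
        if isinstance(self.populations_per_species, list) and \
                len(pops) != self.n_species:
            raise ConfigError("populations_per_species list must have n_species entries")
        if any(p not in (1, 2) for p in pops):
            raise ConfigError("populations_per_species entries must be 1 or 2")
        if isinstance(self.species_split_times, list):
            if len(self.species_split_times) != self.n_species - 1:
                raise ConfigError(
                    "species_split_times list must have n_species - 1 entries")
            times = list(self.species_split_times)
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise ConfigError("ladder split times must be nondecreasing")
        else:
            times = [self.species_split_times] * max(0, self.n_species - 1)
        if any(t <= 0 for t in times) and self.n_species > 1:
            raise ConfigError("species split times must be positive")
        if any(p == 2 for p in pops):
            if self.within_split_time <= 0:
                raise ConfigError("within_split_time must be positive")
            if times and self.within_split_time >= min(times):
                raise ConfigError(
                    "within_split_time must precede all species splits")
        if self.effective_size <= 0:
            raise ConfigError("effective_size must be positive")
        if self.mutation_rate <= 0:
            raise ConfigError("mutation_rate must be positive")
        if self.kappa < 0:
            raise ConfigError("kappa must be >= 0")
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated survey."""

    genealogy_newick: str
    species: dict[str, str]
    population: dict[str, tuple[int, int]]
    area: dict[str, str]
    #: population label -> population label -> expected substitutions/site
    expected_divergence: dict[str, dict[str, float]]
    config: SimConfig


class _Node:
    __slots__ = ("children", "time", "name")

    def __init__(self, time: float, name: str | None = None):
        self.children: list[_Node] = []
        self.time = time
        self.name = name


def _newick(node: _Node, parent_time: float | None = None) -> str:
    if node.children:
        inner = ",".join(_newick(c, node.time) for c in node.children)
        body = f"({inner})"
    else:
        body = node.name
    if parent_time is None:
        return body + ";"
    return f"{body}:{parent_time - node.time:.6f}"


def expected_divergence(t: float, n_e: float, mu: float) -> float:
    """Isolation-model expected substitutions/site between two populations.

    2*mu*t of divergence along the two branches since the split plus the
    coalescent expectation 2*(2*N_e*mu) within the ancestral population.
    At t = 0 this reduces to theta = 4*N_e*mu.
    """
    if n_e < 0 or mu < 0 or t < 0:
        raise ValueError("arguments must be nonnegative")
    return 2.0 * mu * t + 4.0 * n_e * mu


def _split_time(config: SimConfig, s1: int, p1: int, s2: int, p2: int) -> float:
    if (s1, p1) == (s2, p2):
        return 0.0
    if s1 == s2:
        return config.within_split_time
    if isinstance(config.species_split_times, list):
        # ladder: species j joins the ancestral chain at times[j-1]
        return config.species_split_times[max(s1, s2) - 1]
    return float(config.species_split_times)


def simulate_genealogy(config: SimConfig, rng: np.random.Generator) -> _Node:
    """Backward-in-time structured coalescent without migration.

    Lineages coalesce within their population at rate k(k-1)/2 / (2 N_e);
    population pools merge at the within-species split time and at the
    species split times; a single ancestral pool then coalesces to the root.
    """
    pools: dict[str, list[_Node]] = {}
    for s in range(config.n_species):
        for p in range(config.pops_of(s)):
            pool = []
            for k in range(config.samples_per_population):
                name = f"sp{s + 1:02d}_p{p + 1}_{k + 1:02d}"
                pool.append(_Node(0.0, name))
            pools[f"s{s}p{p}"] = pool

    events: list[tuple[float, str, int]] = []
    for s in range(config.n_species):
        if config.pops_of(s) == 2:
            events.append((config.within_split_time, "within", s))
    if config.n_species > 1:
        if isinstance(config.species_split_times, list):
            for j in range(1, config.n_species):
                events.append((config.species_split_times[j - 1], "species", j))
        else:
            for j in range(1, config.n_species):
                events.append((float(config.species_split_times), "species", j))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    t = 0.0
    two_ne = 2.0 * config.effective_size

    def _coalesce_until(t: float, t_end: float) -> float:
        while True:
            best_key, best_t = None, math.inf
            for key in pools:
                k = len(pools[key])
                if k < 2:
                    continue
                rate = k * (k - 1) / 2.0 / two_ne
                cand = t + rng.exponential(1.0 / rate)
                if cand < best_t:
                    best_key, best_t = key, cand
            if best_key is None or best_t >= t_end:
                return t_end
            pool = pools[best_key]
            i, j = rng.choice(len(pool), size=2, replace=False)
            i, j = int(i), int(j)
            parent = _Node(best_t)
            parent.children = [pool[i], pool[j]]
            pools[best_key] = [nd for m, nd in enumerate(pool) if m not in (i, j)]
            pools[best_key].append(parent)
            t = best_t

    for ev_time, kind, idx in events:
        t = _coalesce_until(t, ev_time)
        if kind == "within":
            pools[f"s{idx}p0"].extend(pools.pop(f"s{idx}p1"))
        else:
            dest = "s0p0"
            pools[dest].extend(pools.pop(f"s{idx}p0"))
    t = _coalesce_until(t, math.inf)
    (root_pool,) = pools.values()
    assert len(root_pool) == 1
    return root_pool[0]


def _k2p_transition_probs(t: float, mu: float, kappa: float
                          ) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after t generations."""
    beta = mu / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 * (1.0 - e1)
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def evolve_sequence(codes: np.ndarray, t: float, mu: float, kappa: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Evolve coded sequence (A=0,G=1,C=2,T=3) along a branch of t generations.

    Transition partner of code c is c^1; the two transversion partners are
    c^2 and c^3.
    """
    p_same, p_ts, p_tv = _k2p_transition_probs(t, mu, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    out[ts_mask] ^= 1
    out[tv1_mask] ^= 2
    out[tv2_mask] ^= 3
    return out


def simulate_survey(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Simulate a full survey: genealogy, sequences, metadata, truth.

    Deterministic per seed: identical config -> identical Dataset and truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    root = simulate_genealogy(config, rng)

    # mutate down the genealogy; root sequence uniform random
    seqs: dict[str, str] = {}
    root_codes = rng.integers(0, 4, size=config.seq_length).astype(np.uint8)

    def _down(node: _Node, codes: np.ndarray) -> None:
        if not node.children:
            seqs[node.name] = "".join(_ALPHABET[c] for c in codes)
            return
        for child in node.children:
            branch = node.time - child.time
            _down(child, evolve_sequence(codes, branch, config.mutation_rate,
                                         config.kappa, rng))

    _down(root, root_codes)

    pop_index = 0
    records: list[BarcodeRecord] = []
    species_of: dict[str, str] = {}
    population_of: dict[str, tuple[int, int]] = {}
    area_of: dict[str, str] = {}
    for s in range(config.n_species):
        species = f"{config.genus} sp{s + 1:02d}"
        for p in range(config.pops_of(s)):
            area = config.area_codes[pop_index % len(config.area_codes)]
            pop_index += 1
            for k in range(config.samples_per_population):
                sid = f"sp{s + 1:02d}_p{p + 1}_{k + 1:02d}"
                records.append(BarcodeRecord(
                    specimen_id=sid, species=species, sequence=seqs[sid],
                    genus=config.genus, locality=f"{area}_locality", area=area,
                ))
                species_of[sid] = species
                population_of[sid] = (s, p)
                area_of[sid] = area

    pop_key: dict[str, tuple[int, int]] = {}
    for s in range(config.n_species):
        for p in range(config.pops_of(s)):
            pop_key[f"sp{s + 1:02d}_p{p + 1}"] = (s, p)
    exp_div: dict[str, dict[str, float]] = {}
    for la, (s1, p1) in pop_key.items():
        exp_div[la] = {}
        for lb, (s2, p2) in pop_key.items():
            t_split = _split_time(config, s1, p1, s2, p2)
            exp_div[la][lb] = expected_divergence(
                t_split, config.effective_size, config.mutation_rate)

    truth = SimTruth(
        genealogy_newick=_newick(root),
        species=species_of,
        population=population_of,
        area=area_of,
        expected_divergence=exp_div,
        config=config,
    )
    return Dataset(records), truth


def write_survey(dataset: Dataset, truth: SimTruth, out_dir: str | Path
                 ) -> dict[str, Path]:
    """Emit FASTA + metadata TSV + truth newick in the dialects seqio reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "survey.fasta"
    meta = out / "survey.tsv"
    nwk = out / "truth.nwk"
    write_dataset(dataset, fasta, meta)
    nwk.write_text(truth.genealogy_newick + "\n")
    return {"fasta": fasta, "metadata": meta, "truth_newick": nwk}
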