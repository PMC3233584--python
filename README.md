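# barcodesurvey

Analysis toolkit for COI DNA-barcode surveys of birds (or any animal group
barcoded with a single mitochondrial marker). Given an aligned set of
barcode sequences and per-specimen metadata (species, locality, area of
endemism), the package answers the survey questions:

- How do genetic distances distribute **within** species versus **among**
  congeneric species (the "barcode gap")?
- Which species are **identifiable** from their barcodes, and which fail —
  because they are not monophyletic, share barcodes with a congener, or are
  too weakly sampled to reject chance reciprocal monophyly?
- Which species harbour **deeply divergent intraspecific clusters**
  (putative cryptic species), and between which **pairs of geographic
  areas** do those splits concentrate?

It is aimed at systematists and phylogeographers running barcode surveys
who want the standard distance/monophyly/delimitation battery as tested,
reproducible code instead of one-off scripts.

## Models and statistics

**Kimura two-parameter (K2P) distance.** With `P` and `Q` the proportions of
compared sites differing by a transition (A↔G, C↔T) and a transversion,

```
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
```

Sites with gaps, `N` or IUPAC ambiguities are excluded per pair (pairwise
deletion); pairs with fewer than 100 jointly resolved sites, or beyond the
model's saturation ceiling, are reported missing rather than guessed.

**Exact test of chance reciprocal monophyly.** Under a neutral-coalescent
null ("random branching"), the probability that two sister groups sampled
with `n_a` and `n_b` individuals are reciprocally monophyletic by chance is
computed by the recursion over labeled coalescent histories

```
P(i, j) = [C(i,2) P(i-1, j) + C(j,2) P(i, j-1)] / C(i+j, 2),   P(1,1) = 1
```

in exact rational arithmetic (e.g. `p(4,1) = 1/10`, `p(1,6) = 1/21`). A
brute-force enumeration of all labeled histories is included as an
independent oracle.

**Delimitation rules.** A species is *not identifiable* if (a) it is not
monophyletic on the analysis tree; (b) it shares barcodes (zero distance or
tree interdigitation) with a congener; or (c) its intraspecific variation
overlaps the lowest 5% of among-congener variation — or its sister lies
closer than 1% K2P — while the reciprocal-monophyly test cannot reject
chance at p = 0.05. Non-identifiable species carry the categories
I (sharing, sympatric), II (sharing, allopatric), III (monophyletic but
very close to the sister) and IV (paraphyletic with clusters > 1.5%
divergent). Intraspecific clusters are single-linkage components at the
1.5% K2P threshold.

Trees come from a deterministic neighbor-joining implementation with
seeded column-bootstrap support, or from any externally built newick.
A coalescent simulator (`simgen`) generates whole surveys with known truth
for testing and power exploration.

## Worked example

```python
import barcodesurvey as bs

# a synthetic genus: 5 species radiating at ~10% K2P; species 1 carries an
# internal two-population split at an expected 4%
cfg = bs.SimConfig(seed=7, n_species=5, samples_per_population=2,
                   populations_per_species=[2, 1, 1, 1, 1],
                   within_split_time=400_000, effective_size=2_000)
dataset, truth = bs.simulate_survey(cfg)

results = bs.BarcodeSurvey(dataset).fit()
print(results.summary())
```

prints

```
Barcode survey summary
======================
specimens: 12   species: 5   alignment: 700 bp
tree: nj
within-species K2P: n=10 pairs, range 0.00-4.74%
among-congener K2P: n=56 pairs, range 8.38-10.42%
lowest 5% of among-species variation: 8.38% K2P
identifiable species: 5/5 (100%)
categories: I=0  II=0  III=0  IV=0
deep-divergence species: 1
area-pair patterns: 1
```

All five species are identifiable (every rule is quiet), but the pipeline
flags exactly the deliberately split species as monophyletic-with-deep-
divergence — `results.deep_divergence` reports `Simulornis sp01` with two
clusters (areas N and Ron) at a maximum intraspecific distance of 4.7%, and
`results.area_patterns` credits the N–Ron area pair with that split.
`results.write_tables(out_dir)` emits the report TSVs (species summary,
non-identifiable, clusters, deep divergence, area pairs) plus a manifest
that suffices to re-run the analysis; reruns are byte-identical.

The same pipeline runs from the shell:

```
barcodesurvey simulate --seed 7 --out sim/
barcodesurvey survey --fasta sim/survey.fasta --meta sim/survey.tsv --out report/
barcodesurvey monop --na 4 --nb 1     # p(4,1) = 1/10 = 0.1
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from sample sizes alone, the exact probabilities of chance
reciprocal monophyly for the three published sister-pair sampling designs
(4,1), (1,3) and (1,6), cross-checks each against full enumeration of
labeled coalescent histories, and writes them at published precision.
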