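# barcodegap

Distance-based DNA-barcode analysis for species identification, built
around the workflow used to audit COI barcode reference libraries: compute
Kimura two-parameter (K2P) distances between ~652 bp mitochondrial COI
fragments, quantify the "barcoding gap" between intraspecific and
interspecific divergence, build the unrooted neighbor-joining tree, test
species monophyly, flag mitochondrial introgression and cryptic-species
signals, and identify query sequences against a reference library with an
explicit divergence threshold.

It is written for people who curate or use barcode libraries — molecular
taxonomists, fisheries and food-authentication labs, biodiversity
surveyors — and for anyone who wants the classic barcoding-gap analysis as
a tested, scriptable library instead of a chain of GUI tools.

## The model in brief

For two aligned sequences with transition proportion *P* (A↔G, C↔T) and
transversion proportion *Q* over the compared sites (pairwise deletion of
padded/ambiguous columns), the K2P distance is

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

Every specimen pair is assigned to the lowest taxonomic rank it shares —
S (same species), G (same genus), F (same family), O (order), C (class) —
and per-category summaries, Tukey-hinge boxplot statistics, Mann-Whitney
comparisons and min/max overlap reports describe the gap between the S and
G distributions. The unrooted NJ tree (Saitou–Nei agglomeration on the K2P
matrix) supports bipartition-based monophyly tests and detection of the
introgression signature in which one species' haplotypes sit inside another
species' cluster at intraspecific distances. Identification is
nearest-species matching under a threshold *t* (default 2.0%): `match`,
`ambiguous`, or `novel_candidate`.

A built-in simulator generates labelled COI-like libraries under a two-rate
substitution process matching the K2P model (default divergence depths:
0.3% within species, 16% between congeners, 20% within families), with
optional injected introgression events and cryptic species, so the whole
pipeline is testable without downloading anything. See `docs/methods.md`
for conventions, parameters and limitations.

## Worked example

Simulate a small library (4 families × 2 genera × 2 species × 3
individuals) and analyze it:

```sh
cat > sim.ini <<EOF
n_families = 4
genera_per_family = 2
species_per_genus = 2
individuals_per_species = 3
EOF
barcodegap simulate --out sim --seed 11 --config sim.ini
barcodegap analyze --fasta sim/simulated.fasta \
    --taxonomy sim/simulated_taxonomy.tsv --out results
cat results/rank_summaries.tsv
```

```
category  taxa  comparisons  mean    median  minimum  maximum  se
S         16    48           0.257   0.307   0.000    0.773    0.030
G         8     72           15.615  15.075  11.929   20.456   0.317
F         4     144          18.039  17.586  15.134   23.534   0.184
O         1     864          19.527  -       14.723   24.934   0.065
```

Distances are percent K2P. Conspecific individuals differ by 0.26% on
average while congeneric species differ by 15.6% — a ~60-fold separation
with no overlap (the report's `S vs G` entry shows a gap of 11.2 percentage
points between the deepest conspecific pair, 0.773%, and the closest
congeneric pair, 11.929%). That clean gap is what makes threshold-based
identification work. `results/report.json` also records that all 16
species are monophyletic in the NJ tree (`tree.nwk`), family cohesion is
1.0, and the S-vs-G Mann-Whitney test rejects at p ≈ 2e-20. Adding
`n_introgression_events = 1` to the config produces a dataset where the
report flags exactly the injected donor/recipient species pair.

Identify queries against a reference library:

```sh
barcodegap identify --query queries.fasta \
    --ref-fasta sim/simulated.fasta \
    --ref-taxonomy sim/simulated_taxonomy.tsv \
    --threshold 2.0 --out identifications.tsv
```

The same functionality is available as a library
(`barcodegap.run_analysis`, `barcodegap.identify_query`, ...); the CLI is a
thin wrapper.

## Analyzing the published survey data

The package reproduces the rank-divergence table of the marine-fish COI
survey whose 321 sequences are deposited under GenBank accessions
EF607296–EF607616. The sequences are not redistributed here; fetch and
convert them (network required) with

```sh
python scripts/fetch_genbank.py data/real
```

then complete the `family`/`order` columns of `data/real/taxonomy.tsv` from
a fish taxonomy source if any are blank. With those files in place, the
real-data checks in `tests/test_acceptance.py` compare the pipeline's
output against the published values (mean intraspecific 0.319%, mean
congeneric 15.742%, 652 bp consensus window, >10% congeneric minimum once
the hybridizing *Pampus* pair is excluded).

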