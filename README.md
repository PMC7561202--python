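# ssrkit

Toolkit for SSR/microsatellite characterization of germplasm collections:
diversity statistics, Bayesian admixture clustering, DAPC, Rogers-distance
neighbor-joining trees, fingerprint-based identity resolution, and
core-collection selection — plus a synthetic-germplasm generator with
ground truth so the entire pipeline can be exercised and verified without
external data.

## Modules

| module | what it does |
| --- | --- |
| `ssrkit.genotypes` | genotype data model, pairs-CSV / two-column parsing, two-rows-per-individual integer export, reference panels, allele-size standardization |
| `ssrkit.diversity` | Na, Ne, Ho, He, F, PIC, discriminating power (Dj), null-allele EM, private/rare alleles, collection summaries |
| `ssrkit.identity` | duplicate/synonym grouping on exact multilocus profiles, reference-panel validation (validated / misnamed / unknown / unreported) |
| `ssrkit.phylogeny` | Rogers' genetic distance, deterministic neighbor joining, locus bootstrap supports, Newick I/O |
| `ssrkit.admixture` | Gibbs-sampled admixture model, multi-run K scan, ΔK (second-difference) K selection, run alignment, q-threshold classification, hierarchical second round |
| `ssrkit.dapc` | allele-indicator transform, exact PCA, K-means scan with classification BIC, linear discriminant analysis |
| `ssrkit.cores` | greedy + steepest-ascent core selection (allele coverage / entry-to-nearest-entry objectives), core evaluation |
| `ssrkit.simulate` | multi-pool germplasm generator (admixture, clones, null alleles, missingness) and pinned fixtures |
| `ssrkit.pipeline`, `ssrkit.cli` | end-to-end orchestration and `ssrkit` command-line interface |

## CLI

```sh
# generate a synthetic collection with ground truth
ssrkit simulate --seed 7 --out germplasm.csv --truth-out truth.json \
    --n-pure 100 --n-admixed 80 --n-duplicate-pairs 5 --n-synonym-groups 4

# per-locus diversity table (Na, Ne, Ho, He, F, PIC, Dj, r)
ssrkit stats germplasm.csv --out locus_table.csv

# duplicates/synonyms, optionally validated against a reference panel CSV
ssrkit identity germplasm.csv --out report.json [--panel panel.csv]

# Rogers-distance NJ tree with bootstrap supports
ssrkit tree germplasm.csv --out tree.nwk --bootstrap 1000 --seed 1

# admixture K scan (use --scaled for the documented desk-scale MCMC mode:
# burn-in 2,000 / 10,000 sweeps instead of 100,000 / 1,000,000)
ssrkit structure germplasm.csv --out structure/ --seed 1 --scaled

# DAPC and core collections
ssrkit dapc germplasm.csv --out dapc/ --seed 1
ssrkit core germplasm.csv --out cores/ --fraction 0.1 --fraction 0.2 --fraction 0.3
ssrkit core germplasm.csv --out cores/ --size-absolute 120 --seed 1

# the whole pipeline in survey order
ssrkit pipeline germplasm.csv --out run/ --seed 1 --scaled
```

Input format (`pairs_csv`): header row with locus names, first column the
accession ID, optional `meta:`-prefixed metadata columns (e.g. `meta:name`
for the declared cultivar name), cells `a/b` in base pairs, missing `.`.

Full-scale MCMC settings (1e6 sweeps × 10 runs × 10 K values) reproduce
survey practice but are **not** desk-scale; the `--scaled` mode is a
first-class, documented configuration used throughout the tests.

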