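# polylink

Multipoint recombination-fraction estimation and parental haplotype
phasing for full-sib (F1) populations of autopolyploids with any even
ploidy level.

The model treats meiosis as random bivalent pairing of the `m` homologs:
a gamete carries one homolog per bivalent, offspring genotype states are
pairs of parental gamete states, and an HMM over those states (with
dosage-based emissions) yields multipoint recombination fractions via
forward–backward EM. Linkage phases are found by a sequential search
whose candidate space is pruned with two-point LOD scores over sharing
partitions, with homolog-permutation redundancy removed via canonical
forms. A meiosis simulator (with optional preferential pairing) makes
the whole system testable end to end.

## Layout

| module | contents |
| --- | --- |
| `polylink.states` | bivalent configurations, gamete/genotype ranking, recombinant-bivalent counts |
| `polylink.model` | gamete/genotype transition probabilities, emissions, polysomic priors |
| `polylink.twopoint` | collapsed dosage-class tables `A(r)`, per-partition r estimation, LOD scores, Fisher information |
| `polylink.hmm` | forward–backward, EM re-estimation, chain likelihood, genotype posteriors |
| `polylink.phasing` | sequential phase search (two-point pruning + HMM scoring), canonical forms |
| `polylink.sim` | parental-haplotype scenarios A/B/C, bivalent meiosis, replicated studies, Haldane map function |
| `polylink.io` | dosage CSV dialect, truth sidecars, phased-map/pairwise TSV, filtering and segregation QC |
| `polylink.cli` | `polylink` command-line tool |

## CLI

```sh
# simulate a tetraploid full-sib family: writes pop.csv + pop.truth.json
polylink simulate -m 4 -n 200 -z 10 --scenario A --seed 1 -o pop

# all pairwise two-point estimates (best phase per pair)
polylink pairwise -d pop.csv -o pairwise.tsv

# sequential phasing of the chain in file order
polylink phase -d pop.csv --eta 3 --multipoint-lod 10 -o map.tsv

# re-estimate recombination fractions for an existing phased map
polylink refit --map map.tsv -d pop.csv

# compare a phased map against the simulation truth
polylink evaluate --map map.tsv --truth pop.truth.json

# replicated simulate-phase-evaluate study
polylink study -m 4 --replicates 50 --eta 3 --seed 7 -o study.tsv
```

Dosage files are comma-separated with `#` comments, header records
`ploidy` / `n.mrk` / `n.ind`, a `marker,dP,dQ,<individuals...>` table and
`NA` for missing calls. Genotype-caller posteriors can be attached
programmatically (`DosageDataset.priors`); a VCF convenience reader
(`polylink.io.read_vcf_dosages`) extracts dosages from `DS` or `GT`
fields.

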