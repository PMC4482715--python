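# svk

Allele-level comparison of maize starch-biosynthesis genes (*Zpu1*, SSIII)
with CAPS restriction typing, polydispersity analysis of amylopectin glucan
chain-length distributions, and the statistical association of pullulanase
activity and chain-length dispersity with kernel vitreousness — plus a
synthetic-data generator so the whole pipeline runs with no external
downloads.

## Modules

| module | what it does |
| --- | --- |
| `svk.io` | FASTA / CSV readers and writers, domain types (`SequenceRecord`, `RilRecord`, `RunConfig`) |
| `svk.simulate` | synthetic allele pairs with planted variants, FACE-like chain-length distributions, RIL phenotype panels with known truth |
| `svk.alleles` | global alignment (affine gaps, leftmost-gap normalization), variant calling, conceptual translation, coding-effect classification, domain assignment |
| `svk.digest` | IUPAC-degenerate restriction-site scanning (BslI `CCNNNNN^NNGG` shipped), linear digest prediction, gained/lost CAPS sites between alleles |
| `svk.chains` | chain-length distribution moments: number-average DP, mass-average DP, dispersity (PDI), replicate averaging |
| `svk.stats` | slope ANOVA, pairwise-t and Tukey-HSD compact letter displays, exponential growth regression with Wald CI, full association battery |

## CLI

```sh
svk simulate --kind alleles|chains|panel [--spec config.toml] --seed N --out dir/
svk alleles  --ref ref.fa --alt alt.fa [--cds-offset N] [--domains domains.csv] --out variants.csv
svk digest   --seq amplicon.fa --enzyme BslI [--region 2632:2965] --out fragments.csv
svk chains   --table face.csv --out summaries.csv
svk associate --panel phenotypes.csv --chains summaries.csv --alpha 0.05 --out report/
```

End-to-end on synthetic data:

```sh
svk simulate --kind panel --seed 1 --out fixtures/
svk chains --table fixtures/chains.csv --out fixtures/summaries.csv
svk associate --panel fixtures/phenotypes.csv --chains fixtures/summaries.csv --out report/
```

Every stage logs its configuration, seed, input digests and row counts to
stderr, and exits nonzero without partial outputs on malformed input.
Coordinates are 1-based and inclusive throughout.

## Accession data

The sequence-level results are anchored to six GenBank records:
`AF080567` (W64A+ *Zpu1*), `KP872821` (W64A*o2* *Zpu1*), `KP872822`
(K0326Y *Zpu1*), `JF273457` (W64A+ SSIII), `KR350619` (W64A*o2* SSIII),
`KR350620` (K0326Y SSIII). The pipeline never fetches them itself —
downloading is a documented external step:

```sh
mkdir -p data/accessions
for acc in AF080567 KP872821 KP872822 JF273457 KR350619 KR350620; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text" \
    > data/accessions/${acc}.fasta
done
```

With the files in place, `tests/test_acceptance.py::TestSequenceTargets` and
the accession-based entries of the acceptance report become computable; in an
offline environment those tests fail with an explanatory message and the
report omits the corresponding keys.

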