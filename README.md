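# ncmap

Discovery of immune-edited, non-canonical MHC class I associated peptides
(MAPs) in mismatch-repair-deficient (MMRd) versus proficient (MMRp) tumor
cells. The package implements, as a tested and reusable pipeline:

- **`ncmap.intervals`** — interval algebra (merge / complement / sizes) and
  construction of the labeled genomic region partition (coding, 5'UTR,
  3'UTR, ncRNA, intron, extragenic) from a refFlat-style transcript table,
  with priority-based region assignment.
- **`ncmap.variants`** — somatic variant filtering (depth ≥ 10, ≥ 9
  supporting reads, germline subtraction), per-region tumor mutational
  burden (variants/Mb), immune-editing log-ratios ln(TMB_post/TMB_pre),
  gained/lost alteration rates, silent/non-silent classification, and a
  microsatellite tandem-repeat scanner with indel flagging.
- **`ncmap.peptides`** — six-frame translation of RNA-seq reads, 8–11-mer
  k-mer counting per sample, and the genotype-specific database selection
  rules (count floor, loss/counter-selection and expansion-exclusion
  formulas, cross-genotype exclusions), plus observed-peptide matching.
- **`ncmap.annotation`** — back-annotation of matched peptides: peptide
  location within source reads, a seed-and-extend genomic matcher scored as
  `match + rep_match − mismatch − q_gap_count − t_gap_count`, locus merging
  (distance 5 bp, distinct read counts), uniqueness filtering, and region /
  frame / mutation annotation (canonical ⇔ coding ∧ in-frame).
- **`ncmap.quantify`** — coverage-normalized MAP rates (bases covered
  ≥ 10×), the region-level peptide TPM formula, RNA fold changes
  ln((post+1)/(pre+1)), and the candidate filters (expressed pre-injection,
  absent in immunocompetent hosts, atypical translation, composite rank)
  with round-robin pooling.
- **`ncmap.simulate`** — a synthetic-data generator with planted truth:
  toy genome with gene structure and microsatellites, per-region variant
  rates with an MMRd multiplier, canonical and aberrant transcription,
  an immune-editing plan removing planted peptides from
  immunocompetent-host samples only, and an observed-peptide list.
- **`ncmap.cli` / `ncmap.pipeline`** — one CLI orchestrating every stage on
  serialized plain-text artifacts, with manifests.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: the
planted-truth round trip (the MMRd database equals the planted
edited-peptide closure with precision = recall = 1.0), oracle equivalence
of the k-mer counting and alignment against naive enumerations, the exact
formula truth tables, 100% annotation agreement with planted truth,
directional recovery of immune editing over 20 seeded runs, and the
in-paper candidate-table worked example.

## CLI

```sh
# full workflow on synthetic data
ncmap all --seed 1 --outdir runs/demo

# or stage by stage
ncmap simulate --seed 1 --outdir runs/demo
ncmap regions  --refflat runs/demo/transcripts.refflat \
               --genome-sizes runs/demo/genome.sizes --outdir runs/demo/regions
ncmap tmb      --vcf runs/demo/vcf/MMRd_pre.vcf \
               --germline runs/demo/vcf/germline.vcf \
               --regions-dir runs/demo/regions --out tmb.tsv
ncmap build-db --reads-dir runs/demo/reads --outdir runs/demo/db
ncmap match    --observed runs/demo/observed_peptides.tsv \
               --db-self runs/demo/db/db_MMRd.tsv \
               --db-other runs/demo/db/db_MMRp.tsv --out matched.tsv
ncmap annotate --rundir runs/demo --matched matched.tsv --out annotated.tsv
ncmap quantify --coverage runs/demo/coverage/MMRd_pre.bedgraph \
               --regions-dir runs/demo/regions --annotated annotated.tsv \
               --out quant.tsv
```

Simulation parameters come from a YAML config whose keys mirror
`ncmap.simulate.SimulationConfig`; all method thresholds (depth ≥ 10,
alt ≥ 9, count floor 10, diff ≥ 10, ratio ≥ 10, merge distance 5,
coverage depth 10, k = 8–11) are exposed with their default values.

## Conventions

All coordinates are 0-based half-open (BED convention) internally; VCF
positions are converted on read. Region tracks are unstranded after
construction; strand is used for UTR sides and frame status. Counting unit
for peptides defaults to occurrences (read × frame × offset × k);
`count_mode="reads"` collapses to distinct reads.
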