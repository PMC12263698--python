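# tumevo

Tumor evolution analysis from bulk DNA sequencing read counts of a single
patient. From per-sample reference/mutant read counts at SNV positions,
`tumevo` infers:

- **clone genotypes and frequencies** — deconvolution of observed variant
  allele frequencies under a CNA-free heterozygous model (`V = ½·fᵀM`),
  with samples modeled as evolutionarily related;
- **a maximum-parsimony clone phylogeny** rooted at an all-zero germline
  outgroup, with Fitch ancestral genotypes and per-branch mutation sets;
- **a mutational tree** (temporal groups of co-occurring mutations) with
  user-provided driver mutations timed on its edges;
- **branch-specific mutational signature activities** — 96-channel SBS
  spectra per branch, quadratic-programming refits against a COSMIC-format
  catalog, spurious-signature filtering, and cross-branch harmonization;
- **a metastatic cell-migration graph** — exact Bayesian posteriors of
  ancestral anatomical sites (belief propagation on the clone tree) and a
  directed site graph annotated with supporting-mutation counts;
- **a sample tree** — weighted UniFrac / MNTD clone-composition distances
  between samples and a neighbor-joining tree;
- **publication-style SVG figures** for every analysis.

A simulator (`tumevo.simulate`) generates synthetic patients with full
ground truth (tree, genotypes, frequencies, branch signature mixtures,
migration history, read counts), so the whole pipeline is testable with no
external data.

## CLI

```sh
# generate a synthetic patient (inputs + truth/ directory)
tumevo simulate --outdir demo --seed 7

# full analysis
tumevo run --profile demo/profile.tsv --drivers demo/drivers.tsv \
           --signatures demo/signatures.tsv --sites demo/sites.cfg \
           --outdir demo/results --seed 7

# clone deconvolution only
tumevo deconvolve --profile demo/profile.tsv --outdir demo/clones --seed 7
```

`--config` accepts a flat `key=value` file overriding pipeline defaults
(`p_mig`, `presence_threshold`, `epsilon_cos`, `isolation_threshold`,
`min_branch_mutations`, ...). `--sites` maps sample names to anatomical
sites (`sample=site` lines); without it each sample is treated as its own
site.

### Input formats

- **Mutation profile** (TSV): columns `snv_id, ref, alt, trinucleotide`
  (optional `chrom:pos`), then count pairs `<sample>:ref` / `<sample>:alt`.
  At least four tumor samples are required.
- **Driver list** (TSV): `snv_id  gene  label`.
- **Signature catalog** (TSV): COSMIC SBS layout, a `Type` column with
  channel labels like `A[C>A]A` plus one column per signature.

### Outputs

`clones.tsv`, `frequencies.tsv`, `clone_tree.nwk`, `mutation_tree.json`,
`branch_activities.tsv`, `branch_spectra.tsv`, `migration_graph.{json,dot}`,
`location_posteriors.tsv`, `sample_distances{,_mntd}.tsv`,
`sample_tree.nwk`, one SVG per figure, and `manifest.json` (tool version,
input SHA-256 digests, all parameters, seed). Re-running with identical
inputs and seed reproduces every file byte-for-byte except the manifest
timestamp.

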