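# shmkit

Toolkit for analysing how hotspot-motif identity, local sequence context
and motif position shape somatic-hypermutation profiles. It provides:

- **`shmkit.motifs`** — WRCH/DGYW degenerate-motif grammar: two-strand
  scanning (bottom-strand hits detected as top-strand DGYW occurrences
  and reported in top-strand coordinates), orientation classification
  (palindromic / bidirectional / unidirectional), C-centered 15-mer
  context windows, overlapping pyrimidine-dimer (PyPy) counting, and
  symmetric context-swap helpers.
- **`shmkit.repertoire`** — statistics over germline-aligned V-region
  repertoires: exact-15-mer context groups with coverage and central-C
  mutation tallies, a minimum-coverage filter (default 30),
  mutability-vs-PyPy and frequency-vs-PyPy summaries with (weighted)
  Pearson correlations, and per-FWR/CDR subregion mutation loads.
- **`shmkit.mutpe`** — amplicon deep-sequencing quantification: sliding
  window quality trimming (Q25 over 5 nt), mate length filtering
  (200/100 nt), overlap merging (≤10% mismatch), merged-length gating
  (±30 nt), gapless placement on the amplicon reference, a Q30-filtered
  pileup, per-position mutation frequencies, region-normalized
  frequencies, and unpaired two-tailed t-tests between sample groups.
- **`shmkit.simulate`** — synthetic inputs for everything above:
  germlines with motifs planted at chosen coordinates inside
  hotspot-free filler, repertoires mutated under a motif × context ×
  position Bernoulli rate model, and overlapping paired-end reads.
- **`shmkit.traj`** — trajectory descriptors: radius of gyration,
  per-atom/per-residue RMSF with optional Kabsch superposition, and the
  per-nucleotide surface-distance profile Δs = |r_P − c| − Rg(protein),
  with multi-model PDB and XYZ readers.
- **`shmkit.cli`** — a `shmkit` command tying the stages together.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(scanner vs. a brute-force two-strand oracle, PyPy superadditivity,
Pearson vs. a two-pass textbook formula), and `tests/test_acceptance.py`
with one test per acceptance criterion (oracle equivalence on 1,000
random sequences, simulator parameter recovery over 20 seeds, a 5,000×
amplicon round trip, scale invariance of normalized profiles, and
closed-form trajectory cases).

## CLI

```sh
shmkit sim germline --out germ.fasta --regions-out regions.txt --seed 1
shmkit scan --fasta germ.fasta --out hits.tsv
shmkit sim repertoire --germline germ.fasta --regions regions.txt \
    --n 1000 --seed 2 --out records.tsv
shmkit repertoire analyze --records records.tsv --out-dir analysis/
shmkit sim reads --template germ.fasta --depth 2000 --out-prefix sample
shmkit mutpe run --r1 sample_R1.fastq --r2 sample_R2.fastq \
    --reference germ.fasta --out-dir mutpe_out/ --sample-id s1
shmkit mutpe compare --group-a a1.tsv --group-a a2.tsv \
    --group-b b1.tsv --group-b b2.tsv --out compare.tsv
shmkit traj rg    --trajectory traj.pdb --out rg.tsv
shmkit traj rmsf  --trajectory traj.pdb --out rmsf.tsv
shmkit traj deltas --trajectory traj.pdb --out deltas.tsv
```

Every threshold is exposed as a flag with its published default; run
any subcommand with `--help` to see them. Exit codes: 0 ok, 1 data
error, 2 configuration/usage error.

## Layout

```
src/shmkit/        package modules (motifs, repertoire, mutpe,
                   simulate, traj, stats, io, cli, errors)
tests/             pytest suite incl. test_acceptance.py
scripts/acceptance.py
```
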