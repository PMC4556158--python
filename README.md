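# tetrabin

Metagenome binning from sequence composition and multi-sample coverage.
Contigs from a metagenome assembly are grouped into genome bins using two
calibrated probabilistic distances that are combined into one composite
pairwise distance and clustered with an iterative medoid algorithm:

- **TDP** — the posterior probability that two contigs come from different
  genomes given the Euclidean distance between their canonical
  tetranucleotide frequency (TNF) vectors, calibrated empirically per
  contig-size pair with a logistic model `1/(1+exp(-(b + c*d)))` and
  interpolated over a log-size grid.
- **ADP** — the non-shared area (total-variation distance) between the
  normal coverage distributions of two contigs in one sample, evaluated in
  closed form and combined across informative samples as a geometric mean.
- **Composite** — `max(TDP, ADP)` when TDP > 0.05, otherwise
  `ADP*w + TDP*(1-w)` with `w = min(log(n+1)/log(m+1), alpha)` growing with
  the number of informative samples.
- **Binning** — seed on the highest-coverage contig, recruit within the
  distance cutoff `1-p1` of the current medoid, iterate the medoid to
  convergence, optionally refine at `1-p2`, sweep until no contig remains,
  dissolve bins of ≤ 200 kb, and (with ≥ 10 samples) recruit leftover
  contigs by depth-profile correlation.

The package also ships a synthetic-community generator (Markov-chain
genomes, exponential contig sizes, super-Poisson depth tables with ground
truth) and a base-weighted precision/recall evaluator, so the whole method
is testable offline.

## CLI

```sh
# generate a synthetic benchmark community
tetrabin make-fixture -o fixture --seed 42 --genomes 10 --samples 5

# train a distance model from reference genomes (one genome per FASTA record)
tetrabin train-model -g refs.fasta -o model.json

# bin an assembly; coverage is optional (BAMs or a precomputed depth table)
tetrabin bin -i fixture/assembly.fasta --depth fixture/depth.tsv -o out
tetrabin bin -i asm.fa --bam s1.bam --bam s2.bam -o out
tetrabin bin -i asm.fa -o out              # TNF-only mode

# score bins against the ground truth
tetrabin evaluate --membership out/membership.tsv --truth fixture/truth.tsv
```

`bin` writes one FASTA per bin, `membership.tsv` (contig → bin, 0 =
unbinned), `summary.tsv`, and a `run_report.json` that echoes the full
configuration. `--cache-dir` stores reusable intermediates (TNF matrix,
default model) so a re-run skips their recomputation. Without `--model`, a
default model is trained on bundled synthetic genomes; supply your own
genomes via `train-model` for real data.

Key flags mirror the method constants: `--p1 0.90 --p2 0.95`
(probability cutoffs), `--min-contig 2500`, `--min-bin 200000`,
`--min-cv 1.0`, `--tdp-switch 0.05`, `--recruit-corr 0.9`.

The depth table is the standard summarizer layout: `contigName contigLen
totalAvgDepth` followed by one `(mean, variance)` column pair per sample.

## Layout

- `src/tetrabin/tnf.py` — FASTA reading, canonical 136-class TNF vectors.
- `src/tetrabin/tdp.py` — genome shredding, pair sampling, empirical
  posterior, logistic fitting, size-interpolated model (JSON serialized).
- `src/tetrabin/abundance.py` — BAM/depth-table coverage, closed-form ADP,
  geometric-mean combination, sample-count weight.
- `src/tetrabin/composite.py` — composite rule, dense matrix + lazy provider.
- `src/tetrabin/binning.py` — iterative medoid clustering, retention,
  correlation recruitment, output writers.
- `src/tetrabin/synthetic.py` — community simulator with truth tables.
- `src/tetrabin/evaluation.py` — precision/recall scoring, good-genome count.
- `src/tetrabin/pipeline.py`, `src/tetrabin/cli.py` — orchestration.
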