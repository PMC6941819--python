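# endofilter

Somatic variant callers run on libraries fragmented with DNA endonucleases
(instead of ultra-sonication) report thousands of spurious SNVs/indels. The
enzymes cut preferentially at palindromic, hairpin-forming genomic sites, and
the polymerase fill-in step that follows mis-incorporates bases at the
hairpin center. The resulting artifacts have three hallmarks:

* they sit at the center of a palindromic reference context (an
  *SNV-centered palindrome*, SCP);
* on the sequenced reads they cluster 10–15 bases from the 5' or 3' read
  edge (*positional bias*);
* their supporting reads are heavily soft-clipped (multi-nucleotide
  substitutions near the read end).

Because the enzyme prefers the same sites in every library, the artifacts
also *recur* across samples, which makes them dangerously easy to mistake
for driver mutations.

`endofilter` is for anyone analyzing tumor/normal calls from enzymatically
fragmented libraries. It removes these artifacts in two stages:

1. **Cohort recurrence with whitelist rescue.** A call whose exact key
   (chrom, pos, ref, alt) recurs in ≥ 2 other samples of a pooled cohort of
   enzymatically fragmented libraries is removed — unless it appears in a
   known-genuine whitelist (e.g. COSMIC-registered variants), in which case
   it is *returned to* the second stage rather than auto-accepted.
2. **A logistic noise classifier.** For each surviving call the package
   walks the CIGAR of every covering read to locate the variant's in-read
   offset, runs a two-sample Kolmogorov–Smirnov test of variant- vs
   wildtype-supporting read positions (exact, permutation-based, for small
   samples), and measures the soft-clipped fraction of variant reads. A
   logistic regression on x₁ = −log₁₀(p_KS + ε) and x₂ = clip ratio models
   P(artifact | x₁, x₂); the probability cut is chosen to maximize
   sensitivity + specificity, which corresponds to a straight threshold line
   in feature space.

The package also detects and tabulates SCPs (maximal arm k with the 3' flank
equal to the reverse complement of the 5' flank, reported length 2k+1), and
refits mutational-signature exposures w by minimizing ‖f − Pw‖² over the
probability simplex (w ≥ 0, Σw = 1), where f is the sample's 96-class
trinucleotide spectrum and P a signature-probability matrix — removing the
artifacts restores the biological signature composition.

A fully deterministic read simulator (`endofilter simulate`) generates the
complete test bed — reference with embedded hairpins, aligned reads with
implanted artifact/genuine variants, per-sample call tables with controlled
cohort recurrence, and ground-truth labels — so the whole pipeline is
testable offline.

## Worked example

Simulate a 3-sample cohort, extract features, train the classifier on the
simulator's ground-truth labels, and filter sample S1:

```
$ endofilter simulate --outdir sim --seed 7 --n-samples 3 --n-artifact 40 --n-genuine 15 --depth 50
$ endofilter features --calls sim/S1.calls.tsv --bam sim/S1.bam \
      --fasta sim/reference.fa --sample-id S1 --out S1.features.tsv
wrote 49 feature rows to S1.features.tsv
$ endofilter train --features labeled.tsv --out model.json
model saved to model.json (training sensitivity 1.000, specificity 1.000)
$ endofilter filter --calls sim/S1.calls.tsv --sample-id S1 --bam sim/S1.bam \
      --fasta sim/reference.fa --cohort sim/S1.calls.tsv --cohort sim/S2.calls.tsv \
      --cohort sim/S3.calls.tsv --model model.json --out-prefix S1.filtered
{
  "input": 49,
  "removed_recurrent": 26,
  "rescued_whitelist": 0,
  "removed_model": 8,
  "retained": 15
}
```

Of S1's 49 calls (34 implanted artifacts, 15 genuine), 26 artifacts were
caught by cohort recurrence, the remaining 8 by the classifier, and all 15
genuine calls were retained. The accounting always closes: input =
removed_recurrent + removed_model + retained. `S1.filtered.vcf` carries the
decisions as FILTER tags (`recurrent_artifact`, `model_noise`, `PASS`) and
the per-variant features as INFO fields; `--hard-filter` drops the tagged
records instead.

Signature refitting before filtering shows the artifact signature dominating:

```
$ endofilter signatures --calls sim/S1.calls.tsv --sample-id S1 \
      --fasta sim/reference.fa --out S1.exposures.tsv
49 SNVs classified (0 excluded); residual 0.0763; wrote S1.exposures.tsv
signature   exposure
SigNoise    0.531
SigGenuine  0.102
SigFlat     0.367
```

After filtering, the noise-signature exposure drops to zero (see
`endofilter report`, which writes before/after counts, SCP spectra and
exposure tables).

The same machinery is available as a library: `LogisticNoiseClassifier` is a
scikit-learn estimator (`fit`/`predict`/`predict_proba`), and
`SignatureRefitter` a transformer mapping (n, 96) spectra to (n, K)
exposures, so both compose with sklearn pipelines and model selection.

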