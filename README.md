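# dsspectrum

Spectrum-of-activity analysis for insecticidal double-stranded RNA (dsRNA).

Ingested dsRNA triggers RNA interference (RNAi) in insects, and crop-protection
triggers such as a 240-nt *Snf7* fragment are designed to be lethal to a target
pest (western corn rootworm) while sparing non-target organisms. Whether a
non-target is at risk is largely a sequence question: RNAi requires a shared
contiguous stretch of ≥ 21 nt between the trigger and the non-target's
transcript. `dsspectrum` implements the complete specificity screen an
ecological risk assessor runs around that rule, plus the bioassay statistics
used to confirm it experimentally:

- **Sequence specificity metrics** — pairwise global alignment (affine-gap
  Needleman–Wunsch) of the trigger against each ortholog; SNP counts; percent
  identity `100·(L − SNPs − gaps)/L`; the number *m* of shared contiguous
  *k*-nt windows (*k* = 21 by default) and the longest shared run ℓ.
- **Activity prediction** — predicted active ⇔ *m* ≥ 1 at *k* = 21
  (equivalently ℓ ≥ 21).
- **Identity-distance tree** — UPGMA (size-weighted average linkage) on
  `d(i,j) = 100 − percent identity(i,j)`, written as Newick.
- **Bioassay statistics** — maximum-likelihood probit dose-response with
  natural-mortality correction, `P(dead|dose) = c + (1−c)·Φ(a + b·log₁₀ dose)`,
  giving the LC50 `10^(−a/b)` with a delta-method 95% interval; Abbott's
  correction; Fisher's exact test for survival endpoints; pooled-variance
  *t* and Levene tests for continuous endpoints.
- **Synthetic data** — ortholog families with SNPs planted at controlled
  positions (including solving for an exact shared-21-mer count *m*, which
  depends on SNP *location*, not just count) and binomial probit bioassays.

## Worked example

```python
import dsspectrum as ds

trig = ds.random_trigger(240, seed=7, id="trigger")
orths = [
    ds.synthetic_ortholog(trig, ds.OrthologSpec(snp_count=s, seed=10 + s), id=name)
    for s, name in [(3, "close_relative"), (22, "same_subfamily"), (67, "outgroup")]
]
ds.write_fasta([trig], "trigger.fa")
ds.write_fasta(orths, "orthologs.fa")
report = ds.run_spectrum_report(
    ds.RunConfig(trigger_path="trigger.fa", orthologs_path="orthologs.fa", out_dir="out")
)
print(open("out/report.tsv").read())
```

prints

```
species	percent_identity	n_snps	n_k_matches	longest_run	predicted_active
close_relative	98.8	3	182	196	yes
same_subfamily	90.8	22	25	35	yes
outgroup	72.1	67	0	12	no
```

Read each row as: the ortholog with 3 SNPs keeps 98.8% identity to the
trigger, still shares 182 of the 220 possible 21-nt windows (longest run
196 nt) and is predicted susceptible; with 22 SNPs identity drops to 90.8%
but 25 shared 21-nt windows remain, so activity is still predicted; the
outgroup-level ortholog (67 SNPs, 72.1% identity) has no shared run longer
than 12 nt and is predicted safe. `out/tree.nwk` holds the matching UPGMA
tree — for this run
`(((trigger:0.625,close_relative:0.625):4.27,same_subfamily:4.90):10.24,outgroup:15.14);`
(branch lengths in identity percentage points) — and `out/report.json` keeps
the unrounded values.

The same analysis is available from the shell:

```
dsspectrum report --trigger trigger.fa --orthologs orthologs.fa --out out
dsspectrum probit --bioassay assay.csv --species CPB
dsspectrum tree --fasta orthologs.fa --out tree.nwk
dsspectrum simulate --out-fasta sim.fa --out-csv sim.csv --seed 3
```

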