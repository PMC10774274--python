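# clipfoot

Downstream analysis of CLIP-seq binding footprints for an RNA-binding
protein studied across disease conditions, plus the quantification layer
for the splicing and qPCR assays used to validate individual targets.

CLIP-seq experiments immunoprecipitate an RNA-binding protein (here,
hnRNP A1 in a neuroinflammation model) and sequence the crosslinked RNA
fragments, yielding per-replicate sets of scored genomic peaks. Turning
those into trustworthy "footprints" requires a chain of decisions —
background depletion, merging, majority agreement across replicates,
reproducibility modelling — that is usually scattered across ad-hoc
scripts. `clipfoot` implements that chain as a tested, reusable library:

- **Footprint construction** — strand-agnostic interval subtraction against
  size-matched input / IgG background, merging of overlapping and
  book-ended sites, and majority-consensus footprints (a candidate is kept
  when ≥ 2 of 3 or 4 replicates overlap it by ≥ 2 nt), with closest-gene
  assignment and genic-region proportions (CDS / 5′UTR / 3′UTR / intron).
- **Reproducibility (IDR)** — the two-component Gaussian copula mixture on
  rank-transformed peak scores: a fraction π₁ of matched peak pairs draws
  correlated pseudo-scores from N(μ₁, σ₁²) with correlation ρ₁, the rest
  from an independent standard bivariate normal. The posterior null
  probability per pair is the local idr; the running mean of ascending
  local idr is the global IDR. On top sit ENCODE-style quality ratios from
  binomial pseudo-replicate splits: rescue = max(N_p, N_t)/min(N_p, N_t),
  self-consistency = max(N₁, N₂)/min(N₁, N₂), with either ratio < 2
  deemed acceptable and outlier samples flagged.
- **Profile comparison** — Venn partitions of bound-gene sets across
  conditions, gained/lost footprint bases between conditions, and k-mer
  motif enrichment (UAG, AGGU, …) against dinucleotide-preserving shuffles.
- **Assay quantification** — percent-spliced-in ψ = (I/l_I)/(I/l_I + S/l_S)
  and Δψ (positive = higher inclusion in controls), three-primer PCR
  inclusion ratios, restriction-digest isoform fractions, ΔΔCt qPCR fold
  changes, neurite length-per-nucleus summaries, and exact small-sample
  Mann–Whitney U tests by full enumeration.
- **Synthetic data** — every input above can be simulated with the
  statistical structure the analysis assumes (correlated replicate scores,
  condition-dependent site loss, background contamination, planted motifs,
  group-structured assay tables), so the whole pipeline is testable
  without any external data.

## Worked example

```python
from clipfoot import (PipelineConfig, run_pipeline)

config = PipelineConfig(outdir="demo_run", seed=42)
manifest = run_pipeline(config)
print(manifest["stages"]["compare"]["unique_gene_counts"])
print(manifest["stages"]["quant"])
```

prints (numbers produced by this exact run):

```
{'mild': 59, 'naive': 59, 'severe': 54}
{'psi_by_group': {'case': 0.4063929932819012, 'control': 0.7021274837005347},
 'delta_psi': 0.2957344904186335,
 'fold_change_by_group': {'case': 0.52492294923051, 'control': 1.003077070189917}}
```

The default scenario simulates three replicate groups (naive, mild, severe)
in which severe disease loses half of the true binding sites: the pipeline
recovers fewer unique bound genes in severe than naive (54 < 59), the
planted group PSI values (0.70 / 0.40, so Δψ ≈ +0.30 with the
higher-inclusion-in-controls sign convention), and the planted two-fold
qPCR knockdown (case fold ≈ 0.52 relative to the control calibrator).

The same stages are available from the shell:

```bash
clipfoot simulate --seed 42 --outdir demo
clipfoot footprints demo/peaks_naive_rep1.bed --background demo/background.bed --out fp1.bed
clipfoot consensus fp1.bed fp2.bed fp3.bed --annotation demo/annotation.tsv --out consensus.tsv
clipfoot idr demo/peaks_naive_rep1.bed demo/peaks_naive_rep2.bed
clipfoot run --seed 42 --outdir demo_run
```

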