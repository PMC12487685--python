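# calmkit

Quantitative phenotyping toolkit for murine calmodulinopathy studies.

Calmodulinopathies are severe arrhythmia syndromes (long-QT,
catecholaminergic polymorphic VT) caused by heterozygous missense
mutations in one of the three calmodulin genes (*Calm1/2/3*), which
encode an identical protein. Understanding why a single mutant allele —
one of six — is so damaging requires quantifying the mutant's footprint
at every level: its share of the transcript pool, its share of the
protein pool, its turnover, and the cellular and organ-level electrical
phenotype. `calmkit` packages that analysis chain for knockin-mouse
studies of the *Calm1* p.N98S model:

| module | what it computes |
| --- | --- |
| `transcript_quant` | FPKM, allelic read fractions at a tagging variant, mutant share of the Calm transcript pool, 2^-ddCt chamber estimates |
| `protein_quant` | absolute wild-type/mutant calmodulin by stable-isotope dilution (light/heavy peak-area ratio), mutant protein fraction |
| `turnover` | cycloheximide-chase percent-remaining, exponential decay fits, proteasome-inhibitor fold changes |
| `ecg_phenotype` | signal-averaged beats, rate-correction exponent *n* (ln QT vs ln RR/RR_avg regression), QTc, arrhythmia scores, BVT incidence |
| `cellular_ep` | r50 (fraction of peak I_Ca,L remaining 50 ms after the peak) and the CDI statistic f50 = (r50,Ca − r50,Ba)/r50,Ba |
| `optical_map` | activation/APD30/50/80 maps and anisotropic conduction velocities (CV_max/CV_min) from voltage-dye movies |
| `imaging` | fibrosis fraction by red/blue channel-difference thresholding, striation spacing from intensity profiles |
| `cohort_stats` | Mendelian chi-square tests, observed/expected summaries, the \|log2FC\| > 0.5 & P < 0.05 protein filter |
| `synthetic_data` | seed-controlled generators emulating each stage's noise model, with ground truth attached |

## Worked example

The central bookkeeping question: how much of the heart's calmodulin
message comes from the mutant allele? Reads at the tagging variant give
the within-*Calm1* allelic split; RNA-Seq FPKM values give *Calm1*'s
share of the pool:

```python
from calmkit.transcript_quant import (
    AlleleCount, allele_fractions, mutant_transcript_share,
)

# heterozygous left ventricle: wild-type reads exceed mutant 2.34-fold
fr = allele_fractions(AlleleCount(ref_count=2340, alt_count=1000))
print(round(100 * fr.alt_fraction))          # 30  (% of Calm1 transcripts)

# scale by Calm1's share of the summed Calm1+Calm2+Calm3 FPKM
print(mutant_transcript_share(0.30, (34.8, 49.0, 41.4)))   # 8.3  (% of all Calm)
print(mutant_transcript_share(1.0, (34.2, 53.2, 35.7)))    # 27.8 (homozygote)
```

So the mutant message is ~8% of the pool in heterozygotes — yet
stable-isotope-dilution proteomics (`protein_quant`) shows the mutant
*protein* is the majority species, and the downstream modules quantify
the electrophysiological consequences (reduced CDI via `cellular_ep`,
APD/QTc prolongation via `optical_map` and `ecg_phenotype`).

```python
from calmkit.protein_quant import IsotopeLabel, heavy_label_mass_shift
print(heavy_label_mass_shift(IsotopeLabel(n_13c=6, n_15n=1)))  # 7.017165 (Da)
```

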