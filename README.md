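# fusloc

Quantification tools for studying nuclear retention of RNA-binding
proteins (RBPs) such as FUS, whose cytoplasmic mislocalization is a
hallmark of ALS/FTD. The package implements two measurement pipelines and
the synthetic data needed to verify them end to end:

1. **Nascent-transcript binding surface scoring.** FUS binds RNA in a
   length-dependent manner, so the pool of nascent transcripts a cell is
   transcribing sets how much FUS it can tether in the nucleus. Starting
   from HOMER `findPeaks`-style nascent RNA-seq (Bru-Seq) peak tables,
   each peak's read count *r* is normalized to 10 million total aligned
   reads, `peak_score = r × 10⁷ / N_aligned`; peaks with score < 0.1 are
   discarded; and each retained transcript of length *L* gets

   &nbsp;&nbsp;&nbsp;&nbsp;`binding_surface_score = log₂(peak_score × L)`

   Score distributions between conditions (e.g. control vs. sporadic-ALS
   iPSCs), optionally restricted to CLIP-defined RBP target genes, are
   compared by empirical CDFs and the Mann–Whitney U test, reporting the
   percent reduction of the mean relative to the control group.

2. **Per-cell nucleocytoplasmic fluorescence quantification.** From
   intensity channels plus whole-cell and nucleus label masks, the package
   computes background-adjusted integrated densities (sum of pixel
   intensities over an ROI; background mean taken from a staining-free
   ROI), the cytoplasmic-to-nuclear ratio
   `C/N = (ID_whole − ID_nuc) / ID_nuc`, DAPI-normalized totals, nuclear
   poly(A+) RNA concentration, Pearson correlation of paired per-cell
   ratios, and rank-sum / Kruskal–Wallis + Dunn comparisons across
   treatment groups.

`fusloc.simulate` generates both kinds of input with known ground truth:
peak-table pairs with a configurable multiplicative expression effect, and
fields of disk-shaped cells whose true C/N ratio is exact by construction.

## Worked example

```python
import numpy as np
from fusloc.simulate import PeakSimConfig, simulate_peak_pair, CellSimConfig, simulate_cell_image
from fusloc import peaks
from fusloc.imaging import quantify_cells

# a control/affected pair with a true 10% expression reduction
control, affected, truth = simulate_peak_pair(
    PeakSimConfig(n_transcripts=2000, effect_fraction=0.10, seed=0))
score = lambda ps: peaks.filter_peaks(peaks.score_peaks(ps))
sc, sa = score(control), score(affected)
cmp = peaks.compare_samples(sc, sa, value="peak_score")
print("retained:", len(sc), len(sa))
print("mean peak score: %.2f vs %.2f" % (cmp.mean_a, cmp.mean_b))
print("percent reduction: %.2f%%" % cmp.percent_reduction)

# synthetic cells with true C/N ratio 0.5, 5% noise, uniform background
img, _ = simulate_cell_image(CellSimConfig(
    n_cells=50, true_cn_ratio=0.5, noise_sd=5.0, background_level=10.0, seed=0))
ratios = [m.cn_ratio for m in quantify_cells(img, ["signal"])]
print("median C/N ratio: %.4f (truth 0.5)" % np.median(ratios))
```

prints

```
retained: 1978 1977
mean peak score: 133.39 vs 121.44
percent reduction: 8.96%
median C/N ratio: 0.4912 (truth 0.5)
```

The 2000 simulated transcripts nearly all clear the 0.1 score filter at
this depth; the recovered reduction of the mean peak score (8.96%)
estimates the configured 10% effect, and the per-cell quantification
recovers the true cytoplasmic/nuclear ratio to within about 2% despite
noise and a background offset (which cancels exactly through the
staining-free ROI adjustment).

The same runs are available from the shell:

```sh
fusloc simulate-peaks --n-transcripts 2000 --effect-fraction 0.10 --seed 0 --out sim/
fusloc compare-peaks --peaks-a sim/control.peaks.txt --peaks-b sim/affected.peaks.txt \
    --total-a 100000000 --total-b 100000000 --targets sim/targets.txt --out cmp/
fusloc simulate-cells --n-cells 50 --true-cn-ratio 0.5 --noise-sd 5 --out cells/
fusloc quantify-cells --input demo=cells/ --out quant/
```

Every command writes a `provenance.json` (parameters, input checksums,
stage counts) beside its outputs, and logs the record counts surviving
each filter to stderr.

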