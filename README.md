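# introscan

Detect adaptive introgression (AI) in population genomic data with a
convolutional classifier trained on simulations.

The pipeline:

1. **simulate** — generate labelled 100 kbp regions under three scenarios
   (neutral, selective sweep in the recipient, adaptive introgression from a
   donor population) for a configurable demographic model, with rejection
   sampling on the beneficial allele's final frequency and optional
   simulation rescaling (Q). A hybrid engine is used: msprime supplies the
   neutral genealogy of all panels plus the full recipient population at the
   onset of selected dynamics; an explicit forward Wright–Fisher stage then
   evolves the recipient to the present with selection, recombination and
   mutation. A DFE mode adds a deleterious mutational background (heterosis
   confounder).
2. **encode** — turn each region into a fixed-size n×m image: pooled-minor
   alleles coded 1, sites with MAF ≤ 5% and the selected site dropped, minor
   alleles counted per haplotype in m genomic bins (preserving local density
   of segregating sites), optionally collapsed to diploid genotypes, blocks
   ordered (non-donor archaic | donor | recipient | outgroup) and sorted
   within blocks by similarity to the donor's mean allele density.
3. **model** — a small CNN (input batch-norm, then k blocks of batch-norm →
   16×4×4 convolutions with 2×2 stride → leaky ReLU, then one sigmoid unit)
   trained 3 epochs with Adam on cross-entropy, outputs Pr[AI]. Implemented
   in pure NumPy (no deep-learning framework required), bitwise reproducible
   per seed.
4. **calibrate** — resample the training set to a chosen neutral:sweep:AI
   ratio (default 1:0.1:0.02) and fit a monotone calibrator (beta
   calibration by default; isotonic/Platt available) so Pr[AI] is meaningful
   under realistic class imbalance.
5. **windows / report** — slide 100 kbp windows (20 kbp step) across
   indexed VCF/BCF panels, apply site/window QC, encode, predict, rank the
   top regions (merging adjacent windows) and annotate them with genes from
   a GFF3 file.
6. **sumstats / evaluate / saliency** — U(w,x,y), Q95(w,y) and f_d baseline
   statistics with empirical p-values against the neutral null; confusion/
   precision/NPV/ROC/PR/MCC-F1 evaluation and per-(s, T_sel) prediction
   grids; input-gradient saliency maps.

## CLI

```sh
# simulate labelled regions (demographic presets: A1, A2, B)
introscan simulate --model A1 --scenario ai --n-reps 1000 --seed 1 \
    --q 20 --af-cutoff 0.25 --out sims/

# train the CNN on a directory of simulation archives
introscan train --data sims/ --out model/ --m 64 --k 5 --phased

# fit a beta calibrator for skewed class ratios
introscan calibrate --model model/ --data sims/ --ratios 1:0.1:0.02 --m 64

# scan an indexed VCF in sliding windows
introscan scan --model model/ --vcf panel.vcf.gz \
    --panel Nea=AltaiNea,VindijaNea --panel CEU=NA06984,... --panel YRI=... \
    --donor Nea --chrom-length 249250621 --m 64 --out predictions.tsv

# evaluate on the stored validation split; scenario-averaged saliency maps
introscan eval --model model/ --out eval.json
introscan saliency --model model/ --data sims/ --m 64 --out saliency.npz
```

Run configurations can also be kept in a TOML file (see
`introscan.config.load_config`); a single global seed fans out
deterministically to every stage.

## Layout

```
src/introscan/
  simulate/      demographic models + scaling, parameter draws, DFE,
                 genetic maps, the hybrid simulation engine
  encode.py      genotype-matrix construction
  model.py       CNN build/train/predict (NumPy backend in _nn.py)
  calibrate.py   class-ratio resampling, beta/isotonic/Platt calibration
  sumstats.py    U, Q95, f_d, empirical p-values
  evaluate.py    confusion counts, metrics, ROC/PR/MCC-F1, prediction grids
  saliency.py    input-gradient saliency maps
  windows.py     VCF windowing, site intersection and QC
  report.py      genome scan, top regions, GFF3 gene annotation, plots
  config.py      TOML run configuration, fixture generation
  cli.py         `introscan` command-line interface
```
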