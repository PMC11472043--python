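# guidepost

Probabilistic CRISPR/Cas9 off-target activity prediction.

Genome-wide off-target detection assays (CHANGE-seq, GUIDE-seq, SITE-seq)
report cleavage read counts that are extremely sparse and overdispersed:
most putative off-target sites show zero reads — some genuinely inactive,
some active but below assay sensitivity ("technical zeros") — while a few
sites carry very large counts.  A point score cannot express how much of
that spread is uncertainty.  guidepost instead predicts, for every
sgRNA–target site, a full **zero-inflated negative binomial (ZINB)**
posterior over read counts

```
P(y | x_s, x_p) = ZINB(y; π, μ, θ) = π δ₀(y) + (1 − π) NB(y; μ, θ),
NB(y; μ, θ)      = Γ(y+θ)/(Γ(θ) y!) · (μ/(μ+θ))^y · (θ/(μ+θ))^θ
```

where π is the zero-inflation weight, μ the negative-binomial mean and θ
the dispersion.  The three parameters are produced by a two-branch neural
network f_w(x_s, x_p):

* **sequence branch** — the sgRNA–target interface encoded as a 6×23 bit
  matrix (OR-merged one-hot rows A/T/G/C plus a two-bit mismatch-direction
  channel), processed by two convolution stages (128 kernels of width 1,
  32 of width 3, batch-normalized), max pooling (2/2) and a bi-directional
  LSTM (128 hidden units per direction);
* **descriptor branch** — a 4×23 matrix of normalized physical context
  descriptors (block-decomposition sequence complexity, GC content,
  nucleosome occupancy and affinity) computed on 147-bp windows (73-bp
  flanks) around each site position, processed by one convolution stage.

Both branches are projected to 128-d, concatenated, and read out through a
64-unit layer into three heads (sigmoid for π, exponential for μ and θ).
Training minimizes the ZINB negative log likelihood; ZIP, plain-NB and
Poisson heads are available as ablation baselines.  Because the descriptor
branch sees the genomic context, two sites with identical sequences at
different loci get different posteriors.

From the per-site posterior the package derives the outputs a guide
designer needs: the expected activity (point prediction), the coefficient
of variation (per-site uncertainty), one-sided 95% credible intervals with
the lower bound pinned at zero activity, and a randomized-PIT calibration
diagnostic.  Per guide, the **aggregate specificity score**

```
y_sg = log( Σᵢ yⁱ_offtarget / y_ontarget )
```

is sampled site-by-site into a full Monte-Carlo distribution (lower =
more specific), so guides with similar mean specificity can still be
separated by their spread.

A synthetic-data module generates genomes, site tables and ZINB counts
with known ground truth, making the entire pipeline testable offline.

## Worked example

`python examples/03_train_and_score.py` simulates a 20-guide study, trains
the compact ZINB head and scores held-out sites:

```
2020 sites, zero fraction 0.43
best monitored NLL/site: 4.444 (epoch 75)
  site_id       pi         mu    theta       mean       cv  ucb95  mismatches
g018s0002 0.197244 687.565508 0.552425 551.947623 1.581930 2316.0           2
g018s0003 0.206785 458.977923 0.927750 364.068097 1.273700 1301.0           1
...
Spearman(true mean, predicted mean) on held-out sites: 0.890
```

Each row is one sgRNA–target site: `pi/mu/theta` are the predicted ZINB
parameters, `mean = (1−π)μ` the expected read count, `cv` the coefficient
of variation of the posterior, and `ucb95` the 95% upper credible bound
(the lower bound is 0 by convention for off-targets).  The final line
shows that the ranking of the predicted expected activity recovers the
generator's true per-site means.  The other example scripts cover the
interface encoding (`01`), the ZINB machinery (`02`), aggregate
specificity (`04`) and calibration diagnostics (`05`).

A command-line interface wraps the same pipelines:

```sh
guidepost simulate --n-guides 20 --sites-per-guide 100 --seed 1 --out-prefix toy
guidepost train --sites toy.sites.tsv --genome toy.fa --head zinb \
    --lr 1e-3 --epochs 80 --compact --seed 1 --out model.npz
guidepost score --checkpoint model.npz --sites toy.sites.tsv --genome toy.fa --out scores.tsv
guidepost aggregate --checkpoint model.npz --search offtargets.tsv \
    --on-target on.tsv --genome toy.fa --n-samp 1000 --seed 1 --out agg.tsv
guidepost calibrate --checkpoint model.npz --sites toy.sites.tsv --genome toy.fa --out cal.tsv
```

## Layout

- `src/guidepost/encoding.py` — 6×23 interface encoding
- `src/guidepost/descriptors.py` — 147-bp context descriptors (4×23)
- `src/guidepost/distributions.py` — ZINB/ZIP/NB/Poisson closed forms and samplers
- `src/guidepost/nn/` — autodiff engine and layers
- `src/guidepost/network.py` — the fusion regressor and its training loop
- `src/guidepost/uncertainty.py` — intervals, CV, calibration
- `src/guidepost/aggregate.py` — genome-wide specificity distributions
- `src/guidepost/simulate.py` — synthetic genomes/sites/counts with ground truth
- `src/guidepost/io.py`, `src/guidepost/cli.py` — tables, checkpoints, CLI

See `docs/methods.md` for the modeling choices and their rationale.
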