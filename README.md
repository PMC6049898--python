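# cpiem

Detection of cooperatively bound transcription-factor (TF) pairs from
ChIP-seq peak intensities alone.

## The problem

When two TFs, a *target* A and a *partner* B, bind nearby sites, B can raise
A's effective binding affinity (cooperative binding). The gold standard for
finding such regions is a knockout experiment: ChIP-seq of A before and
after B is genetically deleted — A's peak disappearing or weakening marks a
cooperatively bound region. Knockout data are rarely available, though.
`cpiem` implements a sequence-independent detector (CPI-EM) that needs only
the two wild-type ChIP-seq peak files, exploiting one empirical regularity:
at cooperatively bound regions the target TF is, on average, more weakly
bound than at non-cooperatively bound regions.

## The model

For every region where a peak of A overlaps a peak of B by at least one
base pair, the intensity pair (x, y) is modelled as a two-component
mixture with independent axes within each component:

```
p(x, y) = w · f_c(x) g_c(y) + (1 − w) · f_n(x) g_n(y)
```

Each marginal is a two-parameter Log-normal (Gamma and Gaussian are
available for comparison), giving eight marginal parameters plus the
cooperative weight w — nine in total, fitted by expectation maximization.
The component with the lower target-axis mean is identified as cooperative.
Bayes' formula converts the fit into a per-region posterior probability of
cooperative binding,

```
P(coop | x, y) = w f_c(x) g_c(y) / [ w f_c(x) g_c(y) + (1 − w) f_n(x) g_n(y) ],
```

and regions with posterior > α are called cooperative. FPR(α)/TPR(α) sweeps
give ROC curves; auROC summarizes detector quality (0.5 = chance).

The package also provides: knockout-based ground-truth labeling (peak loss,
or significant peak-rank changes against a replicate-derived null), the
peak-summit-distance baseline detector, the cooperative index
Δ = (I′ − I)/I for scoring external occupancy-model predictions, a
PWM-based filter that removes indirectly bound (tethered) peaks using a
negative-control motif-score threshold, evaluation metrics (ROC/PR,
Wilcoxon rank-sum, mutual information, Pearson R²), and a synthetic-data
generator that emulates the full knockout experiment with known labels.

## Worked example

Simulate a labelled experiment (1500 doubly bound regions, cooperative
weight 0.4, knockout loss probability 1) and run the detector:

```
$ python -c "
from cpiem.simulate import SimulationConfig, simulate_experiment, write_experiment
cfg = SimulationConfig(n_pairs=1500, p_loss=1.0, genome_length=1500*900, seed=42)
write_experiment(simulate_experiment(cfg), 'demo')"

$ cpiem detect --target demo/target_wt_rep1.narrowPeak \
               --partner demo/partner.narrowPeak \
               --out-pairs demo/pairs.tsv --out-model demo/model.txt \
               --alpha 0.5 --seed 42
INFO paired 1500 target x 1500 partner peaks -> 1500 overlapping pairs
INFO fit: weight=0.4042 logL=-9178.12 iterations=53 converged=True
INFO wrote 1500 pairs (587 cooperative at alpha=0.5)

$ cpiem evaluate --scores demo/pairs.tsv --truth demo/truth.tsv
auROC	0.9757524755985378
auPR	0.9676928945908702
```

The fitted weight (0.404) recovers the generating cooperative fraction
(0.4); the posterior ranks regions against the knockout-derived truth with
auROC 0.98. The first data line of `demo/pairs.tsv`,

```
chrSim  404  583  t0  p0  0.9210  9.6670  88  0.99994  cooperative
```

is a weak target peak (x ≈ 0.92) overlapping a strong partner peak — the
signature the model associates with cooperative binding, hence the
posterior near 1.

The same workflows are available as library functions
(`cpiem.fit_mixture_em`, `cpiem.posterior_coop`,
`cpiem.label_from_knockout`, ...) and as the other subcommands
(`validate`, `distance`, `filter-indirect`, `simulate`).

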