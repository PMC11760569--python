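# apoetraj

Weight-trajectory discovery in aging humanized-APOE mouse colonies.

Longitudinal body weight is one of the cheapest phenotypes a colony collects,
and in humans weight change is a documented correlate of Alzheimer's-disease
risk: midlife gain and late-life loss both precede diagnosis. `apoetraj`
asks whether the same heterogeneity hides inside an aging mouse colony that
a single mean growth curve would average away. It is written for
biostatisticians and phenotyping cores who have a long-format table of
weighings (mouse id, sex, APOE genotype, dates, weight) plus optional
survival, plasma Aβ and EchoMRI tables, and want reproducible trajectory
groups with validation statistics.

## The model

An autoregressive hidden Markov model (AHMM) over each mouse's visit
sequence. A hidden state `H_t ∈ {1,…,N}` (N = 10 by default) evolves by a
Markov chain with transition matrix `A = [a_ij]`; each visit emits age
(Gaussian), sex and genotype (categorical), and weight

```
w_t | H_t = i  ~  Normal(α_i + δ_i·[male] + φ_i·w_{t−1}, σ²_i)
```

— autoregressive on the previous recorded weight with a state-specific male
offset (the sex–weight interaction). Irregular spacing needs no imputation:
each measurement is one Markov step and age is an observed emission.
Fitting is EM (Baum–Welch) with closed-form M-steps, 10 random restarts,
and exact log-space forward–backward inference (the chain reduction of
junction-tree inference). States with self-transition `a_ii > 0.3` are
*ending* states; mice are grouped by the ending state occupied at their
final visit, and each group's phenotype (gain / loss / stable) is the
percent weight change of its mean curve from 12 months of age to the end of
the trajectory. Groups are then validated with Kaplan–Meier / log-rank
survival analysis, chi-square composition tests and Welch t-tests on
biomarker panels.

A synthetic-colony generator with known ground truth (five archetype states,
genotype-coupled entry, state-dependent mortality and biomarkers) makes the
whole pipeline runnable and testable with no external data.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
simulated colony (here scaled to 400 mice; drop the flags for the full
1,196-mouse, 10-restart protocol):

```
$ python analysis/01_simulate_colony.py --n-mice 400 --seed 1
simulated 400 mice, 4953 weight rows (12.4 visits/mouse)
deaths: 91 natural, 194 sacrificed, 115 alive at window end
biomarker panel: 310 mice sampled at 12-14 months

$ python analysis/02_preprocess.py
400 mice loaded -> 333 retained (4090 datapoints); excluded by reason:
{'breeder': 15, 'too_few_points': 12, 'rapid_loss': 40}
sex: 47% female / 53% male; genotypes: E3/3 28%, E3/4 32%, E4/4 39%

$ python analysis/03_fit_ahmm.py --quick
fitted 10 states on 333 mice (4090 visits)
restart log-likelihoods: -22036, -22310, -22319; kept restart 0 (LL -22036)

$ python analysis/04_trajectories.py
ending states (10 of 10): A, B, C, D, E, F, G, H, I, J
333 mice grouped, 0 unassigned (0%)
state  n  percent_change    phenotype
    A 35       24.429586         gain
    B 28      -12.025955         loss
    ...

$ python analysis/05_validate.py
survival: log-rank chi2=209.5 (df=4), p=3.35e-44 over 143 mice
  median survival (months): A=16.3, D=16.6, F=28.2, H=None, I=None
genotype composition across trajectories: chi2=295.6 (df=18), p=3.78e-52
```

Reading the output: preprocessing removed breeders, mice with >20% monthly
weight loss and series shorter than 3 points; the fitted states (relabeled
A–J by ascending weight level) each kept a self-transition above 0.3, so
every mouse lands in a trajectory group; groups split into gain, loss and
stable phenotypes by their percent change from 12 months; and the validation
battery confirms the groups differ in survival (mice in the early-loss
groups A and D die around 16 months, median) and in genotype composition.
Every stage is also available as a library call (`apoetraj.run_pipeline`)
and as subcommands of the `apoetraj` CLI (`simulate`, `preprocess`, `fit`,
`run-all`, `report`).

## Layout

```
src/apoetraj/      ahmm.py (model + EM), colony.py (I/O + exclusions),
                   trajectories.py, validation.py, synthetic.py,
                   pipeline.py, cli.py
analysis/          numbered narrative drivers (simulate → validate)
tests/             pytest suite incl. enumeration/lifelines oracles
docs/methods.md    model, assumptions, defaults, limitations
```
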