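# neutroskin

Analysis toolkit for dose-dependent tissue response to fast-neutron
irradiation: a multi-event microdosimetry model linking absorbed dose and
target-site size to the probability of multiple ionization events, plus the
complete transcriptomic/qPCR/densitometry statistics pipeline of an *in
vivo* mouse-skin irradiation study, exercised end-to-end on synthetic data
with planted ground truth.

## Who this is for

Radiation biologists and bioinformaticians who need (a) quick, calibrated
multi-event probability scans for high-LET fields (14 MeV neutrons in the
default setup) and (b) a reproducible, tested implementation of the classic
two-channel microarray workflow — spot QC, global lowess normalization,
fold-change + t-test gene selection, UPGMA clustering — together with ΔΔCT
relative quantification and ANOVA/Tukey group statistics.

## The models

**Multi-event microdosimetry.** Energy deposition in a micrometric site is
a sequence of independent events (secondary charged-particle traversals).
At absorbed dose *D* the event count *N* is Poisson with mean

```
n = D / z̄_F,        z̄_F = (4/π)·0.1602 · y_F / (ρ d²)   [Gy]
```

where *z̄_F* is the frequency-mean specific energy per event in a
unit-density sphere of diameter *d* (µm) and *y_F* the frequency-mean
lineal energy (keV/µm). The probability that a site experiences two or more
events is

```
F₂ = P(N ≥ 2) = 1 − (1 + n) e^(−n),
```

and *n* scales as *D·d²* across doses and site sizes. When a measured *y_F*
is not available, the model is calibrated from a single known (*D*, *d*,
*F₂*) reference point. The full multi-event specific-energy distribution is
the compound-Poisson mixture `f(z) = Σ_k e^(−n) n^k/k! · f₁^(*k)(z)` of
k-fold convolutions of the single-event spectrum, with a point mass
e^(−n) at z = 0, cross-checked against a Monte-Carlo sampler.

**Expression pipeline.** Two-channel arrays are filtered (flagged,
saturated and low-signal spots), normalized by a global lowess fit of
M = log₂(Cy5/Cy3) on A = ½·log₂(Cy5·Cy3), and aggregated over replicates.
A gene is called modulated when |mean log₂ ratio| ≥ log₂(1.5) in at least
two conditions and a Student t-test of the replicate ratios against zero
gives p < 0.05 in each passing condition. Selected genes are clustered by
UPGMA (Euclidean distance, average linkage) and exported as a ±3 log₂
heat matrix. qPCR tables are quantified per mouse by ΔΔCT against a
housekeeping reference and sham calibrator; group differences use one-way
ANOVA with Tukey HSD at p < 0.05.

## Worked example

```
$ microdose scan --doses 0.2,1.0 --diameters 0.5,1,2,7 --calibrate-ref 0.2:1.0:0.003
dose_gy  diameter_um  n         F2
0.2      0.5          0.019883  0.000195
0.2      1.0          0.079534  0.003000
0.2      2.0          0.318135  0.041051
0.2      7.0          3.897150  0.900589
1.0      0.5          0.099417  0.004626
1.0      1.0          0.397668  0.060928
1.0      2.0          1.590673  0.472051
1.0      7.0          19.485749 1.000000
```

Calibrated so that a 1 µm site at 0.2 Gy has F₂ = 0.3%, the scan shows the
multi-event probability rising to 6.1% at 1 Gy in the same site, and from
4.1% to 47% in a 2 µm site — a strong dose contrast exactly in the 1–2 µm
(chromosome-territory) size range — while sub-0.5 µm sites stay below 0.5%
at both doses and a cell-sized 7 µm site sees multiple events essentially
always.

The synthetic study pipeline is driven by the numbered scripts:

```
$ python analysis/02_simulate_study.py     # 8 × 28,000-spot arrays + qPCR + densitometry
$ python analysis/03_select_and_cluster.py
19704 genes passed spot QC in every replicate; 8 selected as modulated
(>= 1.5-fold in >= 2 conditions, P < 0.05)
recovery among QC-surviving two-fold planted genes: 100%; false-positive
rate among nulls: 0.00%
```

i.e. every planted ≥2-fold co-regulated gene that survived spot QC was
selected, with no false positives among ~19,600 null genes, and
`analysis/04_validation_and_groups.py` reports an array↔qPCR log₂
fold-change correlation of R = 0.995 on the simulated validation genes.
The same end-to-end run is available as `neutroskin report --outdir DIR`.

## Layout

```
src/neutroskin/      library: microdosim, synthetic, arrays, clustering,
                     group_stats, config, pipeline, cli
analysis/            numbered narrative drivers writing to results/
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      model assumptions, parameter choices, limitations
```
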