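# genefabric

Expression variability, coordination and pair-wise relevance analysis of
replicated expression data.

## The problem

Differential-expression analysis asks only whether a gene's *average* level
changes between conditions.  Profiling the same condition in several
biological replicates — independently cultured dishes of the same system,
each exposed to slightly different micro-environments — supports two more,
mutually independent readouts per gene:

* **how tightly its abundance is controlled** (variability across
  replicates), and
* **which other genes it is coordinated with** (co-variation across
  replicates), the molecular footprint of "transcriptomic stoichiometry":
  genes of a functional pathway must be kept in definite mutual
  proportions.

`genefabric` implements this analysis for redundant-probe array data
(several spots per transcript), from spot-level filtering and
normalization to signed coordination networks.  It was built for
neuroscience-style designs — e.g. sensory neurons electrically stimulated
with different action-potential patterns, 4 replicates per condition — but
nothing in it is specific to neurons.

## The statistics

**REV (Relative Expression Variability).**  For transcript *i* probed by
spots *k* = 1..*R<sub>i</sub>* with per-spot replicate mean μ<sub>ik</sub>
and sample SD s<sub>ik</sub>:

    REV_i = C(R_i) · 100 · sqrt( (1/R_i) Σ_k (s_ik / μ_ik)² )

the chi-square mid-interval estimate of the pooled CV at 4R<sub>i</sub>−1
degrees of freedom; the correction C(R) shrinks toward 1 as redundancy
grows.  Low REV = tight homeostatic control.

**Coordination.**  Pearson ρ between two genes' (log₂) per-replicate
levels, tested two-tailed at df = 4R − 2 (R = number of spots probing each
gene).  At df = 2 only |ρ| > 0.95 is significant at p < 0.05; two spots per
gene give df = 6 and |ρ| > 0.71.  Pairs are classified POS / NEG /
IND (near-zero ρ) / UNCLASSIFIED, and POS↔NEG flips between conditions are
reported as **coordination reversals**.

**PWR (pair-wise relevance).**

    PWR_ij = (μ_i μ_j / μ̄²) · ρ_ij² · (REV̄² / (REV_i REV_j))

ranks pairs that are highly expressed, strongly coordinated and tightly
controlled relative to the condition-wide ("fabric") means μ̄ and REV̄.

## Worked example

`examples/worked_example.py` — three replicate vectors with the same mean
1.0:

```
G1: mean=1.00  CV=4.7%
G2: mean=1.00  CV=4.5%
G3: mean=1.00  CV=41.6%
rho(G1,G2) = -0.985  (tightly anti-coordinated)
rho(G2,G3) = 0.986  (tightly coordinated)
critical |rho| at df=2: 0.95
G1-G2 -> NEG
G2-G3 -> POS
critical |rho| at df=6: 0.71
```

G1 and G2 are equally stable (~5% CV) while G3 is an order of magnitude
noisier (~42%) — yet G2 is near-perfectly anti-coordinated with G1 and
coordinated with G3.  Level, variability and coordination are three
independent views of the same genes; the df = 2 row shows why both
correlations clear the p < 0.05 bar.

The other scripts in `examples/` each exercise one capability end to end:
`simulate_and_coordinate.py` (synthetic study → filter → normalize →
classify all pairs), `pwr_landscape.py` (cross-set PWR matrix and top
"medallion" pairs), `coordination_reversals.py` (POS↔NEG flips and network
diffs between two conditions), `full_pipeline.py` (one-config orchestrated
run with manifest).  A thin CLI mirrors the stages:
`genefabric simulate | filter | normalize | rev | coordinate | run`.

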