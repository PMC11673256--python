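# cadnet

Co-occurrence analysis of diagnoses and comorbidities in coronary artery
disease (CAD) cohorts: detection rates and sex-stratified odds ratios,
weighted co-occurrence networks, community structure (Louvain modularity
and map-equation description length), and edge-weight-filter sensitivity
analysis.

Hospitalized CAD patients rarely present with one condition. Which
diagnoses (unstable angina, myocardial infarction, severity classes) and
comorbidities (hypertension, dyslipidemia, diabetes, …) travel together,
and which act as hubs, matters for integrated management — and can be read
off electronic medical records by treating each hospitalization as one
observation of a set of canonical clinical terms. `cadnet` implements that
pipeline for epidemiologists and health-data analysts: from raw term
normalization through networks and community metrics, with a calibrated
synthetic-cohort generator standing in for record-level data that cannot
be shared.

## The statistics at the core

* **Detection rate** of term *t*: DR(t) = 100 · N_t / N (% of records
  containing *t*), with Wilson CIs.
* **Sex association**: odds ratio of the 2×2 sex-by-condition table with
  the Haldane–Anscombe correction applied to every cell,
  OR = ((a+½)(d+½))/((b+½)(c+½)), Wald 95% CI on the log scale from the
  corrected cells; INF/ZERO sentinels when one sex has zero events.
* **Co-occurrence networks**: nodes are terms (frequency = record count),
  an edge's weight counts the records in which both endpoints appear;
  monopartite per category or bipartite diagnosis×comorbidity.
* **Community structure**: weighted Newman–Girvan modularity
  Q = Σ_c [W_c/W − (S_c/2W)²] maximized Louvain-style, and the two-level
  map equation L(M) = q·H(Q) + Σ_i p_i·H(Pⁱ) in bits, minimized by seeded
  greedy search — both implemented in-package and tested against
  brute-force and closed-form oracles.
* **Sensitivity**: all metrics recomputed under rising edge-weight
  thresholds; hub stability tracked across the sweep.

## Worked example

```python
from cadnet import (
    reference_cohort_config, generate_cohort, build_monopartite,
    network_report, threshold_sweep, odds_ratio, ContingencyTable2x2,
)

# OR for myocardial infarction from the published sex-stratified counts
# (23 of 138 males, 5 of 57 females):
r = odds_ratio(ContingencyTable2x2(23, 115, 5, 52))
print(f"OR {r.estimate:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")
# -> OR 1.94 (95% CI 0.73-5.20)

# a 195-record synthetic cohort calibrated to the published margins
cohort = generate_cohort(reference_cohort_config(seed=0))
net = build_monopartite(cohort, "comorbidity")
report = network_report(net, seed=0)
print(report.n_nodes, report.n_edges, report.hub)
# -> 20 150 Hypertension
```

The OR line reproduces the published value exactly because the corrected
2×2 statistic is fully determined by the printed counts. The network line
is a synthetic draw: node/edge counts vary by seed, but hypertension sits
at the top of the weighted-degree ranking because it carries the highest
prevalence and frailty loading in the calibrated generator — the same hub
role it plays in the real cohort.

The numbered scripts under `analysis/` run the full study pipeline on a
synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py      # 195-record calibrated cohort
python analysis/02_descriptive_statistics.py
python analysis/03_build_networks.py       # networks + pair/partner tables
python analysis/04_network_metrics.py
python analysis/05_threshold_sensitivity.py
```

A `cadnet` CLI exposes the same stages (`simulate`, `normalize`, `stats`,
`network`, `metrics`, `sensitivity`, `run`); see `cadnet --help`.

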