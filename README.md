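# telotype

Assessment of telomere maintenance mechanisms (TMM) in neuroblastoma from
whole-genome sequencing, RNA-seq and laboratory assay data.

High-risk neuroblastomas stabilize their telomeres either through
telomerase activation (via *MYCN* amplification, *TERT* rearrangement or
high *TERT* expression) or through the recombination-based alternative
lengthening of telomeres (ALT) pathway; tumors without either mechanism
follow a more benign course. No single assay detects ALT reliably, so a
diagnostic call has to integrate genomic, transcriptomic and assay-level
evidence. `telotype` implements that integration as a tested pipeline:

* **Telomere content (TC)** — a WGS read is telomeric when it contains
  ≥ 4 t-type repeats (TTAGGG or its reverse complement CCCTAA, summed);
  content is telomeric reads per million total reads, reported as the
  tumor/normal ratio (or tumor-only when no matched normal exists).
* **Telomere variant repeats (TVR) and singletons** — NNNGGG hexamers
  counted in the telomeric repeat frame; a *singleton* is
  (TTAGGG)₃–NNNGGG–(TTAGGG)₃. Per-variant singleton rates are compared
  as log₂(tumor rate / normal rate / TC ratio); TTTGGG and TGAGGG
  singletons are depleted in ALT⁺ neuroblastoma.
* **Telomere insertions** — discordant pairs (one telomeric mate, one
  uniquely mapped mate outside telomeric/centromeric exclusion regions)
  screened in 1 kb windows (≥ 3 tumor pairs, 0 normal pairs), refined to
  breakpoints by clustered telomeric soft clips (≥ 15 bp, ≥ 2 repeats,
  start ± 1 bp, ≥ 2 reads) and an automated reference-context filter.
* **TERRA** — telomeric repeat-containing RNA, counted per common TVR
  (≥ 4 copies per read) in reads per million; elevated in ALT⁺ tumors.
* **Assay quantification** — mean telomere restriction fragment
  `mean TRF = Σ(ODᵢ·Lᵢ)/Σ(ODᵢ)` from Southern-blot densitometry;
  C-circle assay calls under threshold th₁ (≥ 5 % of the CHLA-90
  reference) or th₂ (≥ 20 % and ≥ 4× the polymerase-free AUC); a
  two-component Gaussian-mixture threshold separating high from low
  log₂ *TERT* expression at ≥ 95 % posterior (cohort constant: 7.58).
* **TMM classification** — strict rule first (TEL⁺ / ALT⁺ / TMM⁻ /
  ambiguous from MNA, *TERT* RA, *TERT* expression, APB, CCA), then
  evidence-weighted resolution of ambiguous cases using ATRX status,
  TC ≥ 1.22, TRF ≥ 9.01 kb, TERRA, singleton depletion and insertions;
  plus ROC/AUC with Youden-threshold proposal, logistic combination of
  predictors, and Kruskal–Wallis/Dunn subgroup statistics.
* **Synthetic data** — seeded generators for every input (WGS pairs
  with planted telomeric fractions and insertions, RNA with planted
  TERRA, cohort tables around the observed subgroup means,
  densitometry lanes), each with a truth record.

## Worked example

Simulate a 61-sample cohort at the observed subgroup means and run the
stepwise workflow:

```python
from telotype import SimConfig, simulate_cohort_table, run_workflow
from telotype.workflow import reproduce_cohort_statistics

cohort, truth = simulate_cohort_table(SimConfig(seed=1))
report = run_workflow(cohort)
print(report.counts)
# {'TMM_neg': 15, 'ambiguous': 2, 'ALT_pos': 13, 'TEL_pos': 31,
#  'n_samples': 61, 'n_resolved': 5}

stats = reproduce_cohort_statistics(cohort)
print(round(stats["strict_unambiguous_percent"], 1))  # 91.8
print(round(stats["tc_auc"], 3))                      # 0.998
print(round(stats["tc_youden_threshold"], 2))         # 2.15
```

Five samples were ambiguous under the strict rule (the generator flips
one APB/CCA/marker flag in ~10 % of samples, as in real cohorts); the
evidence-weighted resolution recovered three of them and two remained
ambiguous for lack of auxiliary evidence. Telomere content separates
ALT⁺ from the rest almost perfectly on this draw (AUC 0.998), and the
proposed Youden threshold (2.15 here) lands between the TEL⁺/TMM⁻
means (~0.8–0.9) and the ALT⁺ mean (~6).

The same operations are exposed on the command line:

```bash
telotype simulate --preset wgs --seed 7 --out-prefix sim
telotype content --tumor sim_tumor.sam --normal sim_normal.sam
telotype workflow --cohort cohort.tsv --json-out report.json
```

Exit codes: 0 success, 2 input error, 3 configuration error.

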