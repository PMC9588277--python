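"""A complete four-condition comparison study.

Runs the whole pipeline — simulated NEMA scans and point sources for the
NC / RM / TOF / RM+TOF presets, all metrics, Friedman + Dunn / Tukey /
paired-t statistics — and prints the significant findings.
"""

import petiq as pq

config = pq.RunConfig(n_scans=3, base_seed=1)
results = pq.run_full_study(config, "study_output")

findings = results["findings"]
print(f"{len(findings)} comparisons; significant at alpha = {config.alpha}:")
sig = findings[findings.significant]
for _, row in sig.iterrows():
    print(f"  {row.metric:8s} {row.detail:16s} {row.comparison:28s} "
          f"p = {row.p:.2e}")

auc = results["nema"]["nps_auc"].groupby("condition").auc_mm.mean()
print("\nmean NPS AUC (mm) per condition:")
print(auc.to_string(float_format=lambda v: f"{v:.4f}"))
print("\nTables + manifest in study_output/; "
      "verify with: petiq verify --results-dir study_output")
# Expected pattern: resolution modeling shifts FWHM significantly (paired t),
# while RC differences between conditions mostly stay non-significant with
# only three replicate scans.
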