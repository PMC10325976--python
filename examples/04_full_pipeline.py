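"""The full pipeline on generated inputs: filter -> fit -> classify -> compare.

Writes synthetic variant and cohort tables to a temporary directory, runs the
pipeline and prints the report highlights. Equivalent to `moyastrat demo`.
"""

import tempfile
from pathlib import Path

from moyastrat import (
    RunConfig, gen_cohort, gen_variant_scores, paper_default_configs,
    run_pipeline, write_cohort_table, write_variant_table,
)

score_cfg, cohort_cfg = paper_default_configs()

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_variant_table(gen_variant_scores(score_cfg), tmp / "variants.tsv")
    write_cohort_table(gen_cohort(cohort_cfg), tmp / "cohort.tsv")

    report = run_pipeline(RunConfig(
        variants_path=str(tmp / "variants.tsv"),
        cohort_path=str(tmp / "cohort.tsv"),
        out_dir=str(tmp / "report"),
    ))

    print("tier counts:", report.tier_counts)
    print("cutpoints:  CADD", round(report.fits["cadd"]["cutpoint"], 2),
          " VIPUR", round(report.fits["vipur"]["cutpoint"], 3))
    print("cohort:", report.cohort_summary)
    print("inheritance:", report.inheritance)
    for t in report.tests:
        if t["label"] in ("carrier_by_diagnosis", "age_at_onset_months",
                          "artery_PCA", "ischemic_burden"):
            print(f"  {t['label']:24s} p = {t['p_value']:.4g}")
    print("\nReport files (report.json, tier_calls.tsv, tests.tsv, fits.json)")
    print("were written to the run's output directory.")
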