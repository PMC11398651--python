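"""Grade classification from the reproducible feature sets.

For each (observer, phase) with a nonempty intra-phase reproducible set:
group descriptive statistics with rank-sum p-values, then the modelling
protocol — stratified split, SMOTE balancing, treebag RFE (max 3 features),
boosted trees — evaluated on the held-out patients. A 39-patient cohort is
simulated here so the 29/10 split of the full protocol applies. Writes
results/descriptive_statistics.csv and results/model_reports.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from dcect_radiomics.phantom import build_cohort
from dcect_radiomics.pipeline import extract_cohort_table
from dcect_radiomics.concordance import (intra_phase_reproducible,
                                         prune_correlated, PHASES)
from dcect_radiomics.grading import run_grading_pipeline, descriptive_statistics
from common import RESULTS, GRADE_FRACTIONS, SEED, study_spec


def main():
    cases, _ = build_cohort(39, study_spec(), GRADE_FRACTIONS, seed=SEED)
    table = extract_cohort_table(cases)
    grades = pd.Series({c.patient_id: c.grade for c in cases})
    stats_frames, reports = [], {}
    for rad in ("R1", "R2"):
        t = table.radiologist(rad)
        for phase in PHASES:
            feats = intra_phase_reproducible(t, phase, 0.90)
            if not feats:
                print(f"{rad} {phase}: no reproducible features, skipped")
                continue
            mat = t.patient_matrix(phase, feats)
            kept = prune_correlated(mat, 0.90) if len(feats) >= 2 else feats
            df = descriptive_statistics(mat[kept], grades)
            df.insert(0, "radiologist", rad)
            df.insert(1, "phase", phase)
            stats_frames.append(df)
            rep = run_grading_pipeline(mat[kept], grades, 29, 10, seed=SEED)
            reports[f"{rad}_{phase}"] = rep.to_dict()
            print(f"{rad} {phase:5s}: {len(kept):3d} candidate features -> "
                  f"model on {rep.selected_features} | AUC "
                  f"{rep.auc if rep.auc is not None else 'n/a'} "
                  f"sens {rep.sensitivity:.2f} spec {rep.specificity:.2f}")
    RESULTS.mkdir(exist_ok=True)
    pd.concat(stats_frames, ignore_index=True).to_csv(
        RESULTS / "descriptive_statistics.csv", index=False)
    (RESULTS / "model_reports.json").write_text(json.dumps(reports, indent=1))


if __name__ == "__main__":
    main()
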