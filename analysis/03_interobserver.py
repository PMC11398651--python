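"""Inter-observer reproducibility: Dice overlap and per-phase CCC analysis.

Reads results/feature_table.csv (run 02 first), computes Lin's CCC between
the two observers for every feature within each contrast phase, flags
features with min CCC >= 0.90, then Spearman-prunes the reproducible sets.
Writes results/interobserver_{phase}.csv and a summary.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

from dcect_radiomics.tables import FeatureTable
from dcect_radiomics.concordance import (interobserver_reproducible,
                                         prune_correlated, PHASES)
from common import RESULTS


def main():
    table = FeatureTable.from_csv(RESULTS / "feature_table.csv")
    t1, t2 = table.radiologist("R1"), table.radiologist("R2")
    summary = {}
    for phase in PHASES:
        rep = interobserver_reproducible(t1, t2, phase, cutoff=0.90)
        rep.to_frame().to_csv(RESULTS / f"interobserver_{phase}.csv")
        feats = rep.reproducible_features()
        kept = (prune_correlated(t1.patient_matrix(phase, feats), 0.90)
                if len(feats) >= 2 else feats)
        summary[phase] = {"reproducible": len(feats), "non_correlated": len(kept),
                          "features": kept}
        print(f"{phase:5s}: {len(feats):3d}/127 features reproducible between "
              f"observers (CCC >= 0.90); {len(kept)} remain after pruning")
    (RESULTS / "interobserver_summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
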