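"""Inter-sequence and intra-phase reproducibility for each observer.

Builds the 16x16 pairwise matrix of reproducible-feature counts over the
selected sequences, reports its off-diagonal median/range, and lists the
features reproducible across every within-phase comparison. Writes
results/pairwise_counts_{rad}.csv, results/intraphase.json and heat-map
figures under scratch/figures.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np

from dcect_radiomics.tables import FeatureTable
from dcect_radiomics.concordance import (pairwise_sequence_matrix,
                                         intra_phase_reproducible, PHASES)
from common import RESULTS, SCRATCH


def main():
    table = FeatureTable.from_csv(RESULTS / "feature_table.csv")
    figdir = SCRATCH / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    intra = {}
    for rad in ("R1", "R2"):
        counts, _ = pairwise_sequence_matrix(table.radiologist(rad), 0.90)
        counts.to_csv(RESULTS / f"pairwise_counts_{rad}.csv")
        off = counts.values[~np.eye(len(counts), dtype=bool)]
        print(f"{rad}: pairwise reproducible counts "
              f"median {np.median(off):.0f}, range {off.min()}-{off.max()} of 127")

        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(counts.values, cmap="viridis")
        ax.set_xticks(range(len(counts)), counts.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(counts)), counts.index, fontsize=6)
        fig.colorbar(im, label="reproducible features")
        fig.tight_layout()
        fig.savefig(figdir / f"pairwise_counts_{rad}.png", dpi=120)
        plt.close(fig)

        intra[rad] = {}
        for phase in PHASES:
            feats = intra_phase_reproducible(table.radiologist(rad), phase, 0.90)
            intra[rad][phase] = feats
            print(f"  {rad} {phase:5s}: {len(feats):3d} features reproducible "
                  f"across all within-phase comparisons")
    (RESULTS / "intraphase.json").write_text(json.dumps(intra, indent=1))
    print(f"heat maps under {figdir}")


if __name__ == "__main__":
    main()
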