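"""Summarise the screen into features and WT-referenced scores.

Fits Gompertz growth curves, reduces each strain's population to the
26-feature phenoprint, applies the plate-median correction, converts to
robust scores s = 1.35 (F - median_WT)/iqr_WT, and reports how many
strains carry an extreme phenotype (|s| >= 3) per feature class.
Writes features.csv, scores.csv and flags.json under results/.
"""

import json
from pathlib import Path

from phenoscreen import io as psio
from phenoscreen import phenotyping as ph
from phenoscreen.growth import fit_gompertz

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cells = psio.read_cells(ROOT / "screen" / "cells.csv")
    curves = psio.read_growth(ROOT / "screen" / "growth.csv")
    truth = psio.read_truth(ROOT / "screen" / "truth.json")
    wt_ids = sorted(truth.wt_ids)

    fits = {s: fit_gompertz(c) for s, c in curves.items()}
    feats = ph.features_table(cells, fits).drop(columns="low_n")
    plate_map = {sid: tab["plate"].iloc[0] for sid, tab in cells.items()}
    feats = ph.correct_plate_bias(feats, plate_map, feats.loc[wt_ids].median())
    score_mat = ph.compute_scores(feats, wt_ids)

    feats.to_csv(ROOT / "features.csv")
    score_mat.scores.to_csv(ROOT / "scores.csv")
    counts = {
        cls: ph.flag_phenotypes(score_mat, 3.0, cls, exclude=set(wt_ids))["count"]
        for cls in ph.FEATURE_CLASSES
    }
    (ROOT / "flags.json").write_text(json.dumps(counts, indent=1))
    print(f"scored {len(feats)} strains on {score_mat.scores.shape[1]} features")
    print("strains with >= 1 |s| >= 3:", counts)


if __name__ == "__main__":
    main()
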