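"""Replication of screen-wide summary statistics from a score table.

Given a strains x features score table with the canonical feature names
(e.g. a published screen's deposited score dataset exported to CSV, or
a table produced by this package), recompute the headline quantities:
the number of strains carrying at least one extreme score per feature
class, and the feature-feature Pearson correlations.  Because the score
transform is affine per feature, correlations between score columns
equal correlations between the underlying corrected raw features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotyping import FEATURE_CLASSES, flag_phenotypes

__all__ = ["load_scores", "screen_statistics", "HEADLINE_PAIRS"]

#: feature pairs whose screen-wide correlations are of biological interest
HEADLINE_PAIRS = [
    ("<A>", "<NA>"),
    ("rel_T_const", "rel_T_nuc"),
    ("<L>", "<W>"),
    ("<NA>", "rel_T_nuc"),
]


def load_scores(path, wt_prefix: str = "WT") -> pd.DataFrame:
    """Read a scores CSV/TSV with a strain-id first column."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    return df.apply(pd.to_numeric, errors="coerce")


def screen_statistics(
    scores: pd.DataFrame,
    threshold: float = 3.0,
    exclude_wt: bool = True,
    wt_prefix: str = "WT",
) -> dict:
    """Extreme-phenotype strain counts per feature class and headline
    feature correlations (pairwise-complete Pearson)."""
    exclude = (
        {i for i in scores.index if str(i).startswith(wt_prefix)} if exclude_wt else set()
    )
    counts = {}
    for cls in FEATURE_CLASSES:
        cols = [c for c in FEATURE_CLASSES[cls] if c in scores.columns]
        if cols:
            counts[cls] = flag_phenotypes(scores, threshold, cols, exclude=exclude)["count"]
    corr = {}
    for a, b in HEADLINE_PAIRS:
        if a in scores.columns and b in scores.columns:
            sub = scores[[a, b]].dropna()
            corr[f"{a}~{b}"] = float(np.corrcoef(sub[a], sub[b])[0, 1])
    return {"extreme_counts": counts, "correlations": corr, "n_strains": len(scores) - len(exclude)}
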