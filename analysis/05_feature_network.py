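"""Feature-level relevance network over the screened feature set.

Applies the Belsley collinearity screen to the 10 non-collinear
candidate features, estimates pairwise mutual information, prunes with
ARACNE's data-processing inequality and bootstraps edge support (50
replicates here).  Writes edges.csv and network.graphml under results/.
"""

from pathlib import Path

import pandas as pd

from phenoscreen import network as net
from phenoscreen.pipeline import NETWORK_FEATURES

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    scores = pd.read_csv(ROOT / "scores.csv", index_col=0).dropna(axis=1)
    cols = [c for c in NETWORK_FEATURES if c in scores.columns]
    screened = net.belsley_screen(scores[cols])
    if screened.excluded:
        print("excluded as collinear:", screened.excluded)

    result = net.bootstrap_network(scores[screened.retained], n_boot=50,
                                   support_threshold=0.7, seed=SEED)
    result.write_edges_csv(ROOT / "edges.csv")
    result.write_graphml(ROOT / "network.graphml")
    print(f"{len(result.edges)} edges with support > 0.7 "
          f"over {len(screened.retained)} features")
    print(result.edges.to_string(index=False))


if __name__ == "__main__":
    main()
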