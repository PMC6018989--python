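"""Generate the synthetic screen used by the downstream analyses.

Produces a screen of 24 WT replicates plus three planted phenotypic
islands (12 strains each, displaced by 7 WT-SD on disjoint feature
pairs), writing cells.csv, growth.csv and truth.json under
results/screen/.
"""

from pathlib import Path

from phenoscreen import io as psio
from phenoscreen import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"
SEED = 11


def main() -> None:
    truth = syn.planted_archipelago_truth(seed=SEED)
    cells, curves, realized = syn.generate_screen(truth)
    OUT.mkdir(parents=True, exist_ok=True)
    psio.write_cells(cells, OUT / "cells.csv")
    psio.write_growth(curves, OUT / "growth.csv")
    psio.write_truth(realized, OUT / "truth.json")
    n_cells = sum(len(t) for t in cells.values())
    print(f"simulated {len(cells)} strains ({len(truth.wt_ids)} WT replicates), "
          f"{n_cells} cells -> {OUT}")


if __name__ == "__main__":
    main()
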