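#!/usr/bin/env python
"""Filter the proteome-microarray spot table to binder candidates.

Reads results/data/spots.tsv, computes per-spot SNR and fold change and
the duplicate-spot CV, applies the SNR >= 3 / fold >= 5 / CV < 0.15
cutoffs, and writes results/hpm_candidates.tsv.  Prints recovery of the
planted binders.
"""

import json
from pathlib import Path

from spliceratio.hpm import filter_candidates
from spliceratio.io import read_spot_table, write_results_table

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"


def main() -> None:
    spots = read_spot_table(DATA / "spots.tsv")
    stats = filter_candidates(spots)
    write_results_table(stats, ROOT / "results" / "hpm_candidates.tsv")

    called = set(stats.loc[stats["passed"], "protein_id"])
    planted = set(json.loads((DATA / "truth.json").read_text())["binders"])
    print(f"{len(stats)} proteins, {len(called)} pass all three cutoffs")
    print(f"  planted binders recovered: {len(called & planted)}/{len(planted)}")
    print(f"  false candidates: {len(called - planted)}")
    print("wrote results/hpm_candidates.tsv")


if __name__ == "__main__":
    main()
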