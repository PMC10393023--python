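#!/usr/bin/env python
"""Which marks define which states?

For each mark group, hide it from the learned model's emission term and
re-segment; the per-state Jaccard between full and subset segmentations
quantifies each group's contribution.  Marks are grouped by the state block
they diagnose (the synthetic analogue of excluding histone-variant or
modification families)."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from chromstate.genome_io import read_binary_tracks, read_chrom_sizes
from chromstate.hmm import load_model
from chromstate.model_evaluation import eval_subset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "subsets"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = read_chrom_sizes(DATA / "chrom.sizes")
    tracks = read_binary_tracks(DATA / "tracks_wild_type", genome)
    model = load_model(ROOT / "discovery" / "model_wild_type.txt")

    # group marks by the fitted state with the highest emission for them
    owner = model.E.argmax(axis=0)
    groups = {f"no_marks_of_{model.state_names[k]}": np.array([owner[m] != k for m in range(model.M)])
              for k in range(model.K) if (owner == k).any()}

    rows = []
    for name, mask in groups.items():
        ev = eval_subset(model, tracks, mask)
        for state, ji in zip(model.state_names, ev.jaccard):
            rows.append({"excluded": name, "state": state, "jaccard": ji})
        hit = model.state_names[int(np.argmin(ev.jaccard))]
        print(f"{name:<24} hidden {int((~mask).sum())} marks: "
              f"min Jaccard {ev.jaccard.min():.3f} at state {hit}")

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "subset_jaccard.tsv", sep="\t", index=False)
    wide = df.pivot(index="state", columns="excluded", values="jaccard")
    print("\nJaccard of full-model vs subset segmentation:")
    print(wide.round(3).to_string())


if __name__ == "__main__":
    main()
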