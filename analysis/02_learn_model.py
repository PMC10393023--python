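#!/usr/bin/env python
"""Learn chromatin-state models on the wild-type condition and ask how many
states the data support.

Fits models over a range of K, correlates each smaller model's emission rows
against the largest model (the reference), and reports the smallest K at
which no reference state loses its best-correlated partner — the
state-number diagnostic.  Then fits the model at the true K, segments, and
summarizes state coverage and feature composition.
"""

import sys
from pathlib import Path

from chromstate.genome_io import read_binary_tracks, read_chrom_sizes, read_gff3
from chromstate.hmm import FitConfig, fit_model, save_model, segment
from chromstate.model_evaluation import state_number_diagnostics
from chromstate.state_comparison import feature_overlap
from chromstate.genome_io import write_segmentation_bed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "discovery"
K_RANGE = [2, 4, 6, 8, 10]
K_FINAL = 8


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = read_chrom_sizes(DATA / "chrom.sizes")
    tracks = read_binary_tracks(DATA / "tracks_wild_type", genome)

    models = []
    for K in K_RANGE:
        model, report = fit_model(tracks, FitConfig(K=K, seed=SEED))
        models.append(model)
        print(f"K={K:>2}: logL={report.log_likelihoods[-1]:.1f} "
              f"({report.n_iter} iterations, converged={report.converged})")

    table, flagged = state_number_diagnostics(models, drop_threshold=0.9)
    table.to_csv(OUT / "state_number_diagnostics.tsv", sep="\t", index=False)
    print(f"\nstate-number diagnostic (reference K={K_RANGE[-1]}):")
    print(table.to_string(index=False))
    print(f"smallest K with no reference state below 0.9: {flagged}")

    final = next(m for m in models if m.K == K_FINAL)
    save_model(final, OUT / "model_wild_type.txt")
    seg = segment(final, tracks)
    write_segmentation_bed(seg, OUT / "segmentation_wild_type.bed")

    counts = seg.state_counts()
    print(f"\nK={K_FINAL} segmentation: coverage per state "
          f"{dict(zip(seg.state_names, (counts / counts.sum()).round(3)))}")

    ann = read_gff3(DATA / "annotation.gff3")
    fo = feature_overlap(seg, ann, ["TE gene", "gene"], proportions=True)
    fo.to_csv(OUT / "feature_overlap.tsv", sep="\t")
    print("\nfeature composition per state (proportions):")
    print(fo.round(3).to_string())


if __name__ == "__main__":
    main()
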