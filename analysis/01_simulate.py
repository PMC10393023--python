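#!/usr/bin/env python
"""Generate the synthetic two-condition study dataset with known ground truth.

Writes a small binned genome (3 × 1 Mb at 200 bp), binarized mark tracks for a
wild-type-like and a perturbed (mutant-like) condition emitted from a known
8-state model, the true segmentations, the perturbation's expected confusion
matrix, TE-gene/gene annotations and a zero-inflated expression table —
everything the downstream analyses consume.
"""

import json
import sys
from pathlib import Path

import numpy as np

from chromstate.genome_io import (
    write_binary_tracks,
    write_chrom_sizes,
    write_expression_table,
    write_segmentation_bed,
)
from chromstate.hmm import save_model
from chromstate.synthetic import (
    SimulationSpec,
    perturb_condition,
    sample_model,
    simulate_annotations_and_expression,
    simulate_tracks,
    tracks_from_segmentation,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(seed=SEED)
    genome = spec.genome()
    model, type_map = sample_model(spec)

    tracks_wt, seg_wt = simulate_tracks(model, genome, SEED, condition="wild_type")
    sources = [s for s, t in type_map.items() if t == "H"]
    target = next(s for s, t in type_map.items() if t == "F")
    seg_mut, expected_B = perturb_condition(seg_wt, sources, target, spec.perturb_fraction, SEED)
    tracks_mut = tracks_from_segmentation(model, seg_mut, SEED, condition="mutant")
    ann, expr, te_ids = simulate_annotations_and_expression(type_map, seg_wt, seg_mut, spec)

    write_chrom_sizes(genome, OUT / "chrom.sizes")
    save_model(model, OUT / "true_model.txt")
    write_binary_tracks(tracks_wt, OUT / "tracks_wild_type")
    write_binary_tracks(tracks_mut, OUT / "tracks_mutant")
    write_segmentation_bed(seg_wt, OUT / "truth_wild_type.bed")
    write_segmentation_bed(seg_mut, OUT / "truth_mutant.bed")
    np.savetxt(OUT / "expected_confusion.tsv", expected_B, fmt="%d", delimiter="\t")
    with open(OUT / "annotation.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in ann.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tchromstate_sim\t{r.feature_class}\t{r.start + 1}\t{r.end}"
                f"\t.\t{r.strand}\t.\tID={r.id}\n"
            )
    write_expression_table(expr, OUT / "expression.tsv")
    (OUT / "te_ids.txt").write_text("\n".join(te_ids) + "\n")
    (OUT / "manifest.json").write_text(json.dumps({
        "seed": SEED,
        "K": spec.K,
        "marks": model.marks,
        "type_map": type_map,
        "perturbed_sources": sources,
        "perturbed_target": target,
        "perturb_fraction": spec.perturb_fraction,
    }, indent=2, sort_keys=True) + "\n")

    moved = int(expected_B.sum() - np.trace(expected_B))
    print(f"genome: {genome.total_bins} bins over {len(genome.chroms)} chromosomes")
    print(f"model: K={spec.K} states ({type_map}), M={spec.M} marks")
    print(f"perturbation: {moved} bins moved from {sources} into {target}")
    print(f"annotation: {len(ann)} features, {len(te_ids)} TE genes")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
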