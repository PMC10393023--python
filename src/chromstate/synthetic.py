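"""Ground-truth simulation of everything the pipeline consumes.

The generator emulates, at desk scale, the study system the pipeline is built
for: a small multi-chromosome genome binned at 200 bp; a dozen binary
histone-variant/modification tracks emitted from a known K-state HMM with
block-persistent states grouped into chromatin types (constitutive
heterochromatin H, facultative heterochromatin F, euchromatin E, intergenic
I); a perturbed second condition in which contiguous blocks of
heterochromatin-state bins switch to a designated facultative state (the
mutant analogue); TE-gene annotations placed preferentially in
heterochromatin states; and zero-inflated per-gene expression in which TE
genes inside perturbed regions become expressed in the mutant.

All randomness flows from a single seed through named substreams, so each
component is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BinnedGenome, BinaryTrackSet, Segmentation
from .binarization import CountTrackSet
from .hmm import ChromatinModel

__all__ = [
    "SimulationSpec",
    "substream",
    "sample_model",
    "simulate_tracks",
    "simulate_counts",
    "perturb_condition",
    "simulate_annotations_and_expression",
    "expression_table_with_counts",
]


@dataclass
class SimulationSpec:
    """Defaults define the standard synthetic study conditions."""

    n_chroms: int = 3
    chrom_length: int = 1_000_000      # 5,000 bins each at 200 bp
    bin_size: int = 200
    K: int = 8
    M: int = 12
    emission_design: str = "blockwise-distinct"  # or "dirichlet-random"
    self_transition: float = 0.9
    # chromatin-type layout over the K states, truncated/cycled to K
    type_layout: tuple[str, ...] = ("H", "H", "H", "F", "F", "E", "E", "I")
    seed: int = 0
    # perturbation: fraction of source-type (H) bins switching to a facultative state
    perturb_fraction: float = 0.5
    # annotation densities: expected TE genes per 10 kb of state extent
    te_density_h: float = 1.0
    te_density_e: float = 0.1
    gene_density_e: float = 1.0
    te_gene_length: int = 2000
    # expression: P(zero) for unperturbed TE genes; log-normal for expressed
    zero_inflation: float = 0.8
    lognorm_mean: float = 1.0
    lognorm_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturb_fraction <= 1.0:
            raise ValueError("perturb_fraction must be in [0, 1]")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")

    def genome(self) -> BinnedGenome:
        return BinnedGenome(
            tuple((f"chr{i+1}", self.chrom_length) for i in range(self.n_chroms)),
            bin_size=self.bin_size,
        )

    def mark_names(self) -> list[str]:
        return [f"mark{m+1:02d}" for m in range(self.M)]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of the master seed.

    The stream name enters the seed sequence through a stable CRC so runs are
    bit-reproducible across processes.
    """
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def sample_model(spec: SimulationSpec) -> tuple[ChromatinModel, dict[str, str]]:
    """Random valid model plus the state → chromatin-type map.

    The blockwise-distinct design gives every state at least one
    near-diagnostic mark (emission ≥ 0.85 in-state, ≤ 0.15 elsewhere), echoing
    the sparse emission structure of real chromatin-state models.
    """
    rng = substream(spec.seed, "model")
    K, M = spec.K, spec.M
    if M < K:
        raise ValueError("blockwise design needs M >= K (one diagnostic mark per state)")

    if spec.emission_design == "blockwise-distinct":
        E = rng.uniform(0.02, 0.15, size=(K, M))
        # distribute marks over states round-robin; each state's block is diagnostic
        for m in range(M):
            k = m % K
            E[k, m] = rng.uniform(0.85, 0.95)
    elif spec.emission_design == "dirichlet-random":
        E = rng.beta(0.5, 0.5, size=(K, M))
    else:
        raise ValueError(f"unknown emission design {spec.emission_design!r}")

    s = spec.self_transition
    A = np.full((K, K), (1.0 - s) / (K - 1) if K > 1 else 0.0)
    np.fill_diagonal(A, s if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)

    layout = [spec.type_layout[k % len(spec.type_layout)] for k in range(K)]
    state_names = []
    counts: dict[str, int] = {}
    for t in layout:
        counts[t] = counts.get(t, 0) + 1
        state_names.append(f"{t}{counts[t]}")
    model = ChromatinModel(spec.mark_names(), pi, A, E, state_names)
    type_map = dict(zip(state_names, layout))
    return model, type_map


def simulate_tracks(
    model: ChromatinModel, genome: BinnedGenome, seed: int, condition: str = "wild_type"
) -> tuple[BinaryTrackSet, Segmentation]:
    """Sample the hidden chain per chromosome from pi/A, then marks from E."""
    rng = substream(seed, f"tracks:{condition}")
    calls: dict[str, np.ndarray] = {}
    states: dict[str, np.ndarray] = {}
    cumA = np.cumsum(model.A, axis=1)
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        z = np.empty(n, dtype=np.int64)
        u = rng.random(n)
        z[0] = np.searchsorted(np.cumsum(model.pi), u[0], side="right")
        for t in range(1, n):
            z[t] = np.searchsorted(cumA[z[t - 1]], u[t], side="right")
        z = np.minimum(z, model.K - 1)
        X = (rng.random((n, model.M)) < model.E[z]).astype(np.uint8)
        calls[chrom] = X
        states[chrom] = z + 1
    tracks = BinaryTrackSet(genome, condition, list(model.marks), calls)
    seg = Segmentation(genome, condition, states, list(model.state_names))
    return tracks, seg


def tracks_from_segmentation(
    model: ChromatinModel, seg: Segmentation, seed: int, condition: str | None = None
) -> BinaryTrackSet:
    """Emit mark calls from ``model.E`` along a fixed state path (e.g. a
    perturbed ground truth)."""
    condition = condition or seg.condition
    rng = substream(seed, f"tracks:{condition}")
    genome = seg.genome
    calls = {
        c: (rng.random((genome.n_bins(c), model.M)) < model.E[seg.state_of_bin[c] - 1]).astype(np.uint8)
        for c in genome.chrom_names
    }
    return BinaryTrackSet(genome, condition, list(model.marks), calls)


def simulate_counts(
    true_tracks: BinaryTrackSet, depth: float, enrichment: float, seed: int
) -> CountTrackSet:
    """Poisson read counts: rate ``depth`` where the true call is 0 and
    ``depth * enrichment`` where it is 1."""
    if enrichment <= 1.0:
        raise ValueError("enrichment must be > 1")
    rng = substream(seed, "counts")
    counts: dict[str, np.ndarray] = {}
    for chrom in true_tracks.genome.chrom_names:
        lam = depth * np.where(true_tracks.calls[chrom] == 1, enrichment, 1.0)
        counts[chrom] = rng.poisson(lam).astype(np.int64)
    return CountTrackSet(true_tracks.genome, list(true_tracks.marks), counts)


def perturb_condition(
    true_seg: Segmentation,
    source_states: list[str],
    target_state: str,
    fraction: float,
    seed: int,
    condition: str = "mutant",
) -> tuple[Segmentation, np.ndarray]:
    """Second-condition ground truth: contiguous blocks of source-state bins
    reassigned to the target state.

    Whole runs of the source states are flipped (preserving the block
    persistence an HMM refit expects) until at least ``fraction`` of the
    source extent has switched; the last run is split if needed so the moved
    bin count is exact.  Returns the perturbed segmentation and the exact
    expected confusion matrix B implied by the edit, computed by bookkeeping
    (diagonal from condition-1 state counts, moved bins shifted from
    (src, src) to (src, target)).
    """
    rng = substream(seed, "perturb")
    names = true_seg.state_names
    src_idx = {names.index(s) + 1 for s in source_states}
    tgt = names.index(target_state) + 1
    if tgt in src_idx:
        raise ValueError("target state cannot be a source state")

    # collect source runs over all chromosomes
    runs: list[tuple[str, int, int]] = []
    for chrom in true_seg.genome.chrom_names:
        vec = true_seg.state_of_bin[chrom]
        in_src = np.isin(vec, list(src_idx))
        change = np.flatnonzero(np.diff(in_src.astype(np.int8))) + 1
        bounds = np.concatenate(([0], change, [len(vec)]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if in_src[b0]:
                runs.append((chrom, int(b0), int(b1)))

    total_src = sum(b1 - b0 for _, b0, b1 in runs)
    to_move = int(round(fraction * total_src))
    order = rng.permutation(len(runs))
    moved_per_state = np.zeros(len(names) + 1, dtype=np.int64)  # index by state id
    new_states = {c: v.copy() for c, v in true_seg.state_of_bin.items()}
    remaining = to_move
    for ri in order:
        if remaining <= 0:
            break
        chrom, b0, b1 = runs[ri]
        take = min(b1 - b0, remaining)
        sl = slice(b0, b0 + take)
        for sid, cnt in zip(*np.unique(true_seg.state_of_bin[chrom][sl], return_counts=True)):
            moved_per_state[sid] += cnt
        new_states[chrom][sl] = tgt
        remaining -= take

    seg2 = Segmentation(true_seg.genome, condition, new_states, list(names))

    K = len(names)
    B = np.zeros((K, K), dtype=np.int64)
    counts1 = true_seg.state_counts()
    for s in range(K):
        B[s, s] = counts1[s] - moved_per_state[s + 1]
        B[s, tgt - 1] += moved_per_state[s + 1]
    return seg2, B


def simulate_annotations_and_expression(
    type_map: dict[str, str],
    true_seg: Segmentation,
    perturbed_seg: Segmentation | None,
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """TE-gene/gene annotation plus a zero-inflated TPM table.

    TE genes are dropped uniformly into heterochromatin-state extent at
    ``te_density_h`` per 10 kb (and at the much lower ``te_density_e`` into
    euchromatin); genes go into euchromatin.  Expression: genes are expressed
    in both conditions; a TE gene is silent in wild-type except for a small
    wt-expressed subset, and becomes expressed in the mutant preferentially
    when it lies in a perturbed region (its ground-truth state changed),
    otherwise stays zero-inflated.

    Returns (annotation records, expression table, te_ids).
    """
    rng = substream(spec.seed, "annotation")
    erng = substream(spec.seed, "expression")
    genome = true_seg.genome
    names = true_seg.state_names
    h_states = {i + 1 for i, s in enumerate(names) if type_map[s] == "H"}
    e_states = {i + 1 for i, s in enumerate(names) if type_map[s] == "E"}

    rows = []
    te_ids: list[str] = []
    gene_ids: list[str] = []
    for chrom in genome.chrom_names:
        vec = true_seg.state_of_bin[chrom]
        starts, ends = genome.bin_bounds(chrom)
        for sset, density, cls, id_list in (
            (h_states, spec.te_density_h, "TE gene", te_ids),
            (e_states, spec.te_density_e, "TE gene", te_ids),
            (e_states, spec.gene_density_e, "gene", gene_ids),
        ):
            in_set = np.isin(vec, list(sset))
            bp = int((ends - starts)[in_set].sum())
            n_features = erng.poisson(density * bp / 10_000) if cls == "gene" else rng.poisson(density * bp / 10_000)
            candidate_bins = np.flatnonzero(in_set)
            if len(candidate_bins) == 0 or n_features == 0:
                continue
            src = rng if cls == "TE gene" else erng
            chosen = src.choice(candidate_bins, size=n_features, replace=True)
            for b in chosen:
                start = int(starts[b])
                end = min(start + spec.te_gene_length, genome.lengths[chrom])
                fid = f"{cls.replace(' ', '_')}_{len(id_list)+1:05d}"
                id_list.append(fid)
                rows.append((chrom, start, end, "+", cls, fid))

    annotation = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature_class", "id"]
    )

    # per-TE-gene perturbation flag: did its midpoint bin change state?
    changed: dict[str, bool] = {}
    for row in annotation[annotation["feature_class"] == "TE gene"].itertuples(index=False):
        b = ((row.start + row.end) // 2) // genome.bin_size
        if perturbed_seg is None:
            changed[row.id] = False
        else:
            changed[row.id] = bool(
                true_seg.state_of_bin[row.chrom][b] != perturbed_seg.state_of_bin[row.chrom][b]
            )

    expr_rows = {}
    for te in te_ids:
        wt = 0.0
        if erng.random() < 0.05:  # small wt-expressed subset exercises the exclusion rule
            wt = float(erng.lognormal(spec.lognorm_mean, spec.lognorm_sigma))
        if changed.get(te, False):
            mut = float(erng.lognormal(spec.lognorm_mean, spec.lognorm_sigma))
        else:
            mut = 0.0 if erng.random() < spec.zero_inflation else float(
                erng.lognormal(spec.lognorm_mean - 1.0, spec.lognorm_sigma)
            )
        expr_rows[te] = (wt, mut)
    for g in gene_ids:
        expr_rows[g] = (
            float(erng.lognormal(spec.lognorm_mean + 1.0, spec.lognorm_sigma)),
            float(erng.lognormal(spec.lognorm_mean + 1.0, spec.lognorm_sigma)),
        )
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=["wild_type", "mutant"])
    expr.index.name = "gene_id"
    return annotation, expr, te_ids


def expression_table_with_counts(
    n_total: int,
    n_wt_expressed: int,
    n_mut_silent: int,
    seed: int = 0,
    silent_threshold: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic TPM table realizing exact group counts.

    Constructs ``n_total`` TE genes of which exactly ``n_wt_expressed`` have
    wild-type TPM > 0, and of the remainder exactly ``n_mut_silent`` have
    mutant TPM below the silence threshold; the rest form the expressed pool
    with distinct positive mutant TPMs.
    """
    if n_wt_expressed + n_mut_silent > n_total:
        raise ValueError("group counts exceed total")
    rng = substream(seed, "counts-table")
    ids = [f"TE{i+1:05d}" for i in range(n_total)]
    wt = np.zeros(n_total)
    mut = np.zeros(n_total)
    wt[:n_wt_expressed] = rng.uniform(0.5, 50.0, size=n_wt_expressed)
    # wt-expressed TEs may or may not be expressed in the mutant; irrelevant to grouping
    mut[:n_wt_expressed] = rng.uniform(0.0, 50.0, size=n_wt_expressed)
    lo = n_wt_expressed
    mut[lo : lo + n_mut_silent] = rng.uniform(0.0, silent_threshold * 0.99, size=n_mut_silent)
    hi = lo + n_mut_silent
    mut[hi:] = rng.uniform(silent_threshold, 100.0, size=n_total - hi)
    expr = pd.DataFrame({"wild_type": wt, "mutant": mut}, index=pd.Index(ids, name="gene_id"))
    return expr, ids
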