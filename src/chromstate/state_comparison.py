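"""Comparison layer: confusion matrices between segmentations, per-state
Jaccard/overlap/size-fold-change statistics, chromatin-type classification,
genomic-feature overlap, per-state signal aggregation, and TE-gene expression
grouping.

With ``B[w, m]`` the number of bins assigned state ``w`` in condition 1 and
state ``m`` in condition 2, the per-state statistics are

    JI_s = B_ss / (B_s· + B_·s − B_ss)      (Jaccard index)
    O_s  = B_ss / B_s·                      (overlap, fraction retained)
    FC_s = log2(B_·s / B_s·)                (size fold-change)

On a uniform bin grid these bin-count ratios equal the corresponding
base-pair-length ratios, up to at most one trailing partial bin per
chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BinnedGenome, Segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "StateConfusion",
    "StateComparisonStats",
    "ChromatinTypeAssignment",
    "TEExpressionGroups",
    "build_confusion",
    "comparison_stats",
    "feature_overlap",
    "classify_states",
    "chromatin_type_fractions",
    "aggregate_signal_by_state",
    "boxplot_summary",
    "group_te_genes",
]


@dataclass
class StateConfusion:
    B: np.ndarray  # K×K bin-count cross-tabulation
    state_names: list[str]

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.int64)
        K = len(self.state_names)
        if self.B.shape != (K, K):
            raise ValueError("B must be K×K")
        if (self.B < 0).any():
            raise ValueError("confusion entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.B.sum())


@dataclass
class StateComparisonStats:
    """Per-state JI/O/FC plus the genome-wide identical-state fraction.

    States absent from both conditions carry NaN (undefined, flagged in
    ``undefined``); a state absent from condition 1 only has undefined O and a
    +inf FC sentinel.
    """

    jaccard: pd.Series
    overlap: pd.Series
    fold_change: pd.Series
    genome_wide_overlap: float
    undefined: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"jaccard": self.jaccard, "overlap": self.overlap, "fold_change": self.fold_change}
        )


def build_confusion(segA: Segmentation, segB: Segmentation) -> StateConfusion:
    """Exact bins × bins cross-tabulation of two segmentations on one grid."""
    if not segA.genome.same_grid(segB.genome):
        raise ValueError("segmentations are on different bin grids")
    if segA.state_names != segB.state_names:
        raise ValueError("segmentations use different state universes")
    K = segA.n_states
    a = segA.stacked() - 1
    b = segB.stacked() - 1
    B = np.bincount(a * K + b, minlength=K * K).reshape(K, K)
    return StateConfusion(B, list(segA.state_names))


def comparison_stats(confusion: StateConfusion) -> StateComparisonStats:
    B = confusion.B.astype(float)
    names = confusion.state_names
    row = B.sum(axis=1)  # B_s· : state extent in condition 1
    col = B.sum(axis=0)  # B_·s : state extent in condition 2
    diag = np.diag(B)

    with np.errstate(divide="ignore", invalid="ignore"):
        ji = diag / (row + col - diag)
        ov = diag / row
        fc = np.log2(col / row)

    undefined = []
    for s in range(len(names)):
        if row[s] == 0 and col[s] == 0:
            ji[s] = ov[s] = fc[s] = np.nan
            undefined.append(names[s])
        elif row[s] == 0:  # appeared only in condition 2
            ov[s] = np.nan
            fc[s] = np.inf
            undefined.append(names[s])
    if undefined:
        logger.warning("comparison_stats: undefined statistics for states %s", undefined)

    gw = float(diag.sum() / B.sum()) if B.sum() else float("nan")
    idx = pd.Index(names, name="state")
    return StateComparisonStats(
        pd.Series(ji, index=idx), pd.Series(ov, index=idx), pd.Series(fc, index=idx),
        gw, undefined,
    )


# ---------------------------------------------------------------------------
# interval overlap helpers (sorted merge + prefix sums; exact in bp)
# ---------------------------------------------------------------------------


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def _overlap_with_merged(
    q_starts: np.ndarray, q_ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """bp of intersection of each query interval with a merged, sorted interval set."""
    if len(m_starts) == 0:
        return np.zeros(len(q_starts), dtype=np.int64)
    lengths = m_ends - m_starts
    cum = np.concatenate(([0], np.cumsum(lengths)))

    def covered_before(pos: np.ndarray) -> np.ndarray:
        i = np.searchsorted(m_starts, pos, side="right")
        full = cum[i]
        # subtract the part of interval i-1 beyond pos
        prev_end = np.where(i > 0, m_ends[np.maximum(i - 1, 0)], 0)
        over = np.where((i > 0) & (prev_end > pos), prev_end - pos, 0)
        return full - over

    return covered_before(q_ends) - covered_before(q_starts)


def feature_overlap(
    segmentation: Segmentation,
    annotation: pd.DataFrame,
    feature_classes: list[str] | None = None,
    proportions: bool = False,
) -> pd.DataFrame:
    """Base pairs of intersection between each state's regions and each feature class.

    With ``proportions=True`` the requested classes are treated as a partition:
    per-class overlaps are divided by the state's total bp, with an implicit
    ``unannotated`` column absorbing uncovered bp so rows sum to one.  Feature
    classes that overlap each other should be requested as raw bp only.
    """
    if feature_classes is None:
        feature_classes = sorted(annotation["feature_class"].unique())
    iv = segmentation.to_intervals()
    states = segmentation.state_names
    out = pd.DataFrame(0, index=pd.Index(states, name="state"), columns=feature_classes, dtype=np.int64)

    for chrom, seg_sub in iv.groupby("chrom"):
        ann_sub = annotation[annotation["chrom"] == chrom]
        qs = seg_sub["start"].to_numpy()
        qe = seg_sub["end"].to_numpy()
        for fc in feature_classes:
            f = ann_sub[ann_sub["feature_class"] == fc]
            ms, me = _merge_intervals(f["start"].to_numpy(), f["end"].to_numpy())
            bp = _overlap_with_merged(qs, qe, ms, me)
            for state_name, v in zip(seg_sub["state_name"], bp):
                out.loc[state_name, fc] += int(v)

    if proportions:
        state_bp = iv.groupby("state_name")["end"].sum() - iv.groupby("state_name")["start"].sum()
        totals = out.index.map(lambda s: state_bp.get(s, 0)).to_numpy().astype(float)
        prop = out.to_numpy() / np.maximum(totals[:, None], 1.0)
        res = pd.DataFrame(prop, index=out.index, columns=out.columns)
        res["unannotated"] = np.where(totals > 0, 1.0 - prop.sum(axis=1), 0.0)
        # clip tiny negative round-off from overlapping "partition" classes
        res["unannotated"] = res["unannotated"].clip(lower=0.0)
        return res
    return out


@dataclass
class ChromatinTypeAssignment:
    assignment: dict[str, str]  # state -> type or "mixed:T1+T2"
    fractions: pd.DataFrame     # state × type overlap fractions used


def classify_states(
    fractions: pd.DataFrame, major: float = 0.66, minor: float = 0.20
) -> ChromatinTypeAssignment:
    """Assign each state a chromatin type from its overlap fractions.

    A state overlapping one type with strictly more than ``major`` while every
    other type stays strictly below ``minor`` takes that type; otherwise it is
    ``mixed:<top>+<second>`` with the top two types in descending fraction.
    """
    vals = fractions.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("overlap fractions must lie in [0, 1]")
    if (vals.sum(axis=1) > 1.0 + 1e-6).any():
        raise ValueError("per-state fractions sum above 1")
    assignment: dict[str, str] = {}
    for state, row in fractions.iterrows():
        order = row.sort_values(ascending=False)
        top, second = order.index[0], order.index[1] if len(order) > 1 else None
        others_ok = (order.iloc[1:] < minor).all() if len(order) > 1 else True
        if order.iloc[0] > major and others_ok:
            assignment[state] = top
        else:
            assignment[state] = f"mixed:{top}+{second}" if second is not None else f"mixed:{top}"
    # sanity: at most one fraction can exceed major when major >= 0.5
    assert all(int((row > major).sum()) <= 1 for _, row in fractions.iterrows() if major >= 0.5)
    return ChromatinTypeAssignment(assignment, fractions)


def chromatin_type_fractions(
    seg: Segmentation, reference: Segmentation, type_of_ref_state: dict[str, str]
) -> pd.DataFrame:
    """Fraction of each state's bins overlapping each reference chromatin type."""
    if not seg.genome.same_grid(reference.genome):
        raise ValueError("segmentations are on different bin grids")
    types = sorted(set(type_of_ref_state.values()))
    ref_type = reference.stacked()
    type_idx = {t: i for i, t in enumerate(types)}
    ref_t = np.array([type_idx[type_of_ref_state[reference.state_names[s - 1]]] for s in ref_type])
    own = seg.stacked()
    out = np.zeros((seg.n_states, len(types)))
    for s in range(seg.n_states):
        m = own == s + 1
        if m.sum():
            out[s] = np.bincount(ref_t[m], minlength=len(types)) / m.sum()
    return pd.DataFrame(out, index=pd.Index(seg.state_names, name="state"), columns=types)


def aggregate_signal_by_state(
    segmentation: Segmentation,
    signal: pd.DataFrame,
    agg: str = "mean_of_regions",
) -> dict[str, np.ndarray]:
    """Per-state distributions of region-level signal means.

    Each state region gets the bp-weighted mean of the signal intervals
    overlapping it; regions with no signal are dropped (count logged).  With
    ``agg="bp_weighted_mean"`` each state instead gets a single scalar: the
    bp-weighted mean over all its covered bases.
    """
    if agg not in ("mean_of_regions", "bp_weighted_mean"):
        raise ValueError(f"unknown agg {agg!r}")
    iv = segmentation.to_intervals()
    per_state_vals: dict[str, list[float]] = {s: [] for s in segmentation.state_names}
    per_state_w: dict[str, list[float]] = {s: [] for s in segmentation.state_names}
    dropped = 0

    for chrom, seg_sub in iv.groupby("chrom"):
        sig = signal[signal["chrom"] == chrom].sort_values("start")
        ss = sig["start"].to_numpy()
        se = sig["end"].to_numpy()
        sv = sig["value"].to_numpy()
        # prefix integrals of covered bp and value·bp over the signal intervals
        cum_bp = np.concatenate(([0], np.cumsum(se - ss)))
        cum_vbp = np.concatenate(([0.0], np.cumsum(sv * (se - ss))))

        def integral(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            i = np.searchsorted(ss, pos, side="right")
            bp = cum_bp[i].astype(float)
            vbp = cum_vbp[i].copy()
            prev = np.maximum(i - 1, 0)
            over = np.where((i > 0) & (se[prev] > pos), se[prev] - pos, 0)
            bp -= over
            vbp -= over * sv[prev] * ((i > 0) & (se[prev] > pos))
            return bp, vbp

        if len(ss) == 0:
            dropped += len(seg_sub)
            continue
        b0, v0 = integral(seg_sub["start"].to_numpy())
        b1, v1 = integral(seg_sub["end"].to_numpy())
        cov_bp = b1 - b0
        cov_v = v1 - v0
        for name, bp, v in zip(seg_sub["state_name"], cov_bp, cov_v):
            if bp > 0:
                per_state_vals[name].append(v / bp)
                per_state_w[name].append(bp)
            else:
                dropped += 1

    if dropped:
        logger.warning("aggregate_signal_by_state: %d state regions had no signal", dropped)
    if agg == "mean_of_regions":
        return {s: np.asarray(v) for s, v in per_state_vals.items()}
    return {
        s: np.asarray([np.average(v, weights=per_state_w[s])]) if v else np.asarray([])
        for s, v in per_state_vals.items()
    }


def boxplot_summary(values: np.ndarray) -> dict[str, float]:
    """Five-number summary after Tukey outlier exclusion (1.5×IQR fences)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {k: float("nan") for k in ("low", "q1", "median", "q3", "high", "n")}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    keep = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return {
        "low": float(keep.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "high": float(keep.max()),
        "n": float(keep.size),
    }


# ---------------------------------------------------------------------------
# TE-gene expression grouping
# ---------------------------------------------------------------------------


@dataclass
class TEExpressionGroups:
    group_of: dict[str, str]  # te id -> excluded_wt_expressed | no_expression | q1..q4

    def members(self, group: str) -> list[str]:
        return [g for g, grp in self.group_of.items() if grp == group]

    @property
    def expressed(self) -> list[str]:
        """The q3 ∪ q4 'expressed' category."""
        return [g for g, grp in self.group_of.items() if grp in ("q3", "q4")]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for grp in self.group_of.values():
            out[grp] = out.get(grp, 0) + 1
        return out


def group_te_genes(
    expr: pd.DataFrame,
    te_ids: list[str],
    wt_col: str = "wild_type",
    mut_col: str = "mutant",
    silent_threshold: float = 0.1,
) -> TEExpressionGroups:
    """Partition TE genes by mutant expression.

    TE genes with any wild-type expression (TPM > 0) are excluded first; of the
    rest, those with mutant TPM < 0.1 form the no-expression group; the
    remainder is split into four quartiles by ascending mutant TPM (q1 lowest).
    When the pool is not divisible by 4, earlier quartiles take the extra
    genes.  Ties in TPM are broken by gene id for determinism.
    """
    missing = [t for t in te_ids if t not in expr.index]
    if missing:
        raise KeyError(f"TE ids missing from expression table: {missing[:10]}")
    sub = expr.loc[te_ids]
    group_of: dict[str, str] = {}
    wt = sub[wt_col]
    mut = sub[mut_col]

    excluded = set(sub.index[wt > 0.0])
    for g in excluded:
        group_of[g] = "excluded_wt_expressed"
    rest = sub.index[~sub.index.isin(excluded)]
    silent = set(rest[mut.loc[rest] < silent_threshold])
    for g in silent:
        group_of[g] = "no_expression"

    pool = [g for g in rest if g not in silent]
    pool.sort(key=lambda g: (mut.loc[g], g))
    n = len(pool)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    start = 0
    for i, size in enumerate(sizes):
        for g in pool[start : start + size]:
            group_of[g] = f"q{i+1}"
        start += size
    return TEExpressionGroups(group_of)
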