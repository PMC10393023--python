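"""Coordinate backbone, domain containers, and on-disk formats.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed) is
converted at the import boundary.  The genome is partitioned into fixed-width
bins; the last bin of a chromosome may be shorter than ``bin_size`` and is
retained so that conservation invariants (interval lengths summing to
chromosome lengths) hold exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedGenome",
    "BinaryTrackSet",
    "Segmentation",
    "FormatError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_intervals",
    "read_bed",
    "read_gff3",
    "read_signal_track",
    "read_expression_table",
    "write_expression_table",
    "write_segmentation_bed",
    "read_segmentation_bed",
    "write_binary_tracks",
    "read_binary_tracks",
]


class FormatError(ValueError):
    """Malformed on-disk input (bad coordinates, ragged rows, non-binary calls)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinnedGenome:
    """Ordered chromosomes partitioned into fixed-width bins.

    Bin ``i`` of a chromosome of length ``L`` covers
    ``[i*bin_size, min((i+1)*bin_size, L))``; the trailing partial bin is kept.
    """

    chroms: tuple[tuple[str, int], ...]
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    def n_bins(self, chrom: str) -> int:
        length = self.lengths[chrom]
        return -(-length // self.bin_size)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def bin_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of every bin on ``chrom``."""
        length = self.lengths[chrom]
        starts = np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size
        ends = np.minimum(starts + self.bin_size, length)
        return starts, ends

    def bin_widths(self, chrom: str) -> np.ndarray:
        starts, ends = self.bin_bounds(chrom)
        return ends - starts

    def same_grid(self, other: "BinnedGenome") -> bool:
        return self.chroms == other.chroms and self.bin_size == other.bin_size


@dataclass
class BinaryTrackSet:
    """Per-condition binarized mark calls: one bins × marks {0,1} matrix per chromosome."""

    genome: BinnedGenome
    condition: str
    marks: list[str]
    calls: dict[str, np.ndarray]  # chrom -> (n_bins, M) uint8

    def __post_init__(self) -> None:
        if len(set(self.marks)) != len(self.marks):
            raise ValueError("mark names must be unique")
        for chrom in self.genome.chrom_names:
            if chrom not in self.calls:
                raise ValueError(f"missing calls for chromosome {chrom!r}")
            mat = np.asarray(self.calls[chrom])
            expected = (self.genome.n_bins(chrom), len(self.marks))
            if mat.shape != expected:
                raise ValueError(
                    f"calls for {chrom!r} have shape {mat.shape}, expected {expected}"
                )
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"calls for {chrom!r} contain non-binary entries")
            self.calls[chrom] = mat.astype(np.uint8)

    def stacked(self) -> np.ndarray:
        """All chromosomes concatenated in genome order (total_bins, M)."""
        return np.concatenate([self.calls[c] for c in self.genome.chrom_names], axis=0)


@dataclass
class Segmentation:
    """Per-bin state assignment, states numbered 1..K."""

    genome: BinnedGenome
    condition: str
    state_of_bin: dict[str, np.ndarray]  # chrom -> int vector in [1..K]
    state_names: list[str]

    def __post_init__(self) -> None:
        K = len(self.state_names)
        for chrom in self.genome.chrom_names:
            vec = np.asarray(self.state_of_bin[chrom], dtype=np.int64)
            if vec.shape != (self.genome.n_bins(chrom),):
                raise ValueError(f"state vector for {chrom!r} has wrong length")
            if vec.size and (vec.min() < 1 or vec.max() > K):
                raise ValueError(f"states for {chrom!r} outside [1, {K}]")
            self.state_of_bin[chrom] = vec

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def stacked(self) -> np.ndarray:
        return np.concatenate(
            [self.state_of_bin[c] for c in self.genome.chrom_names]
        )

    def to_intervals(self) -> pd.DataFrame:
        """Run-length export: maximal constant-state intervals tiling each chromosome."""
        rows = []
        for chrom in self.genome.chrom_names:
            vec = self.state_of_bin[chrom]
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            run_starts = np.concatenate(([0], change))
            run_ends = np.concatenate((change, [vec.size]))
            starts, ends = self.genome.bin_bounds(chrom)
            for rs, re in zip(run_starts, run_ends):
                rows.append(
                    (chrom, int(starts[rs]), int(ends[re - 1]), int(vec[rs]))
                )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        df["state_name"] = [self.state_names[s - 1] for s in df["state"]]
        return df

    def state_counts(self) -> np.ndarray:
        """Number of bins per state, index s-1 for state s."""
        out = np.zeros(self.n_states, dtype=np.int64)
        for vec in self.state_of_bin.values():
            out += np.bincount(vec - 1, minlength=self.n_states)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path, bin_size: int = 200) -> BinnedGenome:
    """Two-column TSV ``name\\tlength`` -> BinnedGenome, file order preserved."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    return BinnedGenome(tuple(chroms), bin_size=bin_size)


def write_chrom_sizes(genome: BinnedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


_GFF_COLS = [
    "chrom", "source", "feature_class", "start", "end",
    "score", "strand", "frame", "attributes",
]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """GFF3 -> 0-based half-open records with the ``ID`` attribute as ``id``.

    Records whose interval is empty after conversion are dropped (counted in a
    log warning).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"chrom": str}, na_filter=False,
    )
    df["start"] = df["start"].astype(np.int64) - 1  # 1-based closed -> 0-based half-open
    df["end"] = df["end"].astype(np.int64)
    ids = df["attributes"].str.extract(r"(?:^|;)ID=([^;]+)", expand=False)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "strand": df["strand"],
            "feature_class": df["feature_class"],
            "id": ids.fillna(""),
        }
    )
    bad = out["start"] >= out["end"]
    if bad.any():
        logger.warning("read_gff3(%s): rejected %d records with empty intervals", path, int(bad.sum()))
    return out.loc[~bad].reset_index(drop=True)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (3+ columns, 0-based half-open) -> interval records."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype={0: str}, na_filter=False,
    )
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
        }
    )
    out["name"] = df[3] if df.shape[1] > 3 else ""
    out["strand"] = df[5] if df.shape[1] > 5 else "."
    bad = out["start"] >= out["end"]
    if bad.any():
        logger.warning("read_bed(%s): rejected %d empty intervals", path, int(bad.sum()))
    return out.loc[~bad].reset_index(drop=True)


def read_intervals(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Normalized 0-based half-open interval records from BED or GFF3."""
    return read_gff3(path) if one_based else read_bed(path)


def read_signal_track(path: str | Path) -> pd.DataFrame:
    """bedGraph-style TSV chrom/start/end/value with finite float values."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    if not np.isfinite(df["value"]).all():
        raise FormatError(f"{path}: non-finite signal values")
    return df


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id / wild_type / mutant (TPM); gene_id becomes the index."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative TPM values")
    return df


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def write_segmentation_bed(seg: Segmentation, path: str | Path) -> None:
    """BED4 of maximal constant-state runs; inverse of :func:`read_segmentation_bed`."""
    iv = seg.to_intervals()
    with open(path, "w") as fh:
        for row in iv.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.state_name}\n")


def read_segmentation_bed(
    path: str | Path,
    genome: BinnedGenome,
    state_names: Sequence[str] | None = None,
    condition: str = "",
) -> Segmentation:
    """Read a state BED that must tile the genome bin grid exactly."""
    df = read_bed(path)
    if state_names is None:
        state_names = sorted(df["name"].unique())
    index = {name: i + 1 for i, name in enumerate(state_names)}
    state_of_bin: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        vec = np.zeros(n, dtype=np.int64)
        sub = df[df["chrom"] == chrom].sort_values("start")
        cursor = 0
        for row in sub.itertuples(index=False):
            if row.start != cursor:
                kind = "gap" if row.start > cursor else "overlap"
                raise FormatError(
                    f"{path}: {kind} on {chrom} at position {cursor} (next interval starts {row.start})"
                )
            b0 = row.start // genome.bin_size
            b1 = -(-row.end // genome.bin_size)
            try:
                vec[b0:b1] = index[row.name]
            except KeyError:
                raise FormatError(f"{path}: unknown state name {row.name!r}") from None
            cursor = row.end
        if cursor != genome.lengths[chrom]:
            raise FormatError(
                f"{path}: gap on {chrom} at position {cursor} (chromosome end {genome.lengths[chrom]})"
            )
        state_of_bin[chrom] = vec
    return Segmentation(genome, condition, state_of_bin, list(state_names))


# ChromHMM-compatible binarized text: per chromosome one file with a two-line
# header (condition<TAB>chrom, then the mark names) followed by one 0/1 row per bin.


def write_binary_tracks(tracks: BinaryTrackSet, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom in tracks.genome.chrom_names:
        p = outdir / f"{tracks.condition}_{chrom}_binary.txt"
        with open(p, "w") as fh:
            fh.write(f"{tracks.condition}\t{chrom}\n")
            fh.write("\t".join(tracks.marks) + "\n")
            np.savetxt(fh, tracks.calls[chrom], fmt="%d", delimiter="\t")
        paths.append(p)
    return paths


def read_binary_tracks(indir: str | Path, genome: BinnedGenome) -> BinaryTrackSet:
    indir = Path(indir)
    files = sorted(indir.glob("*_binary.txt"))
    if not files:
        raise FormatError(f"no *_binary.txt files in {indir}")
    condition = None
    marks: list[str] | None = None
    calls: dict[str, np.ndarray] = {}
    for p in files:
        with open(p) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) != 2:
                raise FormatError(f"{p}:1: expected 'condition\\tchrom' header")
            cond, chrom = header
            file_marks = fh.readline().rstrip("\n").split("\t")
            rows = []
            for lineno, line in enumerate(fh, 3):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(file_marks):
                    raise FormatError(f"{p}:{lineno}: ragged row ({len(parts)} fields, expected {len(file_marks)})")
                for v in parts:
                    if v not in ("0", "1"):
                        raise FormatError(f"{p}:{lineno}: entry {v!r} not in {{0,1}}")
                rows.append([int(v) for v in parts])
        if condition is None:
            condition, marks = cond, file_marks
        elif cond != condition:
            raise FormatError(f"{p}: condition {cond!r} differs from {condition!r}")
        elif file_marks != marks:
            raise FormatError(f"{p}: mark header differs across chromosomes")
        if chrom not in genome.lengths:
            raise FormatError(f"{p}: unknown chromosome {chrom!r}")
        calls[chrom] = np.asarray(rows, dtype=np.uint8).reshape(len(rows), len(file_marks))
    assert marks is not None
    return BinaryTrackSet(genome, condition, list(marks), calls)
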