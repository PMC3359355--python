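"""Clone-coverage copy-number analysis.

Each proper read pair — the two sequenced ends plus the unsequenced
interlying region — covers the genome as a single *clone*. Pairs whose
template length falls more than two standard deviations from the estimated
insert mean are excluded, as are unmapped mates and flagged duplicates.
Per-base clone depth is averaged over fixed 2 kb windows and divided by the
genome-wide mode of (integer) per-base clone depth over covered bases; the
relative copy number of a window is the log2 ratio of the tumor to the
normal normalized coverage (positive = tumor gain). Maximal runs of windows
beyond a threshold form gain/loss segments; genes overlapping a segment by
at least half their length are reported gained or lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .annotate import GeneModel
from .engine import ReadBlock
from .errors import ConfigError
from .samio import AlignedRead

DEFAULT_WINDOW_SIZE = 2000
GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"


@dataclass(frozen=True)
class CloneInterval:
    """Reference interval covered by one template (both mates + gap)."""

    contig: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("clone end before start")


@dataclass
class CloneCoverageTrack:
    contig: str
    window_size: int
    window_starts: np.ndarray  # 1-based start of each window
    window_means: np.ndarray   # mean per-base clone coverage per window
    mode_coverage: float       # genome-wide mode of rounded per-base depth
    normalized: np.ndarray     # window_means / mode_coverage


@dataclass
class CopyNumberSegment:
    contig: str
    start: int
    end: int
    log2_ratio: float
    call: str  # gain | loss | neutral
    n_windows: int


def extract_clones(
    reads: Union[ReadBlock, Iterable[AlignedRead]],
    min_pairs: int = 100,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Clone intervals and insert statistics from proper pairs.

    Uses the leftmost mate of each pair (tlen > 0) so each template counts
    once. Returns (starts, ends, (insert_mean, insert_sd)); pairs with
    |tlen| outside mean +/- 2 sd are excluded.
    """
    if isinstance(reads, ReadBlock):
        keep = (reads.tlen > 0) & ~reads.is_dup
        starts = reads.pos[keep]
        tlens = reads.tlen[keep]
    else:
        pairs = [
            r
            for r in reads
            if r.mapped and not r.is_duplicate and r.mate_pos is not None and r.tlen > 0
        ]
        starts = np.array([r.pos for r in pairs], dtype=np.int64)
        tlens = np.array([r.tlen for r in pairs], dtype=np.int64)
    if len(starts) < min_pairs:
        raise ConfigError(
            f"only {len(starts)} proper pairs; need >= {min_pairs} to estimate insert stats"
        )
    mean = float(np.mean(tlens))
    sd = float(np.std(tlens))
    keep = (tlens >= mean - 2 * sd) & (tlens <= mean + 2 * sd)
    starts = starts[keep]
    ends = starts + tlens[keep] - 1
    return starts.astype(np.int64), ends.astype(np.int64), (mean, sd)


def clone_depth(starts: np.ndarray, ends: np.ndarray, contig_length: int) -> np.ndarray:
    """Per-base clone depth by interval accumulation (1-based intervals,
    clipped to the contig)."""
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    s = np.clip(starts - 1, 0, contig_length)
    e = np.clip(ends, 0, contig_length)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    return np.cumsum(diff[:contig_length])


def _window_slices(contig_length: int, window_size: int) -> list[tuple[int, int]]:
    if window_size <= 0:
        raise ConfigError("window_size must be positive")
    slices = []
    full = contig_length // window_size
    for w in range(full):
        slices.append((w * window_size, (w + 1) * window_size))
    rem = contig_length - full * window_size
    if rem * 2 >= window_size:  # keep a final partial window of >= 50% size
        slices.append((full * window_size, contig_length))
    return slices


def mode_coverage(depths: Sequence[np.ndarray]) -> int:
    """Mode of integer per-base clone depth over covered (depth > 0) bases,
    ties broken toward the smaller depth."""
    hist = None
    for depth in depths:
        h = np.bincount(depth[depth > 0])
        if hist is None:
            hist = h
        else:
            if len(h) > len(hist):
                hist, h = h, hist
            hist[: len(h)] += h
    if hist is None or hist.sum() == 0:
        raise ConfigError("no covered bases; cannot estimate mode coverage")
    return int(np.argmax(hist))  # first maximum = smaller depth on ties


def build_coverage_tracks(
    clones_by_contig: Mapping[str, tuple[np.ndarray, np.ndarray]],
    contig_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> dict[str, CloneCoverageTrack]:
    """Windowed, mode-normalized clone coverage for every contig, sharing a
    single genome-wide mode."""
    depths = {
        contig: clone_depth(starts, ends, contig_lengths[contig])
        for contig, (starts, ends) in clones_by_contig.items()
    }
    mode = mode_coverage(list(depths.values()))
    tracks = {}
    for contig, depth in depths.items():
        slices = _window_slices(contig_lengths[contig], window_size)
        means = np.array([depth[a:b].mean() for a, b in slices])
        tracks[contig] = CloneCoverageTrack(
            contig=contig,
            window_size=window_size,
            window_starts=np.array([a + 1 for a, _ in slices], dtype=np.int64),
            window_means=means,
            mode_coverage=float(mode),
            normalized=means / mode,
        )
    return tracks


def coverage_track(
    starts: np.ndarray,
    ends: np.ndarray,
    contig: str,
    contig_length: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> CloneCoverageTrack:
    """Single-contig convenience wrapper over :func:`build_coverage_tracks`."""
    return build_coverage_tracks(
        {contig: (starts, ends)}, {contig: contig_length}, window_size
    )[contig]


def log2_relative(
    tumor: CloneCoverageTrack,
    normal: CloneCoverageTrack,
    pseudocount: float = 0.01,
    min_normal_norm: float = 0.1,
) -> np.ndarray:
    """Per-window log2(tumor_norm / normal_norm); windows whose normal
    normalized coverage falls below the callability floor are NaN."""
    if (
        tumor.window_size != normal.window_size
        or len(tumor.window_means) != len(normal.window_means)
    ):
        raise ConfigError("tumor and normal tracks have different window tilings")
    ratio = np.log2((tumor.normalized + pseudocount) / (normal.normalized + pseudocount))
    ratio[normal.normalized < min_normal_norm] = np.nan
    return ratio


def segment_and_call(
    ratios: np.ndarray,
    contig: str,
    contig_length: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
    min_windows: int = 3,
) -> list[CopyNumberSegment]:
    """Threshold run-length segmentation of per-window log2 ratios.

    Maximal runs of >= min_windows consecutive windows beyond a threshold
    become gain/loss segments; everything else (including masked windows) is
    merged into neutral segments.
    """
    n = len(ratios)
    state = np.full(n, NEUTRAL, dtype=object)
    with np.errstate(invalid="ignore"):
        state[np.asarray(ratios) >= gain_threshold] = GAIN
        state[np.asarray(ratios) <= loss_threshold] = LOSS
    # demote short gain/loss runs to neutral
    i = 0
    while i < n:
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        if state[i] != NEUTRAL and j - i < min_windows:
            state[i:j] = NEUTRAL
        i = j
    slices = _window_slices(contig_length, window_size)
    segments = []
    i = 0
    while i < n:
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        run = np.asarray(ratios[i:j], dtype=float)
        mean = float(np.nanmean(run)) if np.any(~np.isnan(run)) else float("nan")
        segments.append(
            CopyNumberSegment(
                contig=contig,
                start=slices[i][0] + 1,
                end=slices[j - 1][1],
                log2_ratio=mean,
                call=str(state[i]),
                n_windows=j - i,
            )
        )
        i = j
    return segments


def genes_in_segments(
    segments: Iterable[CopyNumberSegment],
    genes: Iterable[GeneModel],
    min_overlap_fraction: float = 0.5,
) -> tuple[list[str], list[str]]:
    """(gained, lost) gene names: a gene qualifies when gain (resp. loss)
    segments on its contig overlap at least ``min_overlap_fraction`` of its
    genomic span."""
    segments = list(segments)
    genes = list(genes)
    seg_contigs = {s.contig for s in segments}
    unmatched = sorted({g.contig for g in genes} - seg_contigs)
    if unmatched:
        raise ConfigError(f"gene model contigs absent from segments: {unmatched}")
    gained, lost = [], []
    for gene in genes:
        g_start, g_end = gene.span
        g_len = g_end - g_start + 1
        for call, bucket in ((GAIN, gained), (LOSS, lost)):
            overlap = sum(
                max(0, min(s.end, g_end) - max(s.start, g_start) + 1)
                for s in segments
                if s.contig == gene.contig and s.call == call
            )
            if overlap >= min_overlap_fraction * g_len:
                bucket.append(gene.name)
    return gained, lost
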