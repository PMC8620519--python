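"""Runs-of-homozygosity detection and cross-case shared-region intersection.

The scanner follows the classic windowed ROH algorithm used for autozygosity
mapping from SNP-array data: slide a window of ``window_snps`` consecutive
markers along each chromosome, call a window homozygous when it contains at
most ``window_het`` heterozygous and ``window_missing`` missing calls, score
every marker by the fraction of overlapping windows that are homozygous, and
assemble markers whose fraction reaches ``hit_threshold`` into runs subject
to length, marker-count, gap and density constraints.

Shared candidate regions are the maximal intervals covered by an ROH of
every case, verified by a consensus check that all cases are homozygous for
the *same* allele at every marker inside (unphased allele identity — true
phase is neither available from array homozygotes nor needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix, Marker


@dataclass(frozen=True)
class ROHParams:
    """Scanner parameters; defaults follow the study's option set with the
    tool's documented defaults for the options it left unchanged."""

    min_snps: int = 10                   # --homozyg-snp
    max_gap_kb: float = 1000.0           # --homozyg-gap
    max_density_kb_per_snp: float = 30.0  # --homozyg-density: avg span/SNP cap
    window_snps: int = 50                # --homozyg-window-snp (tool default)
    window_het: int = 0                  # --homozyg-window-het
    window_missing: int = 0              # --homozyg-window-missing
    hit_threshold: float = 0.05          # --homozyg-window-threshold (default)
    min_kb: float = 1000.0               # --homozyg-kb (tool default)

    def __post_init__(self):
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not (0 < self.hit_threshold <= 1):
            raise ValueError("hit_threshold must be in (0, 1]")
        for name in ("min_snps", "max_gap_kb", "max_density_kb_per_snp",
                     "window_het", "window_missing", "min_kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity in one sample; bounds are the positions of the
    first and last marker in the run."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start_bp <= pos <= self.end_bp


@dataclass
class SharedRegion:
    """Interval covered by an ROH of every case, with consensus verification."""

    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int          # markers inside at which all cases are homozygous
    consensus_ok: bool      # same homozygous allele in all cases at all such markers
    marker_ids: list[str] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def region_span(start_bp: int, end_bp: int) -> int:
    """Region span as end − start, the convention used for the reported
    critical-region size."""
    if start_bp > end_bp:
        raise ValueError("start_bp must be <= end_bp")
    return end_bp - start_bp


def window_hit_fractions(sample_codes: np.ndarray, markers: Sequence[Marker],
                         params: ROHParams) -> np.ndarray:
    """Per-marker fraction of overlapping homozygous windows, in [0, 1].

    Markers and codes must belong to a single chromosome and be aligned.  If
    the chromosome is shorter than the window the window shrinks to the
    chromosome length (one window covering everything).
    """
    codes = np.asarray(sample_codes)
    m = len(codes)
    if m != len(markers):
        raise ValueError("codes and markers length mismatch")
    if m == 0:
        return np.empty(0, dtype=float)
    w = min(params.window_snps, m)

    het = (codes == HET).astype(np.int64)
    mis = (codes == MISSING).astype(np.int64)
    # windows start at s = 0 .. m-w; qualify[s]: counts within [s, s+w-1]
    chet = np.concatenate(([0], np.cumsum(het)))
    cmis = np.concatenate(([0], np.cumsum(mis)))
    starts = np.arange(m - w + 1)
    qual = ((chet[starts + w] - chet[starts] <= params.window_het)
            & (cmis[starts + w] - cmis[starts] <= params.window_missing))
    cqual = np.concatenate(([0], np.cumsum(qual)))

    idx = np.arange(m)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, m - w)           # inclusive window-start range
    n_windows = hi - lo + 1
    n_hits = cqual[hi + 1] - cqual[lo]
    return n_hits / n_windows


def call_roh(sample_id: str, sample_codes: np.ndarray, markers: Sequence[Marker],
             params: ROHParams) -> list[ROHSegment]:
    """Call ROH segments on one chromosome of one sample.

    Markers whose hit fraction reaches ``hit_threshold`` become run
    candidates; candidate runs are split at inter-marker gaps above
    ``max_gap_kb`` and emitted when they satisfy the marker-count, length and
    density constraints.
    """
    if len(markers) == 0:
        return []
    chroms = {mk.chrom for mk in markers}
    if len(chroms) != 1:
        raise ValueError("call_roh operates on a single chromosome")
    chrom = chroms.pop()
    frac = window_hit_fractions(sample_codes, markers, params)
    candidates = np.flatnonzero(frac >= params.hit_threshold)

    segments: list[ROHSegment] = []
    run: list[int] = []

    def flush(run_idx: list[int]):
        if not run_idx:
            return
        start = markers[run_idx[0]].pos_bp
        end = markers[run_idx[-1]].pos_bp
        n = len(run_idx)
        span = end - start
        if (n >= params.min_snps and span >= params.min_kb * 1000
                and span / n <= params.max_density_kb_per_snp * 1000):
            segments.append(ROHSegment(sample_id=sample_id, chrom=chrom,
                                       start_bp=start, end_bp=end, n_snps=n))

    # runs split only by the physical-gap rule; markers whose fraction fails
    # (isolated hets/missing islands) are excluded from n_snps but do not by
    # themselves terminate a run
    max_gap_bp = params.max_gap_kb * 1000
    for i in candidates:
        if run and markers[i].pos_bp - markers[run[-1]].pos_bp > max_gap_bp:
            flush(run)
            run = []
        run.append(int(i))
    flush(run)
    return segments


def call_roh_all(gmatrix: GenotypeMatrix, params: ROHParams,
                 sample_ids: Sequence[str] | None = None
                 ) -> dict[str, list[ROHSegment]]:
    """Call ROH for every (sample, chromosome); returns segments per sample."""
    ids = list(sample_ids) if sample_ids is not None else list(gmatrix.samples)
    by_chrom = gmatrix.chrom_indices()
    out: dict[str, list[ROHSegment]] = {}
    for sid in ids:
        row = gmatrix.sample_row(sid)
        segs: list[ROHSegment] = []
        for chrom, idx in by_chrom.items():
            segs.extend(call_roh(sid, row[idx], [gmatrix.markers[i] for i in idx],
                                 params))
        out[sid] = segs
    return out


def _interval_intersection(lists: list[list[tuple[int, int]]]
                           ) -> list[tuple[int, int]]:
    """Intersect per-case sorted disjoint interval lists into maximal common
    intervals."""
    current = lists[0]
    for nxt in lists[1:]:
        merged = []
        i = j = 0
        while i < len(current) and j < len(nxt):
            lo = max(current[i][0], nxt[j][0])
            hi = min(current[i][1], nxt[j][1])
            if lo <= hi:
                merged.append((lo, hi))
            if current[i][1] < nxt[j][1]:
                i += 1
            else:
                j += 1
        current = merged
        if not current:
            break
    return current


def intersect_shared(case_segments: Mapping[str, Sequence[ROHSegment]],
                     gmatrix: GenotypeMatrix) -> list[SharedRegion]:
    """Maximal intervals lying inside an ROH of every case.

    For each interval, ``n_markers`` counts array markers inside at which all
    cases are homozygous (non-missing); ``consensus_ok`` requires the same
    homozygous code in every case at every such marker.  Intervals containing
    no such marker are dropped.
    """
    if len(case_segments) < 2:
        raise ValueError("intersect_shared needs segments from at least 2 cases")
    case_ids = list(case_segments)
    chroms: set[str] = set()
    for segs in case_segments.values():
        chroms.update(s.chrom for s in segs)

    rows = {sid: gmatrix.sample_row(sid) for sid in case_ids}
    by_chrom = gmatrix.chrom_indices()
    out: list[SharedRegion] = []
    for chrom in sorted(chroms):
        per_case = []
        for sid in case_ids:
            ivs = sorted((s.start_bp, s.end_bp)
                         for s in case_segments[sid] if s.chrom == chrom)
            per_case.append(ivs)
        if any(not ivs for ivs in per_case):
            continue
        for lo, hi in _interval_intersection(per_case):
            inside = [i for i in by_chrom.get(chrom, [])
                      if lo <= gmatrix.markers[i].pos_bp <= hi]
            hom_ids, consensus = [], True
            for i in inside:
                col = np.array([rows[sid][i] for sid in case_ids])
                if np.all((col == HOM_A) | (col == HOM_B)):
                    hom_ids.append(gmatrix.markers[i].id)
                    if not np.all(col == col[0]):
                        consensus = False
            if hom_ids:
                out.append(SharedRegion(chrom=chrom, start_bp=lo, end_bp=hi,
                                        n_markers=len(hom_ids),
                                        consensus_ok=consensus,
                                        marker_ids=hom_ids))
    return out
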