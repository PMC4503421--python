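"""Read mapping, depth profiles, deletion calling, junction support,
mixture estimation and terminal-redundancy step detection.

The mapper here is deliberately minimal -- exact k-mer anchoring at both
read ends, diagonal voting, ungapped full-length extension -- and is meant
for synthetic, low-divergence reads; it is documented as unsuitable for real
data.  Real alignments can be imported instead (depth TSV or minimal SAM;
see :mod:`orfanage.io`).

Because a placement requires both terminal k-mers of the read to match the
reference exactly, reads spanning a junction absent from the reference
(e.g. a deletion junction) are reported unmapped rather than placed with a
mismatched overhang.  This keeps the depth signal inside a deleted interval
exactly zero when the junction carries no micro-homology, which is what
makes base-exact breakpoint recovery from coverage well-posed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .genome_model import DeletionEvent, Genome, reverse_complement
from . import io as _io

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentRecord:
    """One (possibly unmapped) read placement on a single reference."""

    read_id: str
    ref_id: str
    pos: int  # 1-based leftmost reference position; 0 when unmapped
    aligned_length: int
    strand: str
    n_mismatch: int
    mapped: bool
    tie: bool = False


@dataclass
class DepthProfile:
    """Per-base read depth over one reference."""

    ref_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    def __len__(self) -> int:
        return self.depth.size

    @property
    def mean(self) -> float:
        return float(self.depth.sum() / self.depth.size)

    @property
    def sd(self) -> float:
        return float(self.depth.std())

    def mean_excluding(self, event: DeletionEvent) -> float:
        """Mean depth with the deleted interval masked out (useful when a
        zero-coverage deletion would otherwise drag the genome-wide mean)."""
        event.validate_against(len(self))
        mask = np.ones(len(self), dtype=bool)
        mask[event.left_retained : event.right_deleted] = False
        return float(self.depth[mask].mean())


@dataclass(frozen=True)
class StepCall:
    """A circular two-change-point piecewise-constant fit of a depth profile."""

    window_start: int  # 1-based, inclusive
    window_end: int  # 1-based, inclusive (may wrap past the origin)
    rate_in: float
    rate_out: float
    fold: float
    degenerate: bool = False


class ReferenceIndex:
    """Exact k-mer index over a (circular) reference, reusable across calls."""

    def __init__(self, reference: Genome, k: int = 21, max_hits_per_kmer: int = 512):
        self.reference = reference
        self.k = k
        self.G = len(reference)
        if k > self.G:
            raise ValueError("k-mer size exceeds reference length")
        self.ext_str = reference.sequence * 2
        self.ext_num = np.concatenate([_encode(reference.sequence)] * 2)
        self.max_hits = max_hits_per_kmer
        index: dict[str, list[int]] = {}
        s = self.ext_str
        for i in range(self.G):
            index.setdefault(s[i : i + k], []).append(i)
        self.index = index

    def candidates(self, seq: str) -> list[int]:
        """0-based diagonals where both terminal k-mers match exactly."""
        k, L = self.k, len(seq)
        head = self.index.get(seq[:k])
        if not head:
            return []
        if len(head) > self.max_hits:
            head = head[: self.max_hits]
        tail = seq[L - k :]
        out = []
        for p in head:
            if self.ext_str[p + L - k : p + L] == tail:
                out.append(p)
        return out


def map_reads(
    reads,
    reference: Genome,
    seed_k: int = 21,
    min_identity: float = 0.8,
    index: ReferenceIndex | None = None,
) -> list[AlignmentRecord]:
    """Map reads to a single circular reference.

    ``reads`` is an iterable of ``(read_id, sequence)``.  Placements are
    found by exact matching of the read's first and last k-mers on a common
    diagonal (both strands), then scored by ungapped full-length mismatch
    count.  The best unique placement is reported; ties between distinct
    placements, or identity below ``min_identity``, leave the read unmapped.
    """
    if index is None:
        index = ReferenceIndex(reference, k=seed_k)
    elif index.k != seed_k:
        raise ValueError("supplied index was built with a different k")
    G = index.G
    ext = index.ext_num
    out: list[AlignmentRecord] = []
    for read_id, seq in reads:
        L = len(seq)
        if seed_k > L:
            raise ValueError(f"k ({seed_k}) exceeds read length ({L}) for {read_id}")
        hits: list[tuple[int, str, int]] = []
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            cands = index.candidates(s)
            if not cands:
                continue
            arr = _encode(s)
            for p in cands:
                mism = int(np.count_nonzero(ext[p : p + L] != arr))
                hits.append((mism, strand, p % G))
        if not hits:
            out.append(AlignmentRecord(read_id, reference.id, 0, 0, "+", 0, False))
            continue
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        best = hits[0]
        tie = len(hits) > 1 and hits[1][0] == best[0] and (hits[1][1], hits[1][2]) != (best[1], best[2])
        identity = (L - best[0]) / L
        if tie or identity < min_identity:
            out.append(AlignmentRecord(read_id, reference.id, 0, 0, "+", best[0], False, tie=tie))
        else:
            out.append(
                AlignmentRecord(read_id, reference.id, best[2] + 1, L, best[1], best[0], True)
            )
    return out


def depth_from_alignments(
    alignments: list[AlignmentRecord], reference_length: int, ref_id: str | None = None, circular: bool = True
) -> DepthProfile:
    """Per-base depth: number of mapped alignments covering each base."""
    G = reference_length
    delta = np.zeros(G + 1, dtype=np.int64)
    clipped = 0
    rid = ref_id
    for a in alignments:
        if not a.mapped:
            continue
        if rid is None:
            rid = a.ref_id
        s = a.pos - 1
        e = s + a.aligned_length
        if e <= G:
            delta[s] += 1
            delta[e] -= 1
        elif circular:
            delta[s] += 1
            delta[G] -= 1
            delta[0] += 1
            delta[e - G] -= 1
        else:
            clipped += 1
            delta[s] += 1
            delta[G] -= 1
    if clipped:
        _io.warn_clipped(clipped)
    depth = np.cumsum(delta[:G])
    return DepthProfile(ref_id=rid or "ref", depth=depth)


def call_deletion(
    profile: DepthProfile, max_depth: int = 0, min_run: int = 500, relative: bool = False
) -> list[DeletionEvent]:
    """Call candidate deletions as maximal low-coverage runs.

    A run is every maximal stretch of bases with depth <= ``max_depth``
    (or <= 5% of the median when ``relative`` is set, for noisy imported
    depth); runs shorter than ``min_run`` are discarded.  Each run
    ``s..e`` (1-based) is reported as ``DeletionEvent(L=s-1, R=e)``, ranked
    by length.  Runs starting at base 1 cannot be represented under the
    (left_retained, right_deleted) convention and are skipped.
    """
    d = profile.depth
    threshold = max_depth if not relative else max(max_depth, 0.05 * float(np.median(d)))
    low = d <= threshold
    if not low.any():
        return []
    padded = np.concatenate([[False], low, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[0::2], changes[1::2]  # 0-based half-open runs
    events = []
    for s, e in zip(starts, ends):
        if e - s < min_run or s == 0:
            continue
        events.append(DeletionEvent(left_retained=int(s), right_deleted=int(e)))
    events.sort(key=lambda ev: ev.length, reverse=True)
    return events


def junction_support(reads, junction: str, max_mismatch: int = 1) -> int:
    """Count reads containing the junction (or its reverse complement) with
    at most ``max_mismatch`` mismatches; the whole junction must lie within
    the read, so the match always covers the junction midpoint.

    Uses pigeonhole seeding: with ``m`` mismatches allowed, at least one of
    ``m + 1`` equal chunks of the junction must occur exactly.
    """
    if len(junction) < 40:
        raise ValueError("junction must be at least 2 x 20 nt")
    targets = [junction.upper(), reverse_complement(junction.upper())]
    jl = len(junction)
    nparts = max_mismatch + 1
    part_bounds = [(i * jl // nparts, (i + 1) * jl // nparts) for i in range(nparts)]
    count = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        seq = seq.upper()
        if _junction_in_read(seq, targets, part_bounds, jl, max_mismatch):
            count += 1
    return count


def _junction_in_read(seq, targets, part_bounds, jl, max_mismatch) -> bool:
    L = len(seq)
    if L < jl:
        return False
    for t in targets:
        seen: set[int] = set()
        for lo, hi in part_bounds:
            part = t[lo:hi]
            start = seq.find(part)
            while start != -1:
                off = start - lo
                if 0 <= off <= L - jl and off not in seen:
                    seen.add(off)
                    mism = sum(1 for a, b in zip(t, seq[off : off + jl]) if a != b)
                    if mism <= max_mismatch:
                        return True
                start = seq.find(part, start + 1)
    return False


def refine_breakpoints(
    candidate: DeletionEvent,
    reference: Genome,
    reads,
    alignments: list[AlignmentRecord] | None = None,
    search_radius: int = 20,
    flank: int = 20,
    max_mismatch: int = 0,
) -> tuple[DeletionEvent, int]:
    """Refine a low-coverage-run deletion call with junction-read evidence.

    A zero-coverage run can only overshoot the true deleted interval: the
    bases immediately flanking the junction are covered solely by reads
    whose footprint ends exactly at a breakpoint, and at finite depth such
    reads are missing from either side with appreciable probability.  The
    reads that *span* the junction are unmapped against the reference, so
    the true breakpoints are recovered by scoring candidate junction
    sequences against them: for every ``(L', R')`` with
    ``candidate.L <= L' <= candidate.L + search_radius`` and
    ``candidate.R - search_radius <= R' <= candidate.R``, count reads
    containing ``junction_sequence(reference, (L', R'), flank)`` and return
    the best-supported event (ties break toward the unrefined candidate).

    ``reads`` is an iterable of ``(read_id, seq)`` (or bare sequences); when
    ``alignments`` is given only reads unmapped there are scored.  Returns
    ``(event, support)``; with zero support the candidate is returned
    unchanged.
    """
    from .genome_model import junction_sequence  # deferred: avoid cycle at import

    pool = list(reads)
    if alignments is not None:
        unmapped = {a.read_id for a in alignments if not a.mapped}
        pool = [r for r in pool if isinstance(r, tuple) and r[0] in unmapped]
    seqs = [r[1] if isinstance(r, tuple) else r for r in pool]
    G = len(reference)
    best_event, best_support = candidate, 0
    for dl in range(search_radius + 1):
        L = candidate.left_retained + dl
        for dr in range(search_radius + 1):
            R = candidate.right_deleted - dr
            if R <= L or L < flank or R + flank > G:
                continue
            ev = DeletionEvent(L, R)
            support = junction_support(seqs, junction_sequence(reference, ev, flank), max_mismatch)
            if support > best_support:
                best_event, best_support = ev, support
    return best_event, best_support


def estimate_mixture(profile: DepthProfile, event: DeletionEvent, flank_width: int = 2000) -> float:
    """Estimate the wild-type frequency f_WT in a WT/deletion mixture as the
    ratio of mean depth inside the deleted interval to mean depth over the
    two flanks, clipped to [0, 1].

    The flanks are ``[L - flank_width + 1, L]`` and ``(R, R + flank_width]``
    (circular indexing).  Raises if the flank mean is zero.
    """
    if flank_width < 1:
        raise ValueError("flank_width must be positive")
    event.validate_against(len(profile))
    d = profile.depth
    G = len(profile)
    L, R = event.left_retained, event.right_deleted
    inside = d[L:R]
    flank_idx = np.concatenate([np.arange(L - flank_width, L), np.arange(R, R + flank_width)]) % G
    flank_mean = float(d[flank_idx].mean())
    if flank_mean == 0:
        raise ValueError("undefined mixture: flank mean depth is zero")
    return float(np.clip(inside.mean() / flank_mean, 0.0, 1.0))


def detect_step(
    profile: DepthProfile,
    grid: int = 100,
    min_arc_frac: float = 0.005,
    max_arc_frac: float = 0.20,
    refine: bool = True,
) -> StepCall:
    """Fit a circular two-change-point piecewise-constant depth model.

    Performs an exhaustive grid search over window starts and arc widths
    (both multiples of ``grid``; widths constrained to
    ``[min_arc_frac, max_arc_frac]`` of the reference), maximising the
    two-segment Poisson log-likelihood with segment-mean rates, then (with
    ``refine``) re-searches the winning cell at single-base resolution.
    Ties break toward the smaller window.  A constant profile returns fold
    1 with a degenerate null window.
    """
    d = profile.depth.astype(np.float64)
    G = d.size
    if grid < 1 or grid > G:
        raise ValueError("grid must be in [1, reference length]")
    if d.max() == d.min():
        rate = float(d[0])
        return StepCall(1, 1, rate, rate, 1.0, degenerate=True)
    c2 = np.concatenate([[0.0], np.cumsum(np.concatenate([d, d]))])
    total = float(d.sum())
    wmin_abs = max(1, int(math.ceil(min_arc_frac * G)))
    wmax = int(math.floor(max_arc_frac * G))
    wmin = max(grid, int(math.ceil(wmin_abs / grid)) * grid)
    if wmin > wmax:
        raise ValueError("min_arc exceeds max_arc for this reference length")

    def _search(start_values: np.ndarray, widths, score_floor: float, incumbent):
        best_score, best = score_floor, incumbent
        for w in widths:
            s_in = c2[start_values + w] - c2[start_values]
            s_out = total - s_in
            score = xlogy(s_in, s_in / w) + xlogy(s_out, s_out / (G - w))
            i = int(np.argmax(score))
            if score[i] > best_score + 1e-9:
                best_score = float(score[i])
                best = (int(start_values[i]), int(w))
        return best_score, best

    coarse_starts = np.arange(0, G, grid)
    best_score, best = _search(coarse_starts, range(wmin, wmax + 1, grid), -np.inf, None)
    if refine and grid > 1:
        s0, w0 = best
        fine_starts = np.arange(max(0, s0 - grid + 1), min(G - 1, s0 + grid - 1) + 1)
        fine_widths = range(max(wmin_abs, w0 - grid + 1), min(wmax, w0 + grid - 1) + 1)
        best_score, best = _search(fine_starts, fine_widths, best_score, best)
    start0, w = best
    s_in = float(c2[start0 + w] - c2[start0])
    rate_in = s_in / w
    rate_out = (total - s_in) / (G - w)
    fold = rate_in / rate_out if rate_out > 0 else math.inf
    return StepCall(
        window_start=start0 + 1,
        window_end=(start0 + w - 1) % G + 1,
        rate_in=rate_in,
        rate_out=rate_out,
        fold=fold,
    )
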