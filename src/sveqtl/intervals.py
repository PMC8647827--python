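"""Genomic interval algebra: overlap tests, strand-aware flanks, constrained
shuffling and multi-track collapse.

All coordinates are 0-based half-open internally.  1-based formats (VCF,
1-based BED dialects) are converted at the I/O boundary; see
:func:`to_zero_based` / :func:`to_one_based`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "overlaps",
    "directional_flank",
    "shuffle_intervals",
    "collapse_tracks",
    "to_zero_based",
    "to_one_based",
    "PlacementError",
]

#: rejection-sampling cap per interval before shuffling fails loudly
MAX_SHUFFLE_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """No valid placement found for an interval under the shuffle constraints."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} ({self.name})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def distance_to_point(self, pos: int) -> int:
        """bp distance from the interval to a point; 0 if the point is inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


def to_zero_based(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based closed coordinates -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open coordinates -> 1-based closed."""
    return start + 1, end


def overlaps(a: GenomicInterval, b: GenomicInterval, flank: int = 0) -> bool:
    """True iff ``a`` intersects ``b`` extended by ``flank`` bp on both sides.

    Half-open semantics: intervals sharing only a boundary do not overlap at
    flank 0.  A negative flank is an error.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if a.chrom != b.chrom:
        return False
    if a.start >= a.end or b.start - flank >= b.end + flank:
        return False  # an empty interval intersects nothing
    return a.start < b.end + flank and b.start - flank < a.end


def directional_flank(gene, which: str, size: int, chrom_length: int | None = None) -> GenomicInterval:
    """Strand-aware window immediately upstream of the TSS or downstream of the
    3' gene end, clipped at chromosome bounds.

    ``gene`` needs ``chrom``, ``start``, ``end`` and ``strand`` attributes.
    """
    if gene.strand not in ("+", "-"):
        raise ValueError(f"gene {getattr(gene, 'gene_id', gene)} is unstranded")
    if size < 0:
        raise ValueError("size must be non-negative")
    if which not in ("upstream_tss", "downstream_3prime"):
        raise ValueError(f"unknown flank kind {which!r}")
    # on '+' the TSS is gene.start and the 3' end gene.end; mirrored on '-'
    upstream = which == "upstream_tss"
    left_of_gene = upstream == (gene.strand == "+")
    if left_of_gene:
        lo, hi = gene.start - size, gene.start
    else:
        lo, hi = gene.end, gene.end + size
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    lo = min(lo, hi)
    return GenomicInterval(gene.chrom, lo, hi, strand=gene.strand)


def _in_any(chrom: str, start: int, end: int, ivs: Sequence[GenomicInterval]) -> bool:
    probe = GenomicInterval(chrom, start, end)
    return any(overlaps(probe, g) for g in ivs)


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    genome: dict[str, int],
    gaps: Sequence[GenomicInterval] = (),
    tss_list: Sequence[tuple[str, int]] | None = None,
    max_tss_distance: int | None = None,
    forbidden: Sequence[GenomicInterval] = (),
    n_shuffles: int = 1,
    seed: int | np.random.Generator = 0,
    max_attempts: int = MAX_SHUFFLE_ATTEMPTS,
) -> list[list[GenomicInterval]]:
    """Length-preserving constrained random placement of ``intervals``.

    Each placed interval lies wholly outside ``gaps``, intersects no
    ``forbidden`` interval, and (when ``tss_list`` and ``max_tss_distance``
    are given) lies within ``max_tss_distance`` bp of at least one TSS.
    Placement is rejection sampling from the uniform proposal over all
    (chromosome, start) positions where the interval fits, so accepted
    placements are uniform over the valid space.  Raises
    :class:`PlacementError` after ``max_attempts`` rejections for an interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    gaps_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in gaps:
        gaps_by_chrom.setdefault(g.chrom, []).append(g)
    forb_by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in forbidden:
        forb_by_chrom.setdefault(f.chrom, []).append(f)
    tss_by_chrom: dict[str, np.ndarray] = {}
    if tss_list is not None:
        for c, p in tss_list:
            tss_by_chrom.setdefault(c, []).append(p)  # type: ignore[arg-type]
        tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    out: list[list[GenomicInterval]] = []
    for _ in range(n_shuffles):
        placed: list[GenomicInterval] = []
        for iv in intervals:
            L = iv.length
            # weight chromosomes by the number of valid start positions
            fits = np.maximum(lengths - L + 1, 0.0)
            if fits.sum() == 0:
                raise PlacementError(f"interval {iv.name or iv} ({L} bp) fits on no chromosome")
            w = fits / fits.sum()
            for attempt in range(max_attempts):
                ci = rng.choice(len(chroms), p=w)
                chrom = chroms[ci]
                start = int(rng.integers(0, genome[chrom] - L + 1))
                end = start + L
                if _in_any(chrom, start, end, gaps_by_chrom.get(chrom, ())):
                    continue
                if _in_any(chrom, start, end, forb_by_chrom.get(chrom, ())):
                    continue
                if max_tss_distance is not None and tss_by_chrom is not None:
                    tss = tss_by_chrom.get(chrom)
                    if tss is None:
                        continue
                    # min distance from [start,end) to any TSS
                    j = np.searchsorted(tss, start)
                    cand = tss[max(j - 1, 0):j + 1]
                    probe = GenomicInterval(chrom, start, end)
                    if not any(probe.distance_to_point(int(p)) <= max_tss_distance for p in cand):
                        continue
                placed.append(GenomicInterval(chrom, start, end, strand=iv.strand, name=iv.name))
                break
            else:
                raise PlacementError(
                    f"no valid placement for interval {iv.name or iv} after {max_attempts} attempts"
                )
        out.append(placed)
    return out


def collapse_tracks(
    tracks: Sequence[Sequence[GenomicInterval]], min_support: int
) -> list[GenomicInterval]:
    """Maximal intervals covered by at least ``min_support`` of the tracks.

    Support at a base counts a track once even if several of its intervals
    cover the base.  Equivalent to per-base counting (asserted in tests by a
    brute-force oracle).
    """
    if not tracks:
        raise ValueError("at least one track required")
    if min_support > len(tracks):
        warnings.warn(
            f"min_support {min_support} exceeds track count {len(tracks)}; empty result",
            stacklevel=2,
        )
        return []
    # merge within each track first so a track contributes at most 1 per base
    events: dict[str, list[tuple[int, int]]] = {}
    for track in tracks:
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in track:
            per_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in per_chrom.items():
            ivs = sorted(ivs, key=lambda x: (x.start, x.end))
            cur_s, cur_e = ivs[0].start, ivs[0].end
            merged = []
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            merged.append((cur_s, cur_e))
            ev = events.setdefault(chrom, [])
            for s, e in merged:
                if e > s:
                    ev.append((s, +1))
                    ev.append((e, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        depth = 0
        run_start: int | None = None
        for i, (pos, delta) in enumerate(ev):
            # apply all events at this position before deciding
            if i + 1 < len(ev) and ev[i + 1][0] == pos:
                depth += delta
                continue
            depth += delta
            if depth >= min_support and run_start is None:
                run_start = pos
            elif depth < min_support and run_start is not None:
                out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    return out
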