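"""Genetic maps, IBD-segment calling, and genomic region set-algebra.

Pairwise identity-by-descent (IBD) sharing along the genome is summarised
by per-marker probabilities of sharing 0, 1 or 2 allele copies IBD
(Merlin-style ``--ibd`` output).  A segment shared IBD between two
relatives is the region spanned by consecutive markers at which
``P(IBD=1) + P(IBD=2)`` exceeds a threshold (0.5 by default).  Candidate
regions for a dominant variant shared by two patients are the
patient-pair segments minus any region also shared pairwise, with both
patients, by an unaffected sib.

Coordinates
-----------
Marker and variant positions are 1-based on input (VCF / linkage-file
convention).  Internally every interval is 0-based half-open
``[start, end)``; the conversion happens exactly once at the I/O
boundary, so a 1-based inclusive marker span ``[100, 200]`` becomes the
interval ``[99, 200)`` and is written to BED as ``start=99 end=200``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "IbdTrack",
    "IbdSegment",
    "RegionSet",
    "interpolate_cm",
    "call_ibd_segments",
    "intersect",
    "subtract",
    "union",
    "candidate_regions",
    "read_genetic_map",
    "read_ibd_table",
    "write_ibd_table",
    "write_bed",
    "read_bed",
]


class GeneticMap:
    """Piecewise-linear bp -> cM map, one anchor list per chromosome.

    Anchors must have strictly increasing bp and non-decreasing cM within
    each chromosome, with at least two anchors so interpolation is
    defined.  Queries outside the anchored range are clamped to the
    terminal anchor's cM value (never extrapolated, which could produce
    negative genetic positions).
    """

    def __init__(self, anchors: Mapping[str, Sequence[tuple[int, float]]]):
        self._bp: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        for chrom, pts in anchors.items():
            if len(pts) < 2:
                raise ValueError(
                    f"chromosome {chrom!r}: need >= 2 map anchors, got {len(pts)}"
                )
            bp = np.asarray([p[0] for p in pts], dtype=np.int64)
            cm = np.asarray([p[1] for p in pts], dtype=float)
            if np.any(bp[1:] <= bp[:-1]):
                raise ValueError(f"chromosome {chrom!r}: bp anchors not strictly increasing")
            if np.any(cm[1:] < cm[:-1]):
                raise ValueError(f"chromosome {chrom!r}: cM anchors decrease")
            if np.any(bp < 1) or np.any(cm < 0):
                raise ValueError(f"chromosome {chrom!r}: anchors must have bp >= 1, cM >= 0")
            self._bp[chrom] = bp
            self._cm[chrom] = cm

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bp)

    def anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        self._check(chrom)
        return self._bp[chrom], self._cm[chrom]

    def _check(self, chrom: str) -> None:
        if chrom not in self._bp:
            raise KeyError(f"chromosome {chrom!r} not present in genetic map")

    def interpolate(self, chrom: str, bp_position) -> np.ndarray | float:
        """Genetic position (cM) at ``bp_position``, clamped at the map ends."""
        self._check(chrom)
        # np.interp is exactly piecewise-linear with terminal clamping
        out = np.interp(bp_position, self._bp[chrom], self._cm[chrom])
        if np.ndim(bp_position) == 0:
            return float(out)
        return out


def interpolate_cm(gmap: GeneticMap, chrom: str, bp_position) -> float | np.ndarray:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, bp_position)


@dataclass(frozen=True)
class IbdSegment:
    """One shared-IBD segment: 0-based half-open, with supporting marker count."""

    chrom: str
    start: int
    end: int
    n_markers: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.n_markers < 1:
            raise ValueError("segment must be supported by >= 1 marker")


class IbdTrack:
    """Per-marker IBD sharing probabilities for one unordered sample pair.

    ``markers`` maps chromosome -> array of shape (m, 4) with columns
    (position_bp, p0, p1, p2); positions are 1-based and strictly
    increasing, probabilities sum to 1 within ``tol``.
    """

    def __init__(
        self,
        pair: tuple[str, str],
        markers: Mapping[str, np.ndarray | Sequence[tuple]],
        tol: float = 1e-6,
    ):
        self.pair = tuple(sorted(map(str, pair)))
        self.markers: dict[str, np.ndarray] = {}
        for chrom, arr in markers.items():
            a = np.asarray(arr, dtype=float)
            if a.size == 0:
                continue
            if a.ndim != 2 or a.shape[1] != 4:
                raise ValueError(f"chromosome {chrom!r}: expected (m, 4) marker array")
            pos, probs = a[:, 0], a[:, 1:]
            if np.any(pos[1:] <= pos[:-1]):
                raise ValueError(f"chromosome {chrom!r}: marker positions not strictly increasing")
            if np.any(probs < -tol) or np.any(probs > 1 + tol):
                raise ValueError(f"chromosome {chrom!r}: probabilities outside [0, 1]")
            bad = np.abs(probs.sum(axis=1) - 1.0) > tol
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValueError(
                    f"chromosome {chrom!r}, marker {int(pos[i])}: "
                    f"p0+p1+p2 = {probs[i].sum():.6g} != 1"
                )
            self.markers[chrom] = a

    @property
    def chromosomes(self) -> list[str]:
        return list(self.markers)

    def __repr__(self) -> str:
        n = sum(len(a) for a in self.markers.values())
        return f"IbdTrack(pair={self.pair}, {n} markers on {len(self.markers)} chromosomes)"


class RegionSet:
    """Per-chromosome sorted, disjoint, non-abutting half-open intervals.

    The canonical container for genomic region algebra: constructed from
    arbitrary intervals, normalised on construction (sort, merge overlaps
    and abutments, drop empties).
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._ivs: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                arr = self._normalize(ivs)
                if len(arr):
                    self._ivs[chrom] = arr

    @staticmethod
    def _normalize(ivs: Iterable[tuple[int, int]]) -> np.ndarray:
        rows = []
        for s, e in ivs:
            s, e = int(s), int(e)
            if s < 0:
                raise ValueError(f"interval start {s} < 0")
            if s < e:
                rows.append((s, e))
            elif s > e:
                raise ValueError(f"interval start {s} > end {e}")
        if not rows:
            return np.empty((0, 2), dtype=np.int64)
        rows.sort()
        merged = [list(rows[0])]
        for s, e in rows[1:]:
            if s <= merged[-1][1]:  # overlap or abut
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._ivs)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivs.get(chrom, np.empty((0, 2), dtype=np.int64))

    def items(self):
        for chrom in self.chromosomes:
            yield chrom, self._ivs[chrom]

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._ivs.values()))

    def is_empty(self) -> bool:
        return not self._ivs

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivs.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._ivs) != set(other._ivs):
            return False
        return all(np.array_equal(self._ivs[c], other._ivs[c]) for c in self._ivs)

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals on {len(self._ivs)} chromosomes, {self.total_length()} bp)"

    def contains(self, chrom: str, position_1based: int) -> bool:
        """Membership of a 1-based position (e.g. a variant coordinate)."""
        p = int(position_1based) - 1
        arr = self.intervals(chrom)
        if not len(arr):
            return False
        i = bisect.bisect_right(arr[:, 0].tolist(), p) - 1
        return i >= 0 and p < arr[i, 1]


def _merge_chroms(a: RegionSet, b: RegionSet) -> set[str]:
    return set(a.chromosomes) | set(b.chromosomes)


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Positions present in both region sets."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in _merge_chroms(a, b):
        ia, ib = a.intervals(chrom), b.intervals(chrom)
        res, i, j = [], 0, 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if s < e:
                res.append((int(s), int(e)))
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
        if res:
            out[chrom] = res
    return RegionSet(out)


def subtract(a: RegionSet, b: RegionSet) -> RegionSet:
    """Positions present in ``a`` and not in ``b``."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ia in a.items():
        ib = b.intervals(chrom)
        res = []
        j = 0
        for s, e in ia:
            cur = int(s)
            while j < len(ib) and ib[j, 1] <= cur:
                j += 1
            k = j
            while k < len(ib) and ib[k, 0] < e:
                if ib[k, 0] > cur:
                    res.append((cur, int(ib[k, 0])))
                cur = max(cur, int(ib[k, 1]))
                k += 1
            if cur < e:
                res.append((cur, int(e)))
        if res:
            out[chrom] = res
    return RegionSet(out)


def union(a: RegionSet, b: RegionSet) -> RegionSet:
    """Positions present in either region set."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in _merge_chroms(a, b):
        ivs = [tuple(map(int, r)) for r in a.intervals(chrom)]
        ivs += [tuple(map(int, r)) for r in b.intervals(chrom)]
        if ivs:
            out[chrom] = ivs
    return RegionSet(out)


def call_ibd_segments(track: IbdTrack, threshold: float = 0.5) -> RegionSet:
    """Call shared-IBD segments: maximal runs of markers with p1 + p2 > threshold.

    A run of qualifying markers spans from its first to its last marker
    inclusive (1-based), i.e. the half-open interval
    ``[first_bp - 1, last_bp)``; a single qualifying marker yields a 1-bp
    segment.  The flanking non-qualifying markers do not extend the
    segment.  The strict ``>`` comparison matches the conventional
    ``P(IBD=1) + P(IBD=2) > 0.5`` rule.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, arr in track.markers.items():
        share = arr[:, 2] + arr[:, 3] > threshold
        if not share.any():
            continue
        pos = arr[:, 0].astype(np.int64)
        # boundaries of runs of True
        padded = np.concatenate(([False], share, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        ivs = [(int(pos[s]) - 1, int(pos[e])) for s, e in zip(starts, ends)]
        out[chrom] = ivs
    return RegionSet(out)


def call_ibd_segment_list(track: IbdTrack, threshold: float = 0.5) -> list[IbdSegment]:
    """Like :func:`call_ibd_segments` but keeping supporting marker counts."""
    segs: list[IbdSegment] = []
    for chrom, arr in track.markers.items():
        share = arr[:, 2] + arr[:, 3] > threshold
        pos = arr[:, 0].astype(np.int64)
        padded = np.concatenate(([False], share, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        for s, e in zip(starts, ends):
            segs.append(
                IbdSegment(chrom, int(pos[s]) - 1, int(pos[e]), int(e - s + 1))
            )
    return segs


def candidate_regions(
    patient_pair_track: IbdTrack,
    sib_vs_patient_tracks: Sequence[tuple[IbdTrack, IbdTrack]] = (),
    threshold: float = 0.5,
) -> RegionSet:
    """Candidate regions for a dominantly-shared variant.

    Start from S, the regions shared IBD by the two patients; for each
    unaffected sib (contributing one track against each patient) remove
    the part of S where the sib is pairwise-IBD with *both* patients:

        S  -  union over sibs of  S ∩ seg(sib, patient1) ∩ seg(sib, patient2)

    This pairwise-conjunction rule approximates three-way sharing of one
    haplotype, which pairwise probability tracks cannot resolve exactly.
    """
    shared = call_ibd_segments(patient_pair_track, threshold)
    excluded = RegionSet()
    for pair in sib_vs_patient_tracks:
        if len(pair) != 2 or pair[0] is None or pair[1] is None:
            raise ValueError("each sib must contribute two tracks (sib vs each patient)")
        t1, t2 = pair
        sib_both = intersect(call_ibd_segments(t1, threshold), call_ibd_segments(t2, threshold))
        excluded = union(excluded, intersect(shared, sib_both))
    return subtract(shared, excluded)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a 3-column text map (chrom, bp, cM); '#' lines are comments."""
    anchors: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns (chrom, bp, cM)")
            try:
                anchors.setdefault(parts[0], []).append((int(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tbp\tcM\n")
        for chrom in gmap.chromosomes:
            bp, cm = gmap.anchors(chrom)
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{int(b)}\t{c:.10g}\n")


def read_ibd_table(path: str | Path, tol: float = 1e-6) -> list[IbdTrack]:
    """Read a whitespace-delimited IBD probability table.

    Columns: pair ("id1,id2"), chromosome, 1-based marker position,
    P(IBD=0), P(IBD=1), P(IBD=2).  Malformed lines and probability
    triples that do not sum to 1 (within ``tol``) are rejected with the
    offending line number.
    """
    rows: dict[tuple[str, ...], dict[str, list[tuple]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            try:
                pair = tuple(sorted(parts[0].split(",")))
                chrom = parts[1]
                pos = int(parts[2])
                p0, p1, p2 = (float(x) for x in parts[3:6])
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed field") from None
            if len(pair) != 2:
                raise ValueError(f"{path}:{ln}: pair must be 'id1,id2', got {parts[0]!r}")
            if abs(p0 + p1 + p2 - 1.0) > tol:
                raise ValueError(
                    f"{path}:{ln}: probabilities sum to {p0 + p1 + p2:.6g}, not 1"
                )
            rows.setdefault(pair, {}).setdefault(chrom, []).append((pos, p0, p1, p2))
    return [IbdTrack(pair, markers, tol=tol) for pair, markers in rows.items()]


def write_ibd_table(tracks: Iterable[IbdTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#pair\tchrom\tpos\tp0\tp1\tp2\n")
        for tr in tracks:
            pair = ",".join(tr.pair)
            for chrom, arr in tr.markers.items():
                for pos, p0, p1, p2 in arr:
                    fh.write(
                        f"{pair}\t{chrom}\t{int(pos)}\t{p0:.17g}\t{p1:.17g}\t{p2:.17g}\n"
                    )


def write_bed(regions: RegionSet, path: str | Path, name: str | None = None) -> None:
    """Write regions as BED (0-based half-open), sorted by chromosome then start."""
    with open(path, "w") as fh:
        for chrom, ivs in regions.items():
            for s, e in ivs:
                row = f"{chrom}\t{int(s)}\t{int(e)}"
                if name:
                    row += f"\t{name}"
                fh.write(row + "\n")


def read_bed(path: str | Path) -> RegionSet:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed coordinates") from None
    return RegionSet(out)
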