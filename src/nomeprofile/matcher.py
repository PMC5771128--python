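"""CpG-cluster detection and CpG-count-matched control region selection.

To ask whether promoter-like chromatin features are caused by CpG
organization or by transcription, the analysis compares each promoter with
a non-promoter region of matching CpG content.  Candidates come from CpG
clusters: maximal runs of CpG sites with successive gaps below 20 bp,
merged when neighbouring clusters lie closer than 50 bp.  Around each
merged cluster's center a window of +/- 1000 bp is placed, and the center
is then shifted until the number of CpG sites on each side of the center
equals the number on either side of the promoter's TSS — an exact,
per-side match.  Regions intersecting +/- 1000 bp of any TSS are excluded
so controls are genuinely non-promoter.

Determinism: shifted centers are tried by ascending absolute offset
(negative first on ties, never beyond the halfwidth); promoters are
processed in ascending genomic order and take the first usable candidate
in genomic order, each candidate at most once.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_sites import SitePositions
from .profiler import Anchor, AnchorSet

__all__ = [
    "CpGCluster",
    "CandidateRegion",
    "MatchResult",
    "ExclusionZones",
    "detect_clusters",
    "merge_clusters",
    "candidate_regions",
    "build_exclusion",
    "promoter_side_counts",
    "match_one",
    "match_all",
    "write_clusters_bed",
    "write_matches_tsv",
    "read_matches_tsv",
    "matches_to_anchors",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CpGCluster:
    """A run of CpG sites; start/end are the first/last member (0-based, inclusive)."""

    chrom: str
    start: int
    end: int
    n_sites: int

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass(frozen=True)
class CandidateRegion:
    """A 2*halfwidth+1 bp window centered on a merged cluster."""

    chrom: str
    center: int
    halfwidth: int
    cluster_id: int


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """A promoter paired with a control region of identical per-side CpG counts."""

    promoter_id: str
    chrom: str
    center: int
    left_n: int
    right_n: int
    promoter_left: int
    promoter_right: int


class ExclusionZones:
    """Merged, sorted intervals (inclusive coordinates) per chromosome."""

    def __init__(self, zones: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.zones = zones

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self.zones.values())

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end] overlaps any zone on the chromosome."""
        if chrom not in self.zones:
            return False
        starts, ends = self.zones[chrom]
        i = int(np.searchsorted(starts, end, side="right"))
        return i > 0 and ends[i - 1] >= start

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self.zones:
            return []
        starts, ends = self.zones[chrom]
        return list(zip(starts.tolist(), ends.tolist()))


def detect_clusters(cpg_positions: SitePositions, max_intra_gap: int = 20) -> list[CpGCluster]:
    """Maximal runs of CpG sites with successive gaps < max_intra_gap.

    Singleton sites form singleton clusters.
    """
    pos = cpg_positions.positions
    if pos.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) >= max_intra_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos.size - 1]))
    return [
        CpGCluster(cpg_positions.chrom, int(pos[s]), int(pos[e]), int(e - s + 1))
        for s, e in zip(starts, ends)
    ]


def merge_clusters(clusters: Sequence[CpGCluster], max_inter_gap: int = 50) -> list[CpGCluster]:
    """Transitively merge adjacent clusters closer than max_inter_gap.

    Member counts are summed; input must be sorted and non-overlapping.
    """
    out: list[CpGCluster] = []
    for c in clusters:
        if out and c.chrom == out[-1].chrom and c.start - out[-1].end < max_inter_gap:
            prev = out[-1]
            if c.start < prev.start:
                raise ValueError("clusters must be sorted")
            out[-1] = CpGCluster(prev.chrom, prev.start, max(prev.end, c.end),
                                 prev.n_sites + c.n_sites)
        else:
            out.append(c)
    return out


def candidate_regions(
    clusters: Sequence[CpGCluster],
    halfwidth: int = 1000,
    chrom_length: int | None = None,
) -> list[CandidateRegion]:
    """One candidate window per cluster, centered on its midpoint (rounded down).

    Clusters whose window would leave the chromosome are flagged and skipped.
    """
    out = []
    for i, c in enumerate(clusters):
        center = c.center
        if center - halfwidth < 0 or (chrom_length is not None and center + halfwidth >= chrom_length):
            log.warning("cluster %d at %s:%d-%d too close to a chromosome end; skipped",
                        i, c.chrom, c.start, c.end)
            continue
        out.append(CandidateRegion(c.chrom, center, halfwidth, i))
    return out


def build_exclusion(promoters: AnchorSet | Sequence[Anchor], halfwidth: int = 1000) -> ExclusionZones:
    """Merged intervals [tss - halfwidth, tss + halfwidth] per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for a in promoters:
        by_chrom.setdefault(a.chrom, []).append((a.pos - halfwidth, a.pos + halfwidth))
    zones = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        zones[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
    return ExclusionZones(zones)


def _side_counts(pos: np.ndarray, center, halfwidth: int):
    """CpG counts in [center - H, center) and (center, center + H].

    A site exactly at the center belongs to neither side.  ``center`` may be
    an array (vectorized over shifted centers).
    """
    c = np.asarray(center)
    left = np.searchsorted(pos, c, side="left") - np.searchsorted(pos, c - halfwidth, side="left")
    right = np.searchsorted(pos, c + halfwidth, side="right") - np.searchsorted(pos, c, side="right")
    return left, right


def promoter_side_counts(anchor: Anchor, cpg_positions: SitePositions, halfwidth: int = 1000) -> tuple[int, int]:
    """(left, right) CpG counts around a TSS in the promoter's orientation.

    "Left" means upstream of the TSS, so the two counts swap for
    minus-strand promoters.  The TSS position itself counts to neither side.
    """
    left, right = _side_counts(cpg_positions.positions, anchor.pos, halfwidth)
    if anchor.strand == "-":
        left, right = right, left
    return int(left), int(right)


def _offsets(max_shift: int) -> np.ndarray:
    """0, -1, +1, -2, +2, ... up to +/- max_shift."""
    k = np.arange(1, max_shift + 1)
    out = np.empty(2 * max_shift + 1, dtype=np.int64)
    out[0] = 0
    out[1::2] = -k
    out[2::2] = k
    return out


def match_one(
    promoter_counts: tuple[int, int],
    region: CandidateRegion,
    cpg_positions: SitePositions,
    zones: ExclusionZones,
    max_shift: int | None = None,
) -> int | None:
    """Find a shifted center with exact per-side CpG counts, outside all zones.

    Offsets are scanned by ascending |offset|, negative first on ties, up to
    ``max_shift`` (default: the region halfwidth, so the center never leaves
    the original candidate span).  Returns the matching center coordinate or
    ``None`` (no-match is a value, not an error).
    """
    H = region.halfwidth
    if max_shift is None:
        max_shift = H
    want_l, want_r = promoter_counts
    pos = cpg_positions.positions
    centers = region.center + _offsets(max_shift)
    left, right = _side_counts(pos, centers, H)
    for c in centers[(left == want_l) & (right == want_r)]:
        c = int(c)
        if not zones.intersects(region.chrom, c - H, c + H):
            return c
    return None


def match_all(
    promoters: AnchorSet | Sequence[Anchor],
    candidates: Sequence[CandidateRegion],
    cpg_by_chrom: dict[str, SitePositions],
    zones: ExclusionZones,
    halfwidth: int = 1000,
    *,
    disjoint_controls: bool = False,
) -> tuple[list[MatchResult], list[str]]:
    """Assign each promoter the first usable candidate, without reuse.

    Promoters are processed in ascending genomic order and candidates tried
    in ascending genomic order; a candidate serves at most one promoter.
    With ``disjoint_controls`` every accepted control additionally extends
    the exclusion zones, making controls mutually disjoint.  Returns the
    matches plus the ids of unmatched promoters.
    """
    cand = sorted(range(len(candidates)), key=lambda i: (candidates[i].chrom, candidates[i].center))
    used = np.zeros(len(candidates), dtype=bool)
    extra: dict[str, list[tuple[int, int]]] = {}
    matches: list[MatchResult] = []
    unmatched: list[str] = []

    proms = sorted(promoters, key=lambda a: (a.chrom, a.pos, a.id))
    for prom in proms:
        cpg = cpg_by_chrom[prom.chrom]
        want = promoter_side_counts(prom, cpg, halfwidth)
        total = want[0] + want[1]
        found = None
        for ci in cand:
            if used[ci]:
                continue
            r = candidates[ci]
            if r.chrom != prom.chrom:
                continue
            # quick reject: the shifted window always lies within +/- 2H of
            # the original center, so it can never see more CpGs than that span holds
            pos = cpg.positions
            avail = int(np.searchsorted(pos, r.center + 2 * r.halfwidth, side="right")
                        - np.searchsorted(pos, r.center - 2 * r.halfwidth, side="left"))
            if avail < total:
                continue
            c = match_one(want, r, cpg, zones)
            if c is not None and disjoint_controls:
                if any(s <= c + halfwidth and e >= c - halfwidth
                       for s, e in extra.get(r.chrom, [])):
                    c = None
            if c is not None:
                used[ci] = True
                l, rr = _side_counts(pos, c, halfwidth)
                matches.append(MatchResult(prom.id, r.chrom, c, int(l), int(rr), want[0], want[1]))
                if disjoint_controls:
                    extra.setdefault(r.chrom, []).append((c - halfwidth, c + halfwidth))
                found = c
                break
        if found is None:
            unmatched.append(prom.id)
    return matches, unmatched


def matches_to_anchors(matches: Sequence[MatchResult]) -> AnchorSet:
    """Control-region centers as unstranded anchors (windows use + orientation)."""
    return AnchorSet(
        Anchor(id=f"ctrl_{m.promoter_id}", chrom=m.chrom, pos=m.center, strand=".")
        for m in matches
    )


# -- serialization ---------------------------------------------------------

def write_clusters_bed(clusters: Sequence[CpGCluster], path: str | Path) -> None:
    """Clusters as BED (0-based half-open); score column = member CpG count."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end + 1}\tcluster_{i}\t{c.n_sites}\n")


def write_controls_bed(matches: Sequence[MatchResult], path: str | Path,
                       halfwidth: int = 1000) -> None:
    """Matched control regions as BED spans (0-based half-open).

    Name column carries the source promoter id, score the total matched
    CpG count.
    """
    with open(path, "w") as fh:
        for m in matches:
            fh.write(f"{m.chrom}\t{m.center - halfwidth}\t{m.center + halfwidth + 1}\t"
                     f"{m.promoter_id}\t{m.left_n + m.right_n}\n")


def write_matches_tsv(matches: Sequence[MatchResult], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in matches]).to_csv(path, sep="\t", index=False)


def read_matches_tsv(path: str | Path) -> list[MatchResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        MatchResult(str(r.promoter_id), str(r.chrom), int(r.center), int(r.left_n),
                    int(r.right_n), int(r.promoter_left), int(r.promoter_right))
        for r in df.itertuples()
    ]
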