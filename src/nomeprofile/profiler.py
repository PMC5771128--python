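"""Anchor-aligned average profiles of occupancy, methylation and CpG density.

The central operation of the analysis: for a set of oriented anchor points
(TSSs, or matched control-region centers) extract a window of +/- ``halfwidth``
base pairs, orient it so that positive relative positions are downstream of
the anchor, and average the three tracks position by position over all
windows:

* nucleosome occupancy (1 - GpC methylation) — averaged over windows that
  have a covered GpC measurement at that position; uncovered windows are
  disregarded, not zero-filled;
* CpG methylation level — same masking rule;
* CpG density — fraction of windows carrying a CpG at that position, with
  the denominator always the full window set.  A genomic CpG that already
  contributed to an earlier window is excluded from later windows' density
  numerators so overlapping windows do not double-count it.

Profiles are optionally smoothed with a centered moving average (default
30 bp; for an even width w the window spans i - w//2 .. i + w - w//2 - 1,
truncated at the profile edges).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_sites import SitePositions
from .signal import SiteTable, occupancy_from_gpc

__all__ = [
    "Anchor",
    "AnchorSet",
    "Window",
    "Profile",
    "ProfilerError",
    "EXCLUDED",
    "extract_window",
    "extract_windows",
    "dedup_cpg_indicators",
    "average_profiles",
    "smooth",
    "locate_extremum",
    "fit_gaussian_dip",
    "dominant_period",
]

log = logging.getLogger(__name__)

EXCLUDED = np.int8(-1)  # CpG indicator state: site already counted in an earlier window


class ProfilerError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Anchor:
    """An oriented anchor point (TSS or region center).

    ``strand`` is '+', '-' or '.' (unstranded); ``expression`` is an
    optional non-negative value in arbitrary units.
    """

    id: str
    chrom: str
    pos: int
    strand: str = "."
    expression: float | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-", "."):
            raise ProfilerError(f"bad strand {self.strand!r}")
        if self.expression is not None and self.expression < 0:
            raise ProfilerError(f"negative expression on {self.id}")


class AnchorSet:
    """Ordered collection of anchors with BED6(+expression) I/O."""

    def __init__(self, anchors: Iterable[Anchor]):
        self.anchors: list[Anchor] = list(anchors)
        ids = [a.id for a in self.anchors]
        if len(set(ids)) != len(ids):
            raise ProfilerError("anchor ids must be unique")

    def __iter__(self):
        return iter(self.anchors)

    def __len__(self):
        return len(self.anchors)

    def __getitem__(self, i):
        return self.anchors[i]

    def sorted_genomic(self) -> "AnchorSet":
        return AnchorSet(sorted(self.anchors, key=lambda a: (a.chrom, a.pos, a.id)))

    def by_id(self) -> dict[str, Anchor]:
        return {a.id: a for a in self.anchors}

    def write_bed(self, path: str | Path) -> None:
        """BED6 with the expression value in column 7 (when present)."""
        with open(path, "w") as fh:
            for a in self.anchors:
                cols = [a.chrom, str(a.pos), str(a.pos + 1), a.id, "0", a.strand]
                if a.expression is not None:
                    cols.append(repr(float(a.expression)))
                fh.write("\t".join(cols) + "\n")

    @classmethod
    def read_bed(cls, path: str | Path) -> "AnchorSet":
        anchors = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                expr = float(f[6]) if len(f) > 6 else None
                anchors.append(
                    Anchor(id=f[3], chrom=f[0], pos=int(f[1]),
                           strand=f[5] if len(f) > 5 else ".", expression=expr)
                )
        return cls(anchors)


@dataclasses.dataclass
class Window:
    """One extracted, oriented window of 2*halfwidth + 1 relative positions.

    Track arrays are indexed by relative position + halfwidth.  ``flipped``
    records whether the window was reversed (minus-strand anchor with
    orientation on), which is needed to map indicator indices back to
    genomic coordinates.
    """

    anchor: Anchor
    halfwidth: int
    occupancy: np.ndarray  # float, NaN = missing
    methylation: np.ndarray  # float, NaN = missing
    cpg: np.ndarray  # int8: 0, 1, or EXCLUDED
    flipped: bool = False

    def __post_init__(self):
        n = 2 * self.halfwidth + 1
        for arr in (self.occupancy, self.methylation, self.cpg):
            if arr.shape != (n,):
                raise ProfilerError("window tracks must have 2*halfwidth + 1 positions")

    def genomic_coord(self, idx) -> np.ndarray:
        """Genomic coordinate of window index/indices (0 .. 2*halfwidth)."""
        rel = np.asarray(idx) - self.halfwidth
        return self.anchor.pos - rel if self.flipped else self.anchor.pos + rel

    def copy(self) -> "Window":
        return Window(self.anchor, self.halfwidth, self.occupancy.copy(),
                      self.methylation.copy(), self.cpg.copy(), self.flipped)


@dataclasses.dataclass
class Profile:
    """Per-relative-position averages over a window set.

    Means are NaN wherever no window contributed (count 0); ``cpg_density``
    is defined everywhere with the full window count as denominator.
    """

    rel: np.ndarray
    occ_mean: np.ndarray
    occ_n: np.ndarray
    meth_mean: np.ndarray
    meth_n: np.ndarray
    cpg_density: np.ndarray
    n_windows: int

    @property
    def halfwidth(self) -> int:
        return (len(self.rel) - 1) // 2

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "rel_pos": self.rel,
                "occ_mean": self.occ_mean,
                "occ_n": self.occ_n,
                "meth_mean": self.meth_mean,
                "meth_n": self.meth_n,
                "cpg_density": self.cpg_density,
                "n_windows": self.n_windows,
            }
        )
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Profile":
        df = pd.read_csv(path, sep="\t", na_values="NA")
        return cls(
            rel=df["rel_pos"].to_numpy(np.int64),
            occ_mean=df["occ_mean"].to_numpy(float),
            occ_n=df["occ_n"].to_numpy(np.int64),
            meth_mean=df["meth_mean"].to_numpy(float),
            meth_n=df["meth_n"].to_numpy(np.int64),
            cpg_density=df["cpg_density"].to_numpy(float),
            n_windows=int(df["n_windows"].iloc[0]) if len(df) else 0,
        )


def extract_window(
    sites: SiteTable,
    cpg_positions: SitePositions,
    anchor: Anchor,
    halfwidth: int = 1000,
    *,
    orient: bool = True,
    min_total: float = 1,
    chrom_length: int | None = None,
) -> Window | None:
    """Extract one oriented window around an anchor.

    Relative position r maps to genomic coordinate ``anchor.pos + r`` on the
    plus strand (and for unstranded anchors) and ``anchor.pos - r`` on the
    minus strand when ``orient`` is set.  Occupancy is filled from covered
    GpC measurements as 1 - level, methylation from covered CpG
    measurements, and the CpG indicator from the genome's CpG positions.

    Out-of-bounds anchors are flagged and skipped (returns ``None``), not
    silently dropped by the caller.
    """
    H = halfwidth
    lo, hi = anchor.pos - H, anchor.pos + H
    if lo < 0 or (chrom_length is not None and hi >= chrom_length):
        log.warning("anchor %s at %s:%d out of bounds for halfwidth %d; skipped",
                    anchor.id, anchor.chrom, anchor.pos, H)
        return None
    n = 2 * H + 1
    occ = np.full(n, np.nan)
    meth = np.full(n, np.nan)
    cpg = np.zeros(n, dtype=np.int8)

    gpos, glev = sites.levels(anchor.chrom, "GpC", min_total)
    a, b = np.searchsorted(gpos, (lo, hi + 1))
    occ[gpos[a:b] - lo] = occupancy_from_gpc(glev[a:b])

    cpos, clev = sites.levels(anchor.chrom, "CpG", min_total)
    a, b = np.searchsorted(cpos, (lo, hi + 1))
    meth[cpos[a:b] - lo] = clev[a:b]

    if cpg_positions.chrom != anchor.chrom:
        raise ProfilerError(
            f"CpG positions are for {cpg_positions.chrom!r}, anchor on {anchor.chrom!r}")
    ipos = cpg_positions.positions
    a, b = np.searchsorted(ipos, (lo, hi + 1))
    cpg[ipos[a:b] - lo] = 1

    flipped = orient and anchor.strand == "-"
    if flipped:
        occ, meth, cpg = occ[::-1].copy(), meth[::-1].copy(), cpg[::-1].copy()
    return Window(anchor, H, occ, meth, cpg, flipped)


def extract_windows(
    sites: SiteTable,
    cpg_by_chrom: dict[str, SitePositions],
    anchors: AnchorSet | Sequence[Anchor],
    halfwidth: int = 1000,
    *,
    orient: bool = True,
    min_total: float = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[Window], list[Anchor]]:
    """Extract windows for many anchors; returns (windows, skipped anchors)."""
    windows, skipped = [], []
    for a in anchors:
        clen = chrom_lengths.get(a.chrom) if chrom_lengths else None
        w = extract_window(sites, cpg_by_chrom[a.chrom], a, halfwidth,
                           orient=orient, min_total=min_total, chrom_length=clen)
        (windows if w is not None else skipped).append(w if w is not None else a)
    return windows, skipped


def dedup_cpg_indicators(windows: Sequence[Window]) -> list[Window]:
    """Mark CpG indicators already counted by an earlier window as excluded.

    Windows are visited in ascending (chromosome, anchor position) order;
    each genomic CpG site keeps indicator 1 in the first window containing
    it and becomes ``EXCLUDED`` in every later window.  The returned list
    preserves the input order; inputs are not mutated.
    """
    out = [w.copy() for w in windows]
    order = sorted(range(len(out)),
                   key=lambda i: (out[i].anchor.chrom, out[i].anchor.pos, out[i].anchor.id))
    seen: dict[str, set[int]] = {}
    for i in order:
        w = out[i]
        chrom_seen = seen.setdefault(w.anchor.chrom, set())
        idxs = np.flatnonzero(w.cpg == 1)
        coords = w.genomic_coord(idxs)
        for idx, g in zip(idxs, coords):
            g = int(g)
            if g in chrom_seen:
                w.cpg[idx] = EXCLUDED
            else:
                chrom_seen.add(g)
    return out


def average_profiles(windows: Sequence[Window] | Iterable[Window]) -> Profile:
    """Average many windows into a single profile.

    At each relative position the occupancy and methylation means run over
    windows with a measurement there (missing windows are disregarded and
    the contributing count recorded); CpG density is the count of
    indicator-1 windows divided by the total number of windows, so excluded
    indicators lower the numerator but never the denominator.
    """
    it = iter(windows)
    try:
        first = next(it)
    except StopIteration:
        raise ProfilerError("cannot average an empty window list") from None
    H = first.halfwidth
    n = 2 * H + 1
    occ_sum = np.zeros(n)
    occ_n = np.zeros(n, dtype=np.int64)
    meth_sum = np.zeros(n)
    meth_n = np.zeros(n, dtype=np.int64)
    cpg_sum = np.zeros(n, dtype=np.int64)
    n_windows = 0
    for w in [first, *it]:
        if w.halfwidth != H:
            raise ProfilerError("all windows must share one halfwidth")
        n_windows += 1
        m = np.isfinite(w.occupancy)
        occ_sum[m] += w.occupancy[m]
        occ_n += m
        m = np.isfinite(w.methylation)
        meth_sum[m] += w.methylation[m]
        meth_n += m
        cpg_sum += (w.cpg == 1)
    with np.errstate(invalid="ignore"):
        occ_mean = np.where(occ_n > 0, occ_sum / np.maximum(occ_n, 1), np.nan)
        meth_mean = np.where(meth_n > 0, meth_sum / np.maximum(meth_n, 1), np.nan)
    return Profile(
        rel=np.arange(-H, H + 1, dtype=np.int64),
        occ_mean=occ_mean,
        occ_n=occ_n,
        meth_mean=meth_mean,
        meth_n=meth_n,
        cpg_density=cpg_sum / n_windows,
        n_windows=n_windows,
    )


def _moving_mean(values: np.ndarray, w: int) -> np.ndarray:
    """Centered moving mean ignoring NaNs, truncated at the edges.

    For even w the window at i spans i - w//2 .. i + w - w//2 - 1.
    """
    n = values.size
    finite = np.isfinite(values)
    v = np.where(finite, values, 0.0)
    cs_v = np.concatenate(([0.0], np.cumsum(v)))
    cs_c = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    i = np.arange(n)
    lo = np.maximum(i - w // 2, 0)
    hi = np.minimum(i + (w - 1 - w // 2), n - 1)
    s = cs_v[hi + 1] - cs_v[lo]
    k = cs_c[hi + 1] - cs_c[lo]
    with np.errstate(invalid="ignore"):
        return np.where(k > 0, s / np.maximum(k, 1), np.nan)


def locate_extremum(rel: np.ndarray, values: np.ndarray, kind: str = "min",
                    fit_halfwidth: int = 200) -> float:
    """Sub-bin location of a track's extremum by local parabola-vertex fit.

    The raw argmin/argmax of a noisy, flat-topped track wanders by tens of
    base pairs; fitting a quadratic to the ``fit_halfwidth`` neighbourhood
    of the raw extremum and taking its vertex is far more stable.  Returns
    the vertex position clipped to the fitted range.
    """
    if kind not in ("min", "max"):
        raise ProfilerError("kind must be 'min' or 'max'")
    y = np.asarray(values, dtype=float)
    if not np.isfinite(y).any():
        raise ProfilerError("track is undefined everywhere")
    i = int(np.nanargmin(y) if kind == "min" else np.nanargmax(y))
    m = (np.abs(rel - rel[i]) <= fit_halfwidth) & np.isfinite(y)
    if m.sum() < 3:
        return float(rel[i])
    coef = np.polyfit(rel[m].astype(float), y[m], 2)
    if abs(coef[0]) < 1e-12:
        return float(rel[i])
    vertex = -coef[1] / (2 * coef[0])
    return float(np.clip(vertex, rel[m].min(), rel[m].max()))


def fit_gaussian_dip(rel: np.ndarray, values: np.ndarray,
                     rel_range: tuple[int, int] = (-500, 0),
                     counts: np.ndarray | None = None) -> dict[str, float]:
    """Least-squares fit of a Gaussian dip ``b - d*exp(-(x-mu)^2/(2 s^2))``.

    The standard way to localize and quantify a nucleosome-decreased
    region in an averaged occupancy track: fit over ``rel_range`` (by
    default the upstream flank) and report baseline ``b``, depth ``d``,
    center ``mu`` and width ``s``.  When per-position contributing-window
    ``counts`` are supplied (e.g. an unsmoothed profile's ``occ_n``) the
    fit is count-weighted, since a position averaged over n windows has
    variance proportional to 1/n.
    """
    from scipy.optimize import curve_fit

    lo, hi = rel_range
    mask = (rel >= lo) & (rel <= hi) & np.isfinite(values)
    if counts is not None:
        mask &= counts > 0
    if mask.sum() < 8:
        raise ProfilerError("too few defined positions to fit a dip")
    x = rel[mask].astype(float)
    y = values[mask].astype(float)
    sigma = None if counts is None else 1.0 / np.sqrt(counts[mask].astype(float))
    i = int(np.argmin(y))
    p0 = (float(np.median(y)), float(np.median(y) - y.min()), x[i], (hi - lo) / 6.0)
    bounds = ([0.0, 0.0, float(lo), 5.0], [1.0, 1.0, float(hi), float(hi - lo)])

    def dip(x, b, d, mu, s):
        return b - d * np.exp(-((x - mu) ** 2) / (2 * s**2))

    popt, _ = curve_fit(dip, x, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000)
    b, d, mu, s = popt
    return {"baseline": float(b), "depth": float(d), "center": float(mu), "sigma": float(s)}


def dominant_period(rel: np.ndarray, values: np.ndarray,
                    rel_range: tuple[int, int] = (1, 1000),
                    detrend_bp: int = 301, min_bin: int = 2) -> dict[str, float]:
    """Dominant oscillation period of a track segment via the power spectrum.

    Linearly interpolates missing values, removes the slow trend with a
    ``detrend_bp`` moving average, and returns the discrete-spectrum peak
    (ignoring bins below ``min_bin``) as {'period', 'bin', 'n'} where
    period = n / bin.
    """
    lo, hi = rel_range
    mask = (rel >= lo) & (rel <= hi)
    y = np.asarray(values, dtype=float)[mask].copy()
    bad = ~np.isfinite(y)
    if bad.all():
        raise ProfilerError("track is undefined over the requested range")
    if bad.any():
        y[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), y[~bad])
    y = y - _moving_mean(y, detrend_bp)
    power = np.abs(np.fft.rfft(y)) ** 2
    k = int(np.argmax(power[min_bin:]) + min_bin)
    n = y.size
    return {"period": n / k, "bin": float(k), "n": float(n)}


def smooth(profile: Profile, window_bp: int = 30) -> Profile:
    """Moving-window average of each mean track; count tracks are untouched.

    Undefined positions are excluded from each local mean rather than
    treated as zero, and the window is truncated (never padded) at the
    profile boundaries.
    """
    if window_bp < 1:
        raise ProfilerError("window_bp must be >= 1")
    return Profile(
        rel=profile.rel.copy(),
        occ_mean=_moving_mean(profile.occ_mean, window_bp),
        occ_n=profile.occ_n.copy(),
        meth_mean=_moving_mean(profile.meth_mean, window_bp),
        meth_n=profile.meth_n.copy(),
        cpg_density=_moving_mean(profile.cpg_density, window_bp),
        n_windows=profile.n_windows,
    )
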