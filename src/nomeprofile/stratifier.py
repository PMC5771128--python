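"""Stratum selection and per-profile summary statistics.

Selects promoter/region subsets the analysis contrasts — expression
extremes (top and bottom 5% by default), promoters of below-average CpG
density, control regions of below-average methylation — and condenses a
profile into a single (density, methylation, occupancy) summary point.

Selection rules are deterministic: expression quantiles take exactly
floor(q*N) anchors with ties broken by genomic order, and threshold
selections use strict "<".
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_sites import SitePositions
from .profiler import Anchor, AnchorSet, Profile
from .signal import SiteTable

__all__ = [
    "StratifierError",
    "ProfileSummary",
    "select_by_expression",
    "mean_region_density",
    "mean_region_methylation",
    "select_below_threshold",
    "summarize_profile",
    "summaries_to_frame",
    "write_summary_tsv",
]


class StratifierError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ProfileSummary:
    """One point of the density-vs-methylation/occupancy summary plot.

    Occupancy and methylation are weighted by each position's contributing
    window count (consistent with how the profile means were accumulated);
    density is an unweighted positional mean.  Entries are None when a
    track is undefined everywhere.
    """

    label: str
    mean_density: float | None
    mean_methylation: float | None
    mean_occupancy: float | None
    n_regions: int


def select_by_expression(promoters: AnchorSet, q: float, which: str) -> AnchorSet:
    """The floor(q*N) anchors of highest ("top") or lowest ("bottom") expression.

    Ties are broken by genomic order; q must lie in (0, 0.5].  Anchors with
    missing expression raise an error naming the offenders.
    """
    if not 0 < q <= 0.5:
        raise StratifierError(f"quantile fraction must be in (0, 0.5], got {q}")
    if which not in ("top", "bottom"):
        raise StratifierError(f"'which' must be 'top' or 'bottom', got {which!r}")
    missing = [a.id for a in promoters if a.expression is None]
    if missing:
        raise StratifierError(f"anchors lack expression values: {missing[:10]}"
                              + ("..." if len(missing) > 10 else ""))
    n_sel = math.floor(q * len(promoters))
    sign = -1.0 if which == "top" else 1.0
    ranked = sorted(promoters, key=lambda a: (sign * a.expression, a.chrom, a.pos, a.id))
    return AnchorSet(ranked[:n_sel])


def mean_region_density(
    anchor: Anchor, cpg_positions: SitePositions, halfwidth: int = 1000,
    chrom_length: int | None = None,
) -> float | None:
    """CpG sites per bp in the +/- halfwidth window (no dedup).

    Out-of-bounds windows are flagged and skipped (None).
    """
    lo, hi = anchor.pos - halfwidth, anchor.pos + halfwidth
    if lo < 0 or (chrom_length is not None and hi >= chrom_length):
        return None
    return cpg_positions.count_in(lo, hi) / (2 * halfwidth + 1)


def mean_region_methylation(
    anchor: Anchor, sites: SiteTable, halfwidth: int = 1000, min_total: float = 1,
) -> float:
    """Unweighted mean methylation level over covered CpG sites in the window.

    NaN when no covered CpG site falls inside the window.
    """
    pos, lev = sites.levels(anchor.chrom, "CpG", min_total)
    a, b = np.searchsorted(pos, (anchor.pos - halfwidth, anchor.pos + halfwidth + 1))
    return float(np.mean(lev[a:b])) if b > a else float("nan")


def select_below_threshold(items: Sequence[tuple[str, float]], threshold: float) -> list[str]:
    """Ids whose value is strictly below the threshold; missing values dropped."""
    return [i for i, v in items if v is not None and np.isfinite(v) and v < threshold]


def _weighted(track: np.ndarray, weights: np.ndarray) -> float | None:
    ok = np.isfinite(track) & (weights > 0)
    if not ok.any():
        return None
    return float(np.sum(track[ok] * weights[ok]) / np.sum(weights[ok]))


def summarize_profile(profile: Profile, label: str, n_regions: int | None = None) -> ProfileSummary:
    """Collapse a profile to its mean (density, methylation, occupancy) point."""
    dens = profile.cpg_density[np.isfinite(profile.cpg_density)]
    return ProfileSummary(
        label=label,
        mean_density=float(dens.mean()) if dens.size else None,
        mean_methylation=_weighted(profile.meth_mean, profile.meth_n),
        mean_occupancy=_weighted(profile.occ_mean, profile.occ_n),
        n_regions=profile.n_windows if n_regions is None else n_regions,
    )


def summaries_to_frame(summaries: Sequence[ProfileSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": s.label,
                "mean_density": s.mean_density,
                "mean_methylation": s.mean_methylation,
                "mean_occupancy": s.mean_occupancy,
                "n_regions": s.n_regions,
            }
            for s in summaries
        ]
    )


def write_summary_tsv(summaries: Sequence[ProfileSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False, na_rep="NA",
                                         float_format="%.6g")
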