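"""Per-site NOME-seq measurements: methylation levels and nucleosome occupancy.

A NOME-seq experiment reports, for every informative cytosine, how many
bisulfite reads were methylated out of how many total reads.  Endogenous
methylation is read from CpG sites; chromatin accessibility is read from
GpC sites, which the M.CviPI enzyme methylates only where no nucleosome
protects the DNA.  The methylation level of a site is methylated reads
divided by total reads, and nucleosome occupancy is defined as
1 - GpC methylation level.

Sites with zero total reads are retained in the table (their positions
still matter for density computations) but yield a *missing* level,
represented as NaN.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "SignalError",
    "methylation_level",
    "occupancy_from_gpc",
    "SiteTable",
]

CONTEXTS = ("CpG", "GpC")

COLUMNS = ["chrom", "pos", "context", "meth_reads", "total_reads"]


class SignalError(ValueError):
    """Raised for data-integrity violations in site measurements."""


def methylation_level(meth_reads, total_reads):
    """Methylation level = methylated reads / total reads; NaN when total is 0.

    Accepts scalars or arrays.  Raises :class:`SignalError` if any
    methylated count exceeds its total or is negative.
    """
    m = np.asarray(meth_reads, dtype=float)
    t = np.asarray(total_reads, dtype=float)
    if np.any(m < 0) or np.any(t < 0):
        raise SignalError("read counts must be non-negative")
    if np.any(m > t):
        raise SignalError("methylated reads exceed total reads")
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(t > 0, m / np.where(t > 0, t, 1.0), np.nan)
    return float(level) if level.ndim == 0 else level


def occupancy_from_gpc(gpc_level):
    """Nucleosome occupancy from a GpC methylation level: 1 - level.

    Missing (NaN) levels propagate.  Raises :class:`SignalError` for levels
    outside [0, 1].
    """
    x = np.asarray(gpc_level, dtype=float)
    finite = np.isfinite(x)
    if np.any((x[finite] < 0) | (x[finite] > 1)):
        raise SignalError("GpC methylation level outside [0, 1]")
    out = 1.0 - x
    return float(out) if out.ndim == 0 else out


class SiteTable:
    """Collection of per-site measurements, unique by (chrom, pos, context).

    Backed by a :class:`pandas.DataFrame` with columns
    ``chrom, pos, context, meth_reads, total_reads``, sorted by position
    within chromosome.  Read counts are integers except for tables imported
    from bedGraph, where pre-computed levels are stored as
    ``meth_reads=level, total_reads=1.0`` (total unknown but positive).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, COLUMNS].copy()
        if np.any(df["meth_reads"].to_numpy() < 0) or np.any(df["total_reads"].to_numpy() < 0):
            raise SignalError("read counts must be non-negative")
        if np.any(df["meth_reads"].to_numpy() > df["total_reads"].to_numpy()):
            raise SignalError("methylated reads exceed total reads")
        bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
        if bad_ctx:
            raise SignalError(f"unknown context(s): {sorted(bad_ctx)}")
        df = df.sort_values(["chrom", "pos", "context"], kind="stable").reset_index(drop=True)
        if df.duplicated(["chrom", "pos", "context"]).any():
            dup = df[df.duplicated(["chrom", "pos", "context"])].head(3)
            raise SignalError(f"duplicate (chrom, pos, context) records, e.g.\n{dup}")
        self._df = df
        self._cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(cls, chrom, pos, context, meth_reads, total_reads) -> "SiteTable":
        return cls(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.asarray(pos),
                    "context": context,
                    "meth_reads": np.asarray(meth_reads),
                    "total_reads": np.asarray(total_reads),
                }
            )
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SiteTable":
        """Read the canonical tab-separated dialect ('#' lines are comments)."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=COLUMNS, dtype={"chrom": str})
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# " + "\t".join(COLUMNS) + "\n")
            self._df.to_csv(fh, sep="\t", header=False, index=False)

    @classmethod
    def from_bedgraph(cls, path: str | Path, context: str) -> "SiteTable":
        """Import pre-computed levels from bedGraph (chrom, start, end, value).

        Every position of each interval receives the interval's value as its
        level; totals are marked unknown-but-positive (1.0).
        """
        if context not in CONTEXTS:
            raise SignalError(f"unknown context {context!r}")
        chroms: list[str] = []
        poss: list[int] = []
        vals: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                v = float(value)
                if not 0 <= v <= 1:
                    raise SignalError(f"bedGraph level outside [0, 1]: {v}")
                for p in range(int(start), int(end)):
                    chroms.append(chrom)
                    poss.append(p)
                    vals.append(v)
        return cls.from_arrays(chroms, np.array(poss, dtype=np.int64), context,
                               np.array(vals), np.ones(len(vals)))

    # -- access ------------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, SiteTable) and self._df.equals(other._df)

    def arrays(self, chrom: str, context: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, meth_reads, total_reads) for one chromosome+context, sorted."""
        key = (chrom, context)
        if key not in self._cache:
            sub = self._df[(self._df["chrom"] == chrom) & (self._df["context"] == context)]
            self._cache[key] = (
                sub["pos"].to_numpy(np.int64),
                sub["meth_reads"].to_numpy(float),
                sub["total_reads"].to_numpy(float),
            )
        return self._cache[key]

    def levels(self, chrom: str, context: str, min_total: float = 1) -> tuple[np.ndarray, np.ndarray]:
        """(positions, levels) for covered sites (total >= min_total)."""
        pos, meth, total = self.arrays(chrom, context)
        keep = total >= min_total
        return pos[keep], methylation_level(meth[keep], total[keep])
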