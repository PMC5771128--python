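"""Synthetic NOME-seq data with known ground truth.

Generates a genome, a promoter annotation with expression values, and a
per-site read-count table that together emulate the statistical structure
the promoter/control analysis assumes:

* a background sequence at a configurable GC fraction, with CpG
  dinucleotides stripped and replanted — at a low background rate
  genome-wide and as CpG "islands" whose density peaks sharply at each TSS
  and decays with heavy tails across the window;
* additional *orphan* islands at non-promoter locations, the synthetic
  counterpart of the genome-wide CpG clusters the control matcher draws
  its candidates from;
* island intensity coupled to expression (lowly expressed promoters are
  CpG-poorer), with orphan intensities drawn from the same distribution;
* true CpG methylation a strictly decreasing logistic function of local
  CpG density, so density and methylation are anti-correlated everywhere;
* true nucleosome occupancy flat at a baseline away from promoters and,
  around each TSS, carrying an expression-scaled nucleosome-decreased
  region (NDR) upstream plus decaying phased oscillations downstream;
* reads sampled per site as Poisson totals and binomial methylated counts,
  with GpC success probability 1 - occupancy (the NOME-seq readout).

Dinucleotides are planted on a 4 bp lattice (CpG blocks at offsets
0 mod 4, GpC blocks at 2 mod 4) with single-letter guards at block
boundaries.  This makes planting collision-free, keeps realized rates
exactly at their targets, and guarantees that re-scanning the final
sequence recovers exactly the planted site lists — no site is ever both
CpG and GpC context.  The analysis stages never look at sub-30 bp spacing
structure, so the lattice is invisible to them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .genome_sites import Genome, find_sites
from .profiler import Anchor, AnchorSet
from .signal import SiteTable

__all__ = [
    "SimConfigError",
    "MethylationModel",
    "OccupancyModel",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "true_methylation",
    "true_occupancy",
    "simulate_genome",
    "sample_reads",
    "simulate_dataset",
    "write_dataset",
]


class SimConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MethylationModel:
    """Logistic response of true CpG methylation to local CpG density.

    m(rho) = m_max - (m_max - m_min) * logistic((rho - rho0) / slope),
    strictly decreasing in rho.  ``density_window_bp`` is the window over
    which local density (sites/bp) is measured.
    """

    m_max: float = 0.85
    m_min: float = 0.10
    rho0: float = 0.05
    slope: float = 0.02
    density_window_bp: int = 151


@dataclasses.dataclass(frozen=True)
class OccupancyModel:
    """Positional model of true nucleosome occupancy around a TSS.

    With x the strand-oriented offset from the TSS and e the promoter's
    expression weight in [0, 1]:

    O(x) = baseline
           - e * ndr_amplitude * exp(-(x - ndr_center)^2 / (2 ndr_sigma^2))
           + e * phasing_amplitude * cos(2 pi x / period) * exp(-x / decay) * [x > 0]

    clamped to [0, 1]; O = baseline wherever no TSS lies within the window.
    """

    baseline: float = 0.80
    ndr_amplitude: float = 0.50
    ndr_center: int = -100
    ndr_sigma: float = 60.0
    phasing_amplitude: float = 0.15
    period: float = 200.0
    decay: float = 600.0


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic dataset.

    Rates are sites per bp.  ``island_cpg_rate`` is the island *peak* CpG
    rate attained at the anchor of a maximally expressed promoter; island
    intensity follows :func:`island_bump_shape` (a sharp peak of scale
    ``island_lambda`` on a broad base of width ``island_sigma``) and is
    scaled down for lowly expressed promoters, to a fraction no lower than
    ``expression_coupling_floor``.
    """

    seed: int = 7
    chrom_name: str = "chr1"
    length: int = 2_000_000
    gc_fraction: float = 0.41
    n_promoters: int = 200
    n_orphan_islands: int | None = None  # default: 2 * n_promoters
    min_anchor_spacing: int = 2100
    edge_margin: int = 2000
    island_halfwidth: int = 1000
    island_sigma: float = 450.0
    island_lambda: float = 150.0
    island_cpg_rate: float = 0.08
    background_cpg_rate: float = 0.009
    background_gpc_rate: float = 0.042
    expression_coupling_floor: float = 0.45
    expression_logmean: float = 1.0
    expression_logsd: float = 1.2
    methylation: MethylationModel = dataclasses.field(default_factory=MethylationModel)
    occupancy: OccupancyModel = dataclasses.field(default_factory=OccupancyModel)
    mean_coverage: float = 20.0
    window_halfwidth: int = 1000  # reach of the TSS occupancy features

    def __post_init__(self):
        m, o = self.methylation, self.occupancy
        if not (0 <= m.m_min <= m.m_max <= 1):
            raise SimConfigError("need 0 <= m_min <= m_max <= 1")
        if m.slope <= 0 or m.density_window_bp < 1:
            raise SimConfigError("methylation slope and density window must be positive")
        if not 0 < self.gc_fraction < 1:
            raise SimConfigError("gc_fraction must be in (0, 1)")
        for name in ("island_cpg_rate", "background_cpg_rate", "background_gpc_rate",
                     "mean_coverage"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if max(self.island_cpg_rate, self.background_cpg_rate) * 4 > 1:
            raise SimConfigError("CpG rate too high for the 4 bp planting lattice")
        if self.background_gpc_rate * 4 > 1:
            raise SimConfigError("GpC rate too high for the 4 bp planting lattice")
        # occupancy must stay inside [0, 1] for every e in [0, 1]
        if o.baseline - o.ndr_amplitude - o.phasing_amplitude < 0 or o.baseline + o.phasing_amplitude > 1:
            raise SimConfigError("occupancy model leaves [0, 1]")
        if not 0 <= self.expression_coupling_floor <= 1:
            raise SimConfigError("expression_coupling_floor must be in [0, 1]")
        n_total = self.n_promoters + self.n_orphans
        usable = self.length - 2 * self.edge_margin
        if n_total > 0 and (usable <= 0 or usable / n_total < self.min_anchor_spacing):
            raise SimConfigError(
                f"{n_total} anchors at spacing >= {self.min_anchor_spacing} bp do not fit "
                f"in {self.length} bp")

    @property
    def n_orphans(self) -> int:
        return 2 * self.n_promoters if self.n_orphan_islands is None else self.n_orphan_islands

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class GroundTruth:
    """Planted coordinates and true per-site probabilities (test plumbing)."""

    chrom: str
    length: int
    cpg_positions: np.ndarray
    cpg_meth_p: np.ndarray
    gpc_positions: np.ndarray
    gpc_occupancy: np.ndarray
    promoter_weights: np.ndarray  # aligned with the promoter AnchorSet order
    orphan_centers: np.ndarray
    orphan_weights: np.ndarray
    config: SimConfig
    _tss: np.ndarray = dataclasses.field(default=None, repr=False)
    _tss_strand: np.ndarray = dataclasses.field(default=None, repr=False)
    _tss_weight: np.ndarray = dataclasses.field(default=None, repr=False)

    def occupancy_at(self, positions) -> np.ndarray:
        """True occupancy at arbitrary genomic positions."""
        pos = np.asarray(positions, dtype=np.int64)
        out = np.full(pos.shape, self.config.occupancy.baseline, dtype=float)
        if self._tss is None or self._tss.size == 0:
            return out
        i = np.clip(np.searchsorted(self._tss, pos), 1, self._tss.size) - 1
        # anchors are spaced farther apart than the window reach, so at most
        # one of the two flanking TSSs can be in range
        for j in (i, np.minimum(i + 1, self._tss.size - 1)):
            tss = self._tss[j]
            near = np.abs(pos - tss) <= self.config.window_halfwidth
            if near.any():
                x = np.where(self._tss_strand[j] == 1, pos - tss, tss - pos)
                out[near] = true_occupancy_offset(
                    x[near], self._tss_weight[j][near], self.config.occupancy)
        return out


@dataclasses.dataclass
class SimResult:
    genome: Genome
    promoters: AnchorSet
    truth: GroundTruth
    sites: SiteTable


# -- truth models ----------------------------------------------------------

def true_methylation(local_density, model: MethylationModel = MethylationModel()):
    """True methylation probability at local CpG density (sites/bp)."""
    rho = np.asarray(local_density, dtype=float)
    m = model.m_max - (model.m_max - model.m_min) * expit((rho - model.rho0) / model.slope)
    return float(m) if m.ndim == 0 else m


def true_occupancy_offset(x, e, model: OccupancyModel = OccupancyModel()):
    """True occupancy at strand-oriented offset(s) x from a TSS with weight e."""
    x = np.asarray(x, dtype=float)
    e = np.asarray(e, dtype=float)
    ndr = model.ndr_amplitude * np.exp(-((x - model.ndr_center) ** 2) / (2 * model.ndr_sigma**2))
    phase = (model.phasing_amplitude * np.cos(2 * np.pi * x / model.period)
             * np.exp(-np.maximum(x, 0) / model.decay) * (x > 0))
    o = np.clip(model.baseline - e * ndr + e * phase, 0.0, 1.0)
    return float(o) if o.ndim == 0 else o


def true_occupancy(position, nearest_tss, strand, expression_weight,
                   model: OccupancyModel = OccupancyModel(), within: int = 1000):
    """True occupancy at a genomic position given its nearest TSS.

    Falls back to the flat baseline when the TSS is farther than ``within``.
    """
    pos = np.asarray(position, dtype=float)
    tss = np.asarray(nearest_tss, dtype=float)
    x = np.where(np.asarray(strand) == "-", tss - pos, pos - tss)
    o = true_occupancy_offset(x, expression_weight, model)
    o = np.where(np.abs(pos - tss) <= within, o, model.baseline)
    return float(o) if o.ndim == 0 else o


# -- sequence machinery ----------------------------------------------------

_A, _C, _G, _T = (ord(b) for b in "ACGT")


def _strip_cg_gc(seq: np.ndarray) -> np.ndarray:
    """Remove every CG and GC dinucleotide by rewriting its second base to A.

    Rewriting to A can never create a new CG or GC, so one pass suffices.
    """
    is_cg = (seq[:-1] == _C) & (seq[1:] == _G)
    is_gc = (seq[:-1] == _G) & (seq[1:] == _C)
    hit = np.flatnonzero(is_cg | is_gc) + 1
    seq[hit] = _A
    return seq


def _plant(seq: np.ndarray, starts: np.ndarray, first: int, second: int) -> None:
    """Write a dinucleotide at each start with boundary guards.

    Guards rewrite a neighbouring *background* base to A wherever the new
    block would otherwise complete an unplanned CG or GC, keeping planted
    site lists exactly equal to the realized ones.
    """
    if starts.size == 0:
        return
    left = starts - 1
    right = starts + 2
    if first == _C:  # CpG block: G..C before, or ..C after, would form GC
        seq[left[seq[left] == _G]] = _A
        seq[right[seq[right] == _C]] = _A
    else:  # GpC block: C.. before would form CG; ..G after would form CG
        seq[left[seq[left] == _C]] = _A
        seq[right[seq[right] == _G]] = _A
    seq[starts] = first
    seq[starts + 1] = second


def island_bump_shape(x, config: SimConfig) -> np.ndarray:
    """Normalized island density shape: sharp Laplace peak on a broad Gaussian base.

    Equals 1 at the anchor (x = 0) and decays with heavy tails, emulating
    promoter CpG islands whose density peaks at the TSS yet stays above
    background across the whole window.
    """
    x = np.asarray(x, dtype=float)
    return 0.5 * np.exp(-np.abs(x) / config.island_lambda) + 0.5 * np.exp(
        -(x**2) / (2 * config.island_sigma**2))


def _island_rate_profile(config: SimConfig, centers: np.ndarray, weights: np.ndarray,
                         slots: np.ndarray) -> np.ndarray:
    """Per-slot CpG planting rate: background plus expression-scaled island bumps."""
    rate = np.full(slots.shape, config.background_cpg_rate, dtype=float)
    floor = config.expression_coupling_floor
    scale = floor + (1 - floor) * weights
    amp = (config.island_cpg_rate - config.background_cpg_rate) * scale
    for c, a in zip(centers, amp):
        lo = np.searchsorted(slots, c - config.island_halfwidth)
        hi = np.searchsorted(slots, c + config.island_halfwidth, side="right")
        rate[lo:hi] += a * island_bump_shape(slots[lo:hi] - c, config)
    return rate


def _rank_weights(values: np.ndarray) -> np.ndarray:
    """Empirical-CDF weights in [0, 1] (rank / (n - 1)), ties broken by index."""
    n = values.size
    if n <= 1:
        return np.ones(n)
    order = np.argsort(values, kind="stable")
    w = np.empty(n)
    w[order] = np.arange(n) / (n - 1)
    return w


def _simulate_genome_rng(config: SimConfig, rng: np.random.Generator):
    L = config.length
    g = config.gc_fraction
    # stage 1: iid background at the configured GC fraction
    seq = rng.choice(
        np.array([_A, _C, _G, _T], dtype=np.uint8), size=L,
        p=[(1 - g) / 2, g / 2, g / 2, (1 - g) / 2],
    )
    _strip_cg_gc(seq)

    # stage 2: anchor placement on an evenly slotted grid with jitter
    n_prom, n_orph = config.n_promoters, config.n_orphans
    n_total = n_prom + n_orph
    if n_total > 0:
        usable = L - 2 * config.edge_margin
        slot = usable / n_total
        jitter = rng.uniform(-0.5, 0.5, n_total) * (slot - config.min_anchor_spacing)
        centers = (config.edge_margin + (np.arange(n_total) + 0.5) * slot + jitter).astype(np.int64)
        roles = rng.permutation(n_total) < n_prom  # True -> promoter
    else:
        centers = np.empty(0, dtype=np.int64)
        roles = np.empty(0, dtype=bool)
    tss = centers[roles]
    orphan_centers = centers[~roles]
    strands = rng.choice(np.array(["+", "-"]), size=tss.size)
    expression = rng.lognormal(config.expression_logmean, config.expression_logsd, tss.size)
    weights = _rank_weights(expression)
    orphan_weights = rng.uniform(0.0, 1.0, orphan_centers.size)

    # stage 3: plant GpC blocks on the 2-mod-4 lattice at a uniform rate,
    # independent of islands (GpC content matches plain C+G expectation)
    gpc_slots = np.arange(6, L - 5, 4, dtype=np.int64)
    gpc_mask = rng.random(gpc_slots.size) < 4 * config.background_gpc_rate
    gpc_starts = gpc_slots[gpc_mask]
    _plant(seq, gpc_starts, _G, _C)

    # stage 4: plant CpG blocks on the 0-mod-4 lattice, background everywhere
    # plus Gaussian island bumps at promoter and orphan anchors
    cpg_slots = np.arange(4, L - 5, 4, dtype=np.int64)
    island_centers = np.concatenate([tss, orphan_centers])
    island_weights = np.concatenate([weights, orphan_weights])
    rate = _island_rate_profile(config, island_centers, island_weights, cpg_slots)
    cpg_mask = rng.random(cpg_slots.size) < np.clip(4 * rate, 0, 1)
    cpg_starts = cpg_slots[cpg_mask]
    _plant(seq, cpg_starts, _C, _G)

    genome = Genome({config.chrom_name: seq.tobytes().decode("ascii")})

    # realized sites (provably identical to the planted lists; re-scanned anyway)
    cpg_pos = find_sites(genome[config.chrom_name], "CG", config.chrom_name).positions
    gpc_pos = find_sites(genome[config.chrom_name], "GC", config.chrom_name).positions

    # per-CpG local density and true methylation
    w = config.methylation.density_window_bp
    half = (w - 1) // 2
    counts = (np.searchsorted(cpg_pos, cpg_pos + half, side="right")
              - np.searchsorted(cpg_pos, cpg_pos - half, side="left"))
    cpg_meth_p = true_methylation(counts / w, config.methylation)

    order = np.argsort(tss, kind="stable")
    promoters = AnchorSet(
        Anchor(id=f"prom_{i:05d}", chrom=config.chrom_name, pos=int(tss[j]),
               strand=str(strands[j]), expression=float(expression[j]))
        for i, j in enumerate(order)
    )
    truth = GroundTruth(
        chrom=config.chrom_name,
        length=L,
        cpg_positions=cpg_pos,
        cpg_meth_p=cpg_meth_p,
        gpc_positions=gpc_pos,
        gpc_occupancy=np.empty(0),
        promoter_weights=weights[order],
        orphan_centers=np.sort(orphan_centers),
        orphan_weights=orphan_weights[np.argsort(orphan_centers, kind="stable")],
        config=config,
        _tss=tss[order],
        _tss_strand=np.where(strands[order] == "+", 1, -1),
        _tss_weight=weights[order],
    )
    truth.gpc_occupancy = truth.occupancy_at(gpc_pos)
    return genome, promoters, truth


def simulate_genome(config: SimConfig) -> tuple[Genome, AnchorSet, GroundTruth]:
    """Generate the genome, promoter annotation and ground truth (no reads).

    Deterministic: the same config (including seed) yields a byte-identical
    genome.
    """
    rng = np.random.default_rng(config.seed)
    return _simulate_genome_rng(config, rng)


def sample_reads(truth: GroundTruth, config: SimConfig,
                 rng: np.random.Generator | None = None) -> SiteTable:
    """Sample per-site read counts from the ground truth.

    Totals are Poisson(mean_coverage); methylated counts are
    Binomial(total, p) with p the true methylation probability for CpG
    sites and 1 - true occupancy for GpC sites.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 104729))
    pos = np.concatenate([truth.cpg_positions, truth.gpc_positions])
    p = np.concatenate([truth.cpg_meth_p, 1.0 - truth.gpc_occupancy])
    context = np.array(["CpG"] * truth.cpg_positions.size + ["GpC"] * truth.gpc_positions.size)
    totals = rng.poisson(config.mean_coverage, pos.size)
    meth = rng.binomial(totals, p)
    return SiteTable.from_arrays(truth.chrom, pos, context, meth, totals)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Genome + promoters + truth + sampled reads from one random stream."""
    rng = np.random.default_rng(config.seed)
    genome, promoters, truth = _simulate_genome_rng(config, rng)
    sites = sample_reads(truth, config, rng)
    return SimResult(genome, promoters, truth, sites)


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, promoter BED6+expression, site TSV and ground-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "promoters": outdir / "promoters.bed",
        "sites": outdir / "sites.tsv",
        "truth_cpg": outdir / "truth_cpg.tsv",
        "truth_gpc": outdir / "truth_gpc.tsv",
        "truth_promoters": outdir / "truth_promoters.tsv",
        "config": outdir / "config_resolved.yaml",
    }
    result.genome.to_fasta(paths["genome"])
    result.promoters.write_bed(paths["promoters"])
    result.sites.write_tsv(paths["sites"])
    t = result.truth
    pd.DataFrame({"chrom": t.chrom, "pos": t.cpg_positions, "meth_p": t.cpg_meth_p}).to_csv(
        paths["truth_cpg"], sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"chrom": t.chrom, "pos": t.gpc_positions, "occupancy": t.gpc_occupancy}).to_csv(
        paths["truth_gpc"], sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "id": [a.id for a in result.promoters],
            "expression": [a.expression for a in result.promoters],
            "weight": t.promoter_weights,
        }
    ).to_csv(paths["truth_promoters"], sep="\t", index=False, float_format="%.6g")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(result.truth.config.to_dict(), fh, sort_keys=False)
    return paths
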