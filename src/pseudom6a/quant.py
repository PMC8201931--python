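"""Gene-level m6A quantification, peak calling, and site calling.

LAIC-seq partitions full-length RNAs into an m6A-positive (eluate) and an
m6A-negative (supernatant) fraction: the gene-level m6A level is the eluate
share of the methylation-informative signal, so equal eluate and supernatant
signals mean a level of 50%.  Peaks are called from RIP-vs-input per-base
coverage by sliding-window enrichment; single-nucleotide sites are the
methylatable A's of sense-strand DRACH motifs falling inside peaks.  Levels
are bucketed into the high (>= 0.6) / medium ([0.3, 0.6)) / low (< 0.3)
categories used by all stratified analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import MotifSite, scan_drach

#: category boundaries: high iff level >= HIGH_CUTOFF, low iff level < LOW_CUTOFF
HIGH_CUTOFF = 0.6
LOW_CUTOFF = 0.3

#: minimum scaled informative reads for a level to count as reliable
MIN_INFORMATIVE = 20.0


@dataclass
class FractionCounts:
    """Raw reads per LAIC fraction for one gene, with per-fraction size
    factors (library-size ratios by default; a spike-in normalization can be
    injected here)."""

    gene_id: str
    input_count: int
    eluate_count: int
    supernatant_count: int
    size_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)  # input, eluate, sup

    def __post_init__(self):
        if min(self.input_count, self.eluate_count, self.supernatant_count) < 0:
            raise ValueError("counts must be non-negative")
        if min(self.size_factors) <= 0:
            raise ValueError("size factors must be positive")


@dataclass
class M6AMeasurement:
    gene_id: str
    level: float | None  # None when below the reliability threshold
    category: str | None  # "high" | "medium" | "low" | None
    n_informative: float


@dataclass
class PeakInterval:
    """A called m6A peak in 0-based half-open transcript coordinates;
    intensity is the length-weighted mean input-normalized RIP/input ratio."""

    gene_id: str
    start: int
    end: int
    intensity: float

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad peak interval ({self.start}, {self.end})")


def m6a_level(fc: FractionCounts, min_informative: float = MIN_INFORMATIVE) -> M6AMeasurement:
    """Gene-level m6A stoichiometry from fraction counts.

    level = scaled_eluate / (scaled_eluate + scaled_supernatant).  Genes whose
    scaled informative signal (eluate + supernatant) falls below
    ``min_informative`` are flagged undefined and excluded downstream — the
    operational form of restricting to genes with reliable m6A levels.
    """
    _, sf_elu, sf_sup = fc.size_factors
    elu = fc.eluate_count * sf_elu
    sup = fc.supernatant_count * sf_sup
    informative = elu + sup
    if informative < min_informative or informative == 0:
        return M6AMeasurement(fc.gene_id, None, None, informative)
    level = elu / informative
    return M6AMeasurement(fc.gene_id, level, categorize_level(level), informative)


def categorize_level(level: float) -> str:
    """high iff level >= 0.6; medium iff 0.3 <= level < 0.6; low iff < 0.3."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level must lie in [0, 1], got {level}")
    if level >= HIGH_CUTOFF:
        return "high"
    if level >= LOW_CUTOFF:
        return "medium"
    return "low"


def levels_table(
    fraction_df: pd.DataFrame,
    min_informative: float = MIN_INFORMATIVE,
    size_factors: tuple[float, float, float] | str | None = None,
) -> pd.DataFrame:
    """Vector form over a fraction-counts table (gene_id, input_count,
    eluate_count, supernatant_count).

    ``size_factors=None`` uses unit factors (counts assumed already on a
    common scale, as spike-in-normalized fractions are).  Pass ``"library"``
    to rescale each fraction to the mean library size, or an explicit
    (input, eluate, supernatant) triple.
    """
    if size_factors is None:
        size_factors = (1.0, 1.0, 1.0)
    elif size_factors == "library":
        libs = np.array(
            [
                fraction_df["input_count"].sum(),
                fraction_df["eluate_count"].sum(),
                fraction_df["supernatant_count"].sum(),
            ],
            dtype=float,
        )
        size_factors = tuple(libs.mean() / np.maximum(libs, 1.0))
    rows = []
    for row in fraction_df.itertuples(index=False):
        m = m6a_level(
            FractionCounts(
                row.gene_id,
                int(row.input_count),
                int(row.eluate_count),
                int(row.supernatant_count),
                size_factors,
            ),
            min_informative,
        )
        rows.append((m.gene_id, m.level, m.category, m.n_informative))
    return pd.DataFrame(rows, columns=["gene_id", "level", "category", "n_informative"])


def call_peaks(
    rip_cov: Sequence[float],
    input_cov: Sequence[float],
    gene_id: str = "gene",
    window: int = 100,
    enrich_threshold: float = 2.0,
    min_cov: float = 10.0,
) -> list[PeakInterval]:
    """Sliding-window RIP/input enrichment peak caller.

    Windows of ``window`` nt advance by ``window // 2``.  A window is retained
    when its library-size-normalized RIP/input ratio reaches
    ``enrich_threshold`` and its mean RIP coverage reaches ``min_cov``;
    overlapping or adjacent retained windows merge into one peak whose
    intensity is the length-weighted mean ratio of its windows.  Windows with
    zero input coverage are skipped (ratio undefined).
    """
    rip = np.asarray(rip_cov, dtype=float)
    inp = np.asarray(input_cov, dtype=float)
    if rip.shape != inp.shape:
        raise ValueError("coverage arrays must have equal length")
    if window < 1:
        raise ValueError("window must be >= 1")
    L = rip.size
    if L == 0:
        return []
    # library-size normalization so rip ~ inp genome-wide gives ratio ~ 1
    scale = inp.sum() / rip.sum() if rip.sum() > 0 else 1.0
    step = max(window // 2, 1)
    starts = list(range(0, max(L - window, 0) + 1, step))
    if not starts:
        starts = [0]
    kept: list[tuple[int, int, float]] = []
    for s in starts:
        e = min(s + window, L)
        inp_mean = inp[s:e].mean()
        rip_mean = rip[s:e].mean()
        if inp_mean == 0:
            continue  # undefined ratio
        ratio = (rip_mean * scale) / inp_mean
        if ratio >= enrich_threshold and rip_mean >= min_cov:
            kept.append((s, e, ratio))
    if not kept:
        return []
    peaks: list[PeakInterval] = []
    cur_s, cur_e = kept[0][0], kept[0][1]
    acc: list[tuple[int, float]] = [(kept[0][1] - kept[0][0], kept[0][2])]
    for s, e, ratio in kept[1:]:
        if s <= cur_e:  # overlapping or adjacent
            cur_e = max(cur_e, e)
            acc.append((e - s, ratio))
        else:
            w = sum(a for a, _ in acc)
            peaks.append(
                PeakInterval(gene_id, cur_s, cur_e, sum(a * r for a, r in acc) / w)
            )
            cur_s, cur_e, acc = s, e, [(e - s, ratio)]
    w = sum(a for a, _ in acc)
    peaks.append(PeakInterval(gene_id, cur_s, cur_e, sum(a * r for a, r in acc) / w))
    return peaks


def call_sites(seq: str, peaks: Sequence[PeakInterval], gene_id: str | None = None) -> list[MotifSite]:
    """Single-nucleotide m6A sites: sense-strand DRACH motifs whose
    methylatable A (position 3 of the 5-mer, 1-based) lies inside a peak."""
    for p in peaks:
        if p.end > len(seq):
            raise ValueError(f"peak ({p.start},{p.end}) beyond sequence length {len(seq)}")
    in_peak = np.zeros(len(seq), dtype=bool)
    for p in peaks:
        in_peak[p.start : p.end] = True
    out = []
    for site in scan_drach(seq, "sense", gene_id=gene_id):
        if in_peak[site.pos]:
            out.append(MotifSite(site.pos, site.strand, site.kmer, gene_id, True))
    return out
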