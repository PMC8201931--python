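"""Phylostratigraphic aging of m6A sites.

Each single-nucleotide site is dated by the most distantly related species in
which the DRACH motif is conserved at the orthologous position, over an
ordered species ladder (stratum 0 = focal-species-specific).  The age
distributions of m6A sites (DRACH in peaks) are compared against the neutral
control (DRACH outside peaks) by Wilcoxon rank-sum, and age is related to
peak membership and peak intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import A_OFFSET, MotifSite, PairAlignment, is_drach


@dataclass
class SpeciesLadder:
    """Ordered species, nearest to farthest relative of the focal species.

    Stratum indices run 0..K where 0 means focal-species-specific and
    stratum k >= 1 corresponds to ``species[k-1]``.
    """

    species: list[str]

    def __post_init__(self):
        if len(self.species) < 1:
            raise ValueError("ladder needs at least one non-focal species")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in ladder")

    @property
    def n_strata(self) -> int:
        return len(self.species)

    def stratum(self, species: str) -> int:
        return self.species.index(species) + 1


@dataclass
class AgeAssignment:
    site: MotifSite
    age_stratum: int
    conserved_in: set[str] = field(default_factory=set)
    uncovered_in: set[str] = field(default_factory=set)


def site_conserved(
    site: MotifSite,
    pairwise_aln: PairAlignment,
    pattern_level: bool = True,
) -> tuple[bool, bool]:
    """Is the site's motif intact in the aligned species sequence?

    ``pairwise_aln`` aligns the focal sequence (as ``aligned_pseudo``) to one
    species' ortholog (as ``aligned_cognate``).  Conservation requires all 5
    motif columns to align gap-free and the species' homologous 5-mer to match
    DRACH (``pattern_level=True``, default) or to be identical to the focal
    5-mer (``pattern_level=False``).  Returns (conserved, covered); a site
    outside the aligned span is not-conserved with covered=False.
    """
    focal2col: dict[int, int] = {}
    for col, (fp, _) in enumerate(pairwise_aln.column_map):
        if fp is not None:
            focal2col[fp] = col
    cols = []
    for off in range(-A_OFFSET, 5 - A_OFFSET):
        p = site.pos + off
        if p not in focal2col:
            return False, False  # motif runs outside the aligned span
        cols.append(focal2col[p])
    species_pos = [pairwise_aln.column_map[c][1] for c in cols]
    if any(sp is None for sp in species_pos):
        return False, True  # gap in the species sequence: motif disrupted
    kmer = "".join(pairwise_aln.cognate_seq[p] for p in species_pos)
    focal_kmer = "".join(pairwise_aln.pseudo_seq[site.pos + off] for off in range(-A_OFFSET, 5 - A_OFFSET))
    if pattern_level:
        return is_drach(kmer), True
    return kmer == focal_kmer, True


def assign_age(
    site: MotifSite,
    alignments: Mapping[str, PairAlignment],
    ladder: SpeciesLadder,
    pattern_level: bool = True,
) -> AgeAssignment:
    """Age = maximum stratum among species where the motif is conserved;
    0 (focal-specific) when conserved nowhere.  A species missing from
    ``alignments`` counts as not-conserved and is recorded as uncovered.
    """
    conserved: set[str] = set()
    uncovered: set[str] = set()
    age = 0
    for sp in ladder.species:
        aln = alignments.get(sp)
        if aln is None:
            uncovered.add(sp)
            continue
        ok, covered = site_conserved(site, aln, pattern_level=pattern_level)
        if not covered:
            uncovered.add(sp)
        if ok:
            conserved.add(sp)
            age = max(age, ladder.stratum(sp))
    return AgeAssignment(site, age, conserved, uncovered)


def compare_age_distributions(
    m6a_ages: Sequence[int], control_ages: Sequence[int]
) -> tuple[float, float, pd.DataFrame]:
    """Two-tailed Wilcoxon rank-sum of m6A-site ages vs control DRACH ages,
    with a per-stratum proportion table for the stacked-bar view.

    A negative statistic means the m6A sites are younger than the controls.
    """
    a = np.asarray(m6a_ages)
    b = np.asarray(control_ages)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 sites per group")
    stat, p = stats.ranksums(a, b)
    strata = np.arange(0, max(a.max(), b.max()) + 1)
    table = pd.DataFrame(
        {
            "stratum": strata,
            "m6a_proportion": [(a == s).mean() for s in strata],
            "control_proportion": [(b == s).mean() for s in strata],
        }
    )
    return float(stat), float(p), table


def age_peak_relationships(
    ages: Sequence[int],
    peak_membership: Sequence[bool],
    peak_intensities: Sequence[float],
    n_strata: int,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-stratum in-peak proportion, and the Spearman correlation of
    normalized age (stratum / K, 0 = youngest, 1 = oldest) with peak
    intensity among in-peak sites.

    Empty strata report NaN proportions (undefined, not zero).  The
    correlation is (nan, nan) when fewer than 3 in-peak sites exist or a
    variable is constant.
    """
    ages = np.asarray(ages)
    member = np.asarray(peak_membership, dtype=bool)
    inten = np.asarray(peak_intensities, dtype=float)
    if not (ages.size == member.size == inten.size):
        raise ValueError("ages, membership and intensities must align by site")
    rows = []
    for s in range(n_strata + 1):
        sel = ages == s
        prop = float(member[sel].mean()) if sel.any() else float("nan")
        rows.append((s, int(sel.sum()), prop))
    table = pd.DataFrame(rows, columns=["stratum", "n_sites", "in_peak_proportion"])
    sel = member
    if sel.sum() >= 3 and np.unique(ages[sel]).size > 1 and np.unique(inten[sel]).size > 1:
        rho, p = stats.spearmanr(ages[sel] / n_strata, inten[sel])
        corr = (float(rho), float(p))
    else:
        corr = (float("nan"), float("nan"))
    return table, corr
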