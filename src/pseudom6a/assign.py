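"""SNP-aware strict read assignment for homologous loci.

Pseudogenes and their cognate genes are near-identical, so conventional
mapping cross-assigns reads between the two.  The policy implemented here
admits a read at a locus offset only if every mismatch falls on a known SNP
position of that locus and carries its recorded alternate allele; a read is
used only when exactly one admissible placement exists across all loci and
offsets (both strands).  A lenient mode (up to k mismatches anywhere,
default 3) reproduces the conventional-mapping contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .motifs import revcomp


@dataclass
class Locus:
    """A reference transcript with its known SNP positions.

    ``snps`` maps 0-based position -> set of allowed alternate bases.
    """

    id: str
    seq: str
    snps: dict[int, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.seq = self.seq.upper()
        for pos, alts in self.snps.items():
            if not 0 <= pos < len(self.seq):
                raise ValueError(f"SNP position {pos} outside locus {self.id}")
            if self.seq[pos] in alts:
                raise ValueError(
                    f"SNP alternate equals reference at {self.id}:{pos}"
                )


@dataclass
class Placement:
    locus_id: str
    offset: int
    strand: str  # "+" | "-"
    n_mismatches: int


@dataclass
class Assignment:
    read_id: str
    status: str  # "unique" | "ambiguous" | "unassigned"
    locus_id: str | None = None
    offset: int | None = None
    strand: str | None = None


def loci_from_snp_table(sequences: dict[str, str], snp_df: pd.DataFrame) -> list[Locus]:
    """Build Locus objects from a sequences dict and a SNP table with columns
    (locus, position, ref, alt)."""
    snp_map: dict[str, dict[int, set[str]]] = {g: {} for g in sequences}
    for row in snp_df.itertuples(index=False):
        if row.locus in snp_map:
            snp_map[row.locus].setdefault(int(row.position), set()).add(str(row.alt))
    return [Locus(g, s, snp_map[g]) for g, s in sequences.items()]


def admissible_placements(
    read: str,
    loci: Sequence[Locus],
    lenient_k: int | None = None,
    any_base_at_snp: bool = False,
    both_strands: bool = True,
) -> list[Placement]:
    """Every (locus, offset, strand) where the read may be placed.

    Strict policy (``lenient_k=None``): all mismatches must sit on recorded
    SNP positions and, unless ``any_base_at_snp``, carry the recorded
    alternate.  Lenient policy: at most ``lenient_k`` mismatches anywhere.
    The scan is exhaustive over every offset of every locus; the reverse
    strand is handled by scanning the read's reverse complement.  Loci
    shorter than the read contribute no offsets.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    variants = [(read, "+")]
    if both_strands:
        variants.append((revcomp(read), "-"))
    placements = []
    for query, strand in variants:
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        for locus in loci:
            if len(query) > len(locus.seq):
                continue
            lseq = np.frombuffer(locus.seq.encode(), dtype=np.uint8)
            windows = sliding_window_view(lseq, len(query))
            mm_counts = (windows != q).sum(axis=1)
            if lenient_k is not None:
                for o in np.nonzero(mm_counts <= lenient_k)[0]:
                    placements.append(
                        Placement(locus.id, int(o), strand, int(mm_counts[o]))
                    )
                continue
            # a strict-admissible offset mismatches only at SNP positions,
            # so mm_counts <= |snps| is an exact prefilter
            for o in np.nonzero(mm_counts <= len(locus.snps))[0]:
                off = int(o)
                mmpos = np.nonzero(windows[off] != q)[0]
                ok = True
                for i in mmpos:
                    pos = off + int(i)
                    if pos not in locus.snps:
                        ok = False
                        break
                    if not any_base_at_snp and query[int(i)] not in locus.snps[pos]:
                        ok = False
                        break
                if ok:
                    placements.append(Placement(locus.id, off, strand, len(mmpos)))
    return placements


def assign_read(
    read: str,
    loci: Sequence[Locus],
    read_id: str = "read",
    lenient_k: int | None = None,
    any_base_at_snp: bool = False,
) -> Assignment:
    """Unique / ambiguous / unassigned status for one read.

    A read identical on both strands (a perfect palindrome spanning one
    locus offset twice) counts as two placements and is ambiguous; ambiguous
    reads are discarded downstream, never fractionally allocated.
    """
    placements = admissible_placements(
        read, loci, lenient_k=lenient_k, any_base_at_snp=any_base_at_snp
    )
    if len(placements) == 0:
        return Assignment(read_id, "unassigned")
    if len(placements) > 1:
        return Assignment(read_id, "ambiguous")
    p = placements[0]
    return Assignment(read_id, "unique", p.locus_id, p.offset, p.strand)


def count_by_gene(
    reads: Iterable[tuple[str, str, str | None]],
    loci: Sequence[Locus],
    lenient_k: int | None = None,
    any_base_at_snp: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-locus unique-read counts plus, when true origins are known, a
    confusion matrix (true origin x assigned locus).

    ``reads`` yields (read_id, sequence, true_origin-or-None).  The counts
    table also tallies ambiguous and unassigned reads.  Assignment is
    independent of read order.
    """
    counts = {locus.id: 0 for locus in loci}
    ambiguous = unassigned = 0
    confusion: dict[tuple[str, str], int] = {}
    have_origins = False
    for read_id, seq, origin in reads:
        a = assign_read(
            seq, loci, read_id=read_id, lenient_k=lenient_k, any_base_at_snp=any_base_at_snp
        )
        if a.status == "unique":
            counts[a.locus_id] += 1
            if origin is not None:
                have_origins = True
                confusion[(origin, a.locus_id)] = confusion.get((origin, a.locus_id), 0) + 1
        elif a.status == "ambiguous":
            ambiguous += 1
            if origin is not None:
                have_origins = True
                confusion[(origin, "*ambiguous*")] = confusion.get((origin, "*ambiguous*"), 0) + 1
        else:
            unassigned += 1
            if origin is not None:
                have_origins = True
                confusion[(origin, "*unassigned*")] = confusion.get((origin, "*unassigned*"), 0) + 1
    count_df = pd.DataFrame(
        sorted(counts.items()), columns=["locus_id", "unique_reads"]
    )
    count_df.attrs["ambiguous"] = ambiguous
    count_df.attrs["unassigned"] = unassigned
    conf_df = None
    if have_origins:
        conf_df = (
            pd.Series(confusion)
            .rename_axis(["true_origin", "assigned"])
            .reset_index(name="reads")
            .sort_values(["true_origin", "assigned"])
            .reset_index(drop=True)
        )
    return count_df, conf_df
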