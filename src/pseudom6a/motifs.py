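"""DRACH motif evolution between pseudogenes and their cognate genes.

m6A methyltransferases install the mark on DRACH 5-mers (D=[AGT], R=[AG],
then the methylated A, C, H=[ACT]).  This module aligns each pseudogene to
its cognate protein-coding gene, classifies DRACH motifs as gained, lost or
shared on each strand within the aligned regions covered by m6A peaks, tests
whether sense-strand gains exceed the antisense neutral background
(a 2x2 chi-square on pseudogenes gaining at least one motif), and relates
pseudogene-cognate sequence divergence to m6A level.

The antisense strand is the built-in neutral control: point mutation pressure
is identical on the two strands, so any sense excess of motif gains is the
signature of selection acting on the methylatable strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from scipy import stats

# ---------------------------------------------------------------------------
# DRACH primitives
# ---------------------------------------------------------------------------

DRACH_D = frozenset("AGT")
DRACH_R = frozenset("AG")
DRACH_H = frozenset("ACT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: offset of the methylated A within the 5-mer (0-based)
A_OFFSET = 2


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_drach(kmer: str) -> bool:
    """True iff a 5-mer matches D[AGT] R[AG] A C H[ACT]."""
    return (
        len(kmer) == 5
        and kmer[0] in DRACH_D
        and kmer[1] in DRACH_R
        and kmer[2] == "A"
        and kmer[3] == "C"
        and kmer[4] in DRACH_H
    )


# integer encoding used by the vectorised scanner: A=0, C=1, G=2, T=3
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return arr


def drach_central_a_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask over positions: True where the base is the methylatable A
    of a sense-strand DRACH.

    Works on a 1-D array or row-wise on a 2-D (n_seqs, length) array.
    """
    was_1d = codes.ndim == 1
    codes = np.atleast_2d(codes)
    n, L = codes.shape
    mask = np.zeros((n, L), dtype=bool)
    if L >= 5:
        d = codes[:, : L - 4] != 1  # not C
        r = (codes[:, 1 : L - 3] == 0) | (codes[:, 1 : L - 3] == 2)
        a = codes[:, 2 : L - 2] == 0
        c = codes[:, 3 : L - 1] == 1
        h = codes[:, 4:] != 2  # not G
        mask[:, 2 : L - 2] = d & r & a & c & h
    return mask[0] if was_1d else mask


@dataclass(frozen=True)
class MotifSite:
    """A single DRACH occurrence.

    ``pos`` is the 0-based coordinate of the methylatable A in the input
    sequence's forward frame (antisense hits are mapped back through the
    reverse complement).  ``kmer`` is the motif as read on its own strand.
    """

    pos: int
    strand: str  # "sense" | "antisense"
    kmer: str
    gene_id: str | None = None
    in_peak: bool | None = None


def scan_drach(seq: str, strand: str = "sense", gene_id: str | None = None) -> list[MotifSite]:
    """Find every DRACH occurrence on one strand of ``seq``.

    Antisense scanning is a sense scan of the reverse complement with the
    central-A coordinate mapped back to the forward frame
    (``pos = len(seq) - 1 - pos_rc``).
    """
    if strand not in ("sense", "antisense"):
        raise ValueError(f"strand must be 'sense' or 'antisense', got {strand!r}")
    target = seq if strand == "sense" else revcomp(seq)
    L = len(target)
    sites = []
    for i in range(L - 4):
        kmer = target[i : i + 5]
        if is_drach(kmer):
            p = i + A_OFFSET
            pos = p if strand == "sense" else L - 1 - p
            sites.append(MotifSite(pos=pos, strand=strand, kmer=kmer, gene_id=gene_id))
    return sites


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------


@dataclass
class PairAlignment:
    """A gapped pairwise alignment of a pseudogene to its cognate gene.

    ``column_map[c] = (pseudo_pos | None, cognate_pos | None)`` — the sequence
    coordinate each alignment column corresponds to, None at a gap.
    """

    pair_id: str
    aligned_pseudo: str
    aligned_cognate: str
    score: float = 0.0
    column_map: list[tuple[int | None, int | None]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.aligned_pseudo) != len(self.aligned_cognate):
            raise ValueError("aligned sequences must have equal length")
        if not self.column_map:
            self.column_map = _build_column_map(self.aligned_pseudo, self.aligned_cognate)

    @property
    def pseudo_seq(self) -> str:
        return self.aligned_pseudo.replace("-", "")

    @property
    def cognate_seq(self) -> str:
        return self.aligned_cognate.replace("-", "")


def _build_column_map(a: str, b: str) -> list[tuple[int | None, int | None]]:
    cm = []
    ia = ib = 0
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            raise ValueError("all-gap alignment column")
        pa = pb = None
        if ca != "-":
            pa = ia
            ia += 1
        if cb != "-":
            pb = ib
            ib += 1
        cm.append((pa, pb))
    return cm


#: default scoring: match +2, mismatch -1, first gap residue -5, each further -1
DEFAULT_SCORING = {"match": 2.0, "mismatch": -1.0, "gap_open": -5.0, "gap_extend": -1.0}


def global_align(
    pseudo_seq: str,
    cognate_seq: str,
    pair_id: str = "pair",
    scoring: dict | None = None,
) -> PairAlignment:
    """Optimal global alignment under affine-gap scoring.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``.  Ties are
    broken deterministically by taking the aligner's first optimal traceback.
    """
    if not pseudo_seq or not cognate_seq:
        raise ValueError("sequences must be non-empty")
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = sc["match"]
    aligner.mismatch_score = sc["mismatch"]
    aligner.open_gap_score = sc["gap_open"]
    aligner.extend_gap_score = sc["gap_extend"]
    aln = aligner.align(pseudo_seq, cognate_seq)[0]
    a, b = str(aln[0]), str(aln[1])
    return PairAlignment(pair_id=pair_id, aligned_pseudo=a, aligned_cognate=b, score=aln.score)


def alignment_from_gapped(pair_id: str, aligned_pseudo: str, aligned_cognate: str) -> PairAlignment:
    """Adapter for precomputed alignments (e.g. ClustalW output read as aligned
    FASTA): wrap two equal-length gapped strings as a PairAlignment."""
    return PairAlignment(pair_id=pair_id, aligned_pseudo=aligned_pseudo.upper(), aligned_cognate=aligned_cognate.upper())


# ---------------------------------------------------------------------------
# Motif gain / loss classification
# ---------------------------------------------------------------------------


@dataclass
class MotifChangeRecord:
    """Per-pair, per-strand DRACH bookkeeping within the peak-covered region.

    gained: motifs present in the pseudogene and absent at the homologous
    cognate position; lost: the reverse; shared: present in both;
    gap_spanning: motifs whose 5 columns overlap a gap (homology unassignable,
    excluded from the other tallies).
    """

    pair_id: str
    strand: str
    gained: int = 0
    lost: int = 0
    shared: int = 0
    gap_spanning: int = 0
    region: frozenset[int] = frozenset()


def _positions_in_peaks(peaks: Iterable[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for start, end in peaks:
        out.update(range(start, end))
    return out


def classify_motif_changes(
    aln: PairAlignment,
    peaks_pseudo: Sequence[tuple[int, int]],
    peaks_cognate: Sequence[tuple[int, int]],
    strand: str = "sense",
) -> MotifChangeRecord:
    """Count gained / lost / shared DRACH motifs on one strand within the
    aligned region covered by m6A peaks of either gene.

    The counted region is the set of alignment columns whose pseudogene OR
    cognate coordinate falls in that gene's peaks (the union of the two peak
    projections).  A motif is counted when the column of its methylatable A
    lies in the region.  A pseudogene motif is *gained* iff its 5 columns are
    gap-free and the cognate's homologous 5-mer is not DRACH; *lost* is the
    mirror image; motifs overlapping gap columns go to ``gap_spanning``.
    """
    np_len = len(aln.pseudo_seq)
    nc_len = len(aln.cognate_seq)
    for s, e in peaks_pseudo:
        if not (0 <= s < e <= np_len):
            raise ValueError(f"pseudogene peak ({s},{e}) out of range for length {np_len}")
    for s, e in peaks_cognate:
        if not (0 <= s < e <= nc_len):
            raise ValueError(f"cognate peak ({s},{e}) out of range for length {nc_len}")

    pseudo_in = _positions_in_peaks(peaks_pseudo)
    cog_in = _positions_in_peaks(peaks_cognate)

    # seq coordinate -> alignment column
    p2col: dict[int, int] = {}
    c2col: dict[int, int] = {}
    for col, (pp, cp) in enumerate(aln.column_map):
        if pp is not None:
            p2col[pp] = col
        if cp is not None:
            c2col[cp] = col

    region = frozenset(
        col
        for col, (pp, cp) in enumerate(aln.column_map)
        if (pp is not None and pp in pseudo_in) or (cp is not None and cp in cog_in)
    )

    rec = MotifChangeRecord(pair_id=aln.pair_id, strand=strand, region=region)

    def motif_cols(seq_pos_a: int, s2col: dict[int, int]) -> list[int]:
        return [s2col[seq_pos_a + off] for off in range(-A_OFFSET, 5 - A_OFFSET)]

    def partner_kmer(cols: list[int], which: int, seq: str) -> str | None:
        """Contiguous homologous 5-mer of the partner, None when the motif
        spans a gap (non-consecutive columns = insertion in the partner's
        frame; None position = deletion)."""
        if any(b - a != 1 for a, b in zip(cols, cols[1:])):
            return None
        positions = [aln.column_map[c][which] for c in cols]
        if any(p is None for p in positions):
            return None
        kmer = "".join(seq[p] for p in positions)
        return kmer if strand == "sense" else revcomp(kmer)

    seen_shared_cols: set[tuple[int, ...]] = set()
    for site in scan_drach(aln.pseudo_seq, strand):
        cols = motif_cols(site.pos, p2col)
        if p2col[site.pos] not in region:
            continue
        partner = partner_kmer(cols, 1, aln.cognate_seq)
        if partner is None:
            rec.gap_spanning += 1
        elif is_drach(partner):
            rec.shared += 1
            seen_shared_cols.add(tuple(cols))
        else:
            rec.gained += 1
    for site in scan_drach(aln.cognate_seq, strand):
        cols = motif_cols(site.pos, c2col)
        if c2col[site.pos] not in region:
            continue
        if tuple(cols) in seen_shared_cols:
            continue  # already counted as shared from the pseudogene side
        partner = partner_kmer(cols, 0, aln.pseudo_seq)
        if partner is None:
            rec.gap_spanning += 1
        elif is_drach(partner):
            # shared motif whose pseudogene-side central A sat outside the
            # region convention; count once from the cognate side
            rec.shared += 1
        else:
            rec.lost += 1
    return rec


# ---------------------------------------------------------------------------
# Strand-bias test and divergence statistics
# ---------------------------------------------------------------------------


@dataclass
class StrandBiasResult:
    chi2_yates: float
    p_yates: float
    chi2: float
    p: float
    table: np.ndarray
    low_expected: bool  # any expected cell < 1


def strand_bias_test(
    n_sense_gaining: int,
    n_sense_total: int,
    n_antisense_gaining: int,
    n_antisense_total: int,
) -> StrandBiasResult:
    """Two-tailed chi-square on the 2x2 table of pseudogenes gaining at least
    one DRACH motif on the sense vs antisense strand.

    Returns both the Yates-corrected test (the reported default) and the
    uncorrected statistic.  Degenerate tables with a zero margin give
    chi2 = 0, p = 1.
    """
    if n_sense_total <= 0 or n_antisense_total <= 0:
        raise ValueError("totals must be positive")
    if n_sense_gaining > n_sense_total or n_antisense_gaining > n_antisense_total:
        raise ValueError("gaining counts exceed totals")
    table = np.array(
        [
            [n_sense_gaining, n_sense_total - n_sense_gaining],
            [n_antisense_gaining, n_antisense_total - n_antisense_gaining],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return StrandBiasResult(0.0, 1.0, 0.0, 1.0, table, True)
    res_y = stats.chi2_contingency(table, correction=True)
    res_u = stats.chi2_contingency(table, correction=False)
    low = bool((res_u.expected_freq < 1).any())
    return StrandBiasResult(
        chi2_yates=float(res_y.statistic),
        p_yates=float(res_y.pvalue),
        chi2=float(res_u.statistic),
        p=float(res_u.pvalue),
        table=table,
        low_expected=low,
    )


def sequence_divergence(aln: PairAlignment) -> float:
    """Mismatch proportion over gap-free alignment columns.

    Columns containing a gap on either side are excluded from numerator and
    denominator.  Raises if the alignment has no gap-free column.
    """
    mism = total = 0
    for ca, cb in zip(aln.aligned_pseudo, aln.aligned_cognate):
        if ca == "-" or cb == "-":
            continue
        total += 1
        if ca != cb:
            mism += 1
    if total == 0:
        raise ValueError("divergence undefined: no gap-free columns")
    return mism / total


def divergence_level_correlation(
    divergences: Sequence[float], levels: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between pseudogene-cognate
    sequence divergence and pseudogene m6A level.  Call separately per
    pseudogene class (processed / unprocessed)."""
    x = np.asarray(divergences, dtype=float)
    y = np.asarray(levels, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
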