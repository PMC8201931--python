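"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from the definitions, without reusing
the package's internals: exhaustive scans, explicit enumerations, and hand
step-up procedures.  Slow is fine; these run on tiny inputs.
"""

from __future__ import annotations

from itertools import product

#: all 54 DRACH 5-mers, enumerated explicitly
DRACH_SET = frozenset(
    d + r + "AC" + h for d, r, h in product("AGT", "AG", "ACT")
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "-": "-"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def drach_positions(seq: str) -> list[int]:
    """Central-A positions of every DRACH 5-mer, by direct membership test."""
    return [i + 2 for i in range(len(seq) - 4) if seq[i : i + 5] in DRACH_SET]


def drach_positions_antisense(seq: str) -> list[int]:
    """Antisense central-A positions mapped back to forward coordinates."""
    r = rc(seq)
    return sorted(len(seq) - 1 - p for p in drach_positions(r))


# ---------------------------------------------------------------------------
# Read placement
# ---------------------------------------------------------------------------


def brute_force_placements(read, loci, lenient_k=None, any_base_at_snp=False):
    """Per-offset, per-strand admissibility check straight from the policy
    definition.  Returns a set of (locus_id, offset, strand)."""
    out = set()
    for query, strand in ((read.upper(), "+"), (rc(read.upper()), "-")):
        for locus in loci:
            for off in range(len(locus.seq) - len(query) + 1):
                ok = True
                nmm = 0
                for i, base in enumerate(query):
                    ref = locus.seq[off + i]
                    if base == ref:
                        continue
                    nmm += 1
                    if lenient_k is not None:
                        continue
                    alts = locus.snps.get(off + i)
                    if alts is None or (not any_base_at_snp and base not in alts):
                        ok = False
                        break
                if lenient_k is not None:
                    ok = nmm <= lenient_k
                if ok:
                    out.add((locus.id, off, strand))
    return out


# ---------------------------------------------------------------------------
# Global alignment score by exhaustive path enumeration
# ---------------------------------------------------------------------------


def best_alignment_score_enumerated(a, b, match=2.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0):
    """Maximum global-alignment score over all alignments of two short
    strings, enumerated as M/D/I edit paths.  A gap run of length L scores
    gap_open + (L - 1) * gap_extend."""

    best = [float("-inf")]

    def walk(i, j, score, prev_op):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch), "M")
        if i < len(a):  # gap in b
            walk(i + 1, j, score + (gap_extend if prev_op == "D" else gap_open), "D")
        if j < len(b):  # gap in a
            walk(i, j + 1, score + (gap_extend if prev_op == "I" else gap_open), "I")

    walk(0, 0, 0.0, None)
    return best[0]


# ---------------------------------------------------------------------------
# Motif gain/loss recount by walking alignment columns
# ---------------------------------------------------------------------------


def recount_motif_changes(aligned_p, aligned_c, peaks_p, peaks_c, strand):
    """Independent recount of gained/lost/shared/gap_spanning DRACH motifs.

    Walks the two gapped strings column by column, rebuilds the coordinate
    maps, takes the region as the union of the two peak projections, and
    classifies each strand-appropriate motif of each ungapped sequence.
    Motifs are keyed by the alignment columns they occupy so a motif present
    on both sides is counted once as shared.
    """
    p_seq = aligned_p.replace("-", "")
    c_seq = aligned_c.replace("-", "")
    p_pos2col, c_pos2col = {}, {}
    ip = ic = 0
    for col, (x, y) in enumerate(zip(aligned_p, aligned_c)):
        if x != "-":
            p_pos2col[ip] = col
            ip += 1
        if y != "-":
            c_pos2col[ic] = col
            ic += 1

    def in_peaks(pos, peaks):
        return any(s <= pos < e for s, e in peaks)

    region = set()
    for pos, col in p_pos2col.items():
        if in_peaks(pos, peaks_p):
            region.add(col)
    for pos, col in c_pos2col.items():
        if in_peaks(pos, peaks_c):
            region.add(col)

    def motif_centers(seq):
        if strand == "sense":
            return drach_positions(seq)
        return drach_positions_antisense(seq)

    def partner_window(cols, own2col, other2col, other_seq):
        """(kmer, spans_gap): the partner's homologous 5-mer, or gap flag when
        the motif columns are non-consecutive or the partner is gapped."""
        if any(b - a != 1 for a, b in zip(cols, cols[1:])):
            return None, True
        col2other = {c: p for p, c in other2col.items()}
        if any(c not in col2other for c in cols):
            return None, True
        return "".join(other_seq[col2other[c]] for c in cols), False

    gained = lost = shared = gap_spanning = 0
    shared_cols = set()
    for center in motif_centers(p_seq):
        cols = [p_pos2col[center + off] for off in range(-2, 3)]
        if cols[2] not in region:
            continue
        kmer, gap = partner_window(cols, p_pos2col, c_pos2col, c_seq)
        if gap:
            gap_spanning += 1
        elif (kmer if strand == "sense" else rc(kmer)) in DRACH_SET:
            shared += 1
            shared_cols.add(tuple(cols))
        else:
            gained += 1
    for center in motif_centers(c_seq):
        cols = [c_pos2col[center + off] for off in range(-2, 3)]
        if cols[2] not in region:
            continue
        if tuple(cols) in shared_cols:
            continue
        kmer, gap = partner_window(cols, c_pos2col, p_pos2col, p_seq)
        if gap:
            gap_spanning += 1
        elif (kmer if strand == "sense" else rc(kmer)) in DRACH_SET:
            shared += 1
        else:
            lost += 1
    return {"gained": gained, "lost": lost, "shared": shared, "gap_spanning": gap_spanning}


# ---------------------------------------------------------------------------
# Site age and BH step-up
# ---------------------------------------------------------------------------


def brute_force_age(focal_kmers_by_species, ladder_species):
    """Max stratum over species whose homologous 5-mer is DRACH.

    ``focal_kmers_by_species``: species -> 5-mer string or None (uncovered).
    """
    age = 0
    for k, sp in enumerate(ladder_species, start=1):
        kmer = focal_kmers_by_species.get(sp)
        if kmer is not None and kmer in DRACH_SET:
            age = max(age, k)
    return age


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up walk."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        q = min(prev, pvalues[i] * m / rank_from_end)
        adj[i] = q
        prev = q
    return adj
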