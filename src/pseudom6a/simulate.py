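"""Synthetic cohort generator with known ground truth.

This module produces a complete, self-consistent synthetic dataset with the
statistical structure the downstream analyses assume:

* pseudogene birth — each cognate transcript spawns a pseudogene copy by
  per-site substitution under a soft-selection model that favours mutations
  creating sense-strand DRACH motifs (selection coefficient ``s``; ``s = 0``
  is exactly strand-symmetric);
* ortholog evolution — neutral substitutions accumulated outward along an
  ordered species ladder, giving per-species sequences whose motif
  conservation defines true site ages;
* LAIC-seq-style fraction counts — methylation-informative reads split
  between eluate and supernatant by the true m6A level, so the level
  estimator's generative inverse;
* RIP/input per-base coverage with enriched blocks around truly methylated
  DRACH sites;
* compartment and population expression — m6A-dependent cytosolic decay for
  processed pseudogenes and pseudogene-cognate expression coupling
  attenuated by the pseudogene's m6A level (the ceRNA analogue).

Every random draw descends from a single seed through named substreams, so an
identical :class:`SimulationConfig` yields a bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dataio
from .motifs import drach_central_a_mask, encode

_BASES = np.array(list("ACGT"))

#: default species ladder, nearest to farthest relative of the focal species,
#: with per-branch substitution rates accumulating outward
DEFAULT_TREE = ["chimp", "gorilla", "orangutan", "rhesus"]
DEFAULT_BRANCH_RATES = [0.04, 0.09, 0.16, 0.28]


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


# ---------------------------------------------------------------------------
# Configuration and bundle containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All knobs of the generative model.

    The defaults are the cohort conditions used throughout: 200 pairs,
    70% processed, positive selection s = 2 on sense DRACH creation,
    LAIC depth 2000 reads/gene/fraction, m6A-dependent cytosolic decay for
    processed pseudogenes, ceRNA coupling 0.6 attenuated by pseudogene m6A
    level, and a 462-sample population expression matrix.
    """

    n_pairs: int = 200
    frac_processed: float = 0.7
    seq_length_range: tuple[int, int] = (600, 1500)
    mutation_rate: float = 0.18
    rate_spread: tuple[float, float] = (0.25, 2.0)
    selection_coeff: float = 2.0
    snp_rate: float = 0.002
    tree: list[str] = field(default_factory=lambda: list(DEFAULT_TREE))
    branch_rates: list[float] = field(default_factory=lambda: list(DEFAULT_BRANCH_RATES))
    laic_depth: float = 2000.0
    min_informative: int = 20
    level_intercept: float = 0.12
    level_slope: float = 5.0
    level_sd: float = 0.15
    cognate_level_beta: tuple[float, float] = (1.3, 3.5)
    decay_coeff: float = 1.5
    export_factor: float = 3.0
    expression_sd: float = 0.8
    noise_sd: float = 0.3
    ceRNA_coupling: float = 0.6
    coupling_attenuation: float = 0.8
    n_samples: int = 462
    coverage_depth: float = 30.0
    rip_enrichment: float = 6.0
    peak_halfwidth: int = 60
    site_choice: str = "young_biased"  # young_biased | age_increasing | uniform
    overdispersion: float = 0.0
    read_length: int = 100
    reads_per_gene: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name in ("frac_processed", "coupling_attenuation", "ceRNA_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("mutation_rate", "snp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.selection_coeff < 0 or self.decay_coeff < 0:
            raise ValueError("selection_coeff and decay_coeff must be >= 0")
        if len(self.branch_rates) != len(self.tree):
            raise ValueError("branch_rates must match tree length")
        if any(r < 0 for r in self.branch_rates):
            raise ValueError("branch rates must be >= 0")
        if self.n_samples < 3:
            raise ValueError("n_samples < 3: correlation undefined downstream")
        if self.site_choice not in ("young_biased", "age_increasing", "uniform"):
            raise ValueError(f"unknown site_choice {self.site_choice!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: independent generator derived from the seed."""
        h = np.frombuffer(stream.encode(), dtype=np.uint8)
        return np.random.default_rng(np.random.SeedSequence([self.seed, *h.tolist()]))


@dataclass
class GenePair:
    """A pseudogene transcript linked to its cognate protein-coding gene."""

    pseudogene_id: str
    cognate_id: str
    klass: str  # "processed" | "unprocessed"
    exon_count: int


@dataclass
class CohortBundle:
    """Complete synthetic dataset plus the generating ground truth."""

    config: SimulationConfig
    sequences: dict[str, str]
    pairs: list[GenePair]
    snps: dict[str, list[tuple[int, str, str]]]  # gene -> [(pos, ref, alt)]
    fraction_counts: dict[str, tuple[int, int, int]]  # gene -> (input, eluate, sup)
    coverages: dict[str, tuple[np.ndarray, np.ndarray]]  # gene -> (rip, input)
    compartment_expression: dict[str, tuple[float, float]]  # gene -> (nuc, cyt)
    population_expression: pd.DataFrame  # genes x samples
    orthologs: dict[str, dict[str, str]]  # pseudogene -> species -> sequence
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write the bundle to a directory of plain-text files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        dataio.write_fasta(self.sequences, out / "transcripts.fasta")
        dataio.write_tsv(
            pd.DataFrame(
                [(p.pseudogene_id, p.cognate_id, p.klass, p.exon_count) for p in self.pairs],
                columns=["pseudogene_id", "cognate_id", "class", "exon_count"],
            ),
            out / "pairs.tsv",
        )
        snp_rows = [
            (g, pos, ref, alt) for g, lst in self.snps.items() for pos, ref, alt in lst
        ]
        dataio.write_tsv(
            pd.DataFrame(snp_rows, columns=["locus", "position", "ref", "alt"]),
            out / "snps.tsv",
        )
        dataio.write_tsv(
            pd.DataFrame(
                [(g, *c) for g, c in self.fraction_counts.items()],
                columns=["gene_id", "input_count", "eluate_count", "supernatant_count"],
            ),
            out / "fraction_counts.tsv",
        )
        dataio.write_coverage({g: rip for g, (rip, _) in self.coverages.items()}, out / "coverage_rip.tsv")
        dataio.write_coverage({g: inp for g, (_, inp) in self.coverages.items()}, out / "coverage_input.tsv")
        dataio.write_tsv(
            pd.DataFrame(
                [(g, n, c) for g, (n, c) in self.compartment_expression.items()],
                columns=["gene_id", "nucleus", "cytosol"],
            ),
            out / "compartment_expression.tsv",
        )
        self.population_expression.rename_axis("gene_id").reset_index().to_csv(
            out / "population_expression.tsv", sep="\t", index=False
        )
        ortho = {
            f"{pg}|{sp}": seq
            for pg, per_species in self.orthologs.items()
            for sp, seq in per_species.items()
        }
        dataio.write_fasta(ortho, out / "orthologs.fasta")
        dataio.write_json(self.truth, out / "truth.json")
        dataio.write_json({"tree": self.config.tree}, out / "tree.json")


# ---------------------------------------------------------------------------
# Mutation under soft selection for sense-strand DRACH creation
# ---------------------------------------------------------------------------


def _creates_sense_drach(codes: np.ndarray, pos: int, new_base: int) -> bool:
    """Does substituting ``pos`` -> ``new_base`` create a new sense DRACH whose
    methylatable A lies in the affected window?"""
    lo = max(pos - 4, 0)
    hi = min(pos + 5, len(codes))
    window = codes[lo:hi]
    before = drach_central_a_mask(window)
    window = window.copy()
    window[pos - lo] = new_base
    after = drach_central_a_mask(window)
    return bool(np.any(after & ~before))


def mutate_with_selection(
    seq: str,
    rate: float,
    s: float,
    rng: np.random.Generator,
    p0: float | None = None,
) -> str:
    """Mutate a sequence under per-site substitution with soft selection for
    sense-strand DRACH creation.

    Each site independently proposes a substitution with probability ``rate``
    (uniform over the three alternative bases).  A proposal that creates at
    least one new sense-strand DRACH is accepted with probability
    ``min(1, (1 + s) * p0)``; any other proposal with ``p0``.  The default
    baseline is ``p0 = 1 / (1 + s)``, so motif-creating proposals are accepted
    with probability exactly 1 and the neutral case ``s = 0`` accepts every
    proposal, making the process strand-symmetric.

    Proposals are evaluated sequentially in coordinate order; "new" is judged
    against the current state of the sequence.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if s < 0:
        raise ValueError(f"selection coefficient must be >= 0, got {s}")
    codes = encode(seq)  # raises on non-ACGT
    if p0 is None:
        p0 = 1.0 / (1.0 + s)
    if not 0.0 < p0 <= 1.0 / (1.0 + s) + 1e-12:
        raise ValueError("p0 must lie in (0, 1/(1+s)] so acceptance stays <= 1")
    if rate == 0.0:
        return seq
    L = len(codes)
    propose = rng.random(L) < rate
    if not propose.any():
        return seq
    positions = np.nonzero(propose)[0]
    shifts = rng.integers(1, 4, size=positions.size)
    accept_fast = s == 0.0 and p0 >= 1.0  # every proposal accepted: vectorise
    if accept_fast:
        codes = codes.copy()
        codes[positions] = (codes[positions] + shifts) % 4
        return decode(codes)
    p_hit = min(1.0, (1.0 + s) * p0)
    codes = codes.copy()
    u = rng.random(positions.size)
    for i, pos in enumerate(positions):
        new_base = (codes[pos] + shifts[i]) % 4
        p_acc = p_hit if _creates_sense_drach(codes, pos, new_base) else p0
        if u[i] < p_acc:
            codes[pos] = new_base
    return decode(codes)


def mutate_many_neutral(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised neutral mutation of a batch of sequences.

    Equivalent in distribution to :func:`mutate_with_selection` with ``s = 0``
    and default baseline acceptance, applied row-wise to a 2-D code array.
    """
    propose = rng.random(codes.shape) < rate
    shifts = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out = codes.copy()
    out[propose] = (out[propose] + shifts[propose]) % 4
    return out


def strand_gain_flags(
    root: np.ndarray, mutated: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence booleans: gained >= 1 new DRACH on the sense / antisense
    strand (positional comparison; substitution-only evolution keeps
    coordinates aligned).
    """
    root = np.atleast_2d(root)
    mutated = np.atleast_2d(mutated)
    sense = np.any(drach_central_a_mask(mutated) & ~drach_central_a_mask(root), axis=1)
    root_rc = (3 - root)[:, ::-1]
    mut_rc = (3 - mutated)[:, ::-1]
    anti = np.any(drach_central_a_mask(mut_rc) & ~drach_central_a_mask(root_rc), axis=1)
    return sense, anti


def strand_bias_calibration(
    n_cohorts: int,
    n_seqs: int,
    length: int,
    rate: float,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the strand-bias chi-square under neutral evolution.

    Each replicate cohort draws two independent sets of ``n_seqs`` random
    sequences, mutates them neutrally, counts sequences gaining >= 1 DRACH on
    the sense strand in the first set and on the antisense strand in the
    second (independent groups, as the two-proportion test assumes), and
    rejects at the uncorrected p < alpha.  Returns the rejection rate.
    """
    from .motifs import strand_bias_test

    rej = 0
    for _ in range(n_cohorts):
        root = rng.integers(0, 4, size=(2 * n_seqs, length)).astype(np.uint8)
        mutated = mutate_many_neutral(root, rate, rng)
        sense, anti = strand_gain_flags(root, mutated)
        res = strand_bias_test(
            int(sense[:n_seqs].sum()), n_seqs, int(anti[n_seqs:].sum()), n_seqs
        )
        if res.p < alpha:
            rej += 1
    return rej / n_cohorts


def strand_bias_power(
    n_cohorts: int,
    n_seqs: int,
    length: int,
    rate: float,
    s: float,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Detection power of the strand-bias test under selection ``s``.

    Each replicate cohort evolves ``n_seqs`` pseudogenes under
    :func:`mutate_with_selection` and tests sense-vs-antisense gaining
    proportions (Yates-corrected, as reported).  Returns (power, mean ratio
    of sense-gaining to antisense-gaining counts) so the realized effect size
    is observable alongside the rejection rate.
    """
    from .motifs import strand_bias_test

    rej = 0
    ratios = []
    for _ in range(n_cohorts):
        sense_n = anti_n = 0
        for _ in range(n_seqs):
            root_codes = rng.integers(0, 4, size=length).astype(np.uint8)
            mut = mutate_with_selection(decode(root_codes), rate, s, rng)
            f_s, f_a = strand_gain_flags(root_codes[None, :], encode(mut)[None, :])
            sense_n += int(f_s[0])
            anti_n += int(f_a[0])
        ratios.append(sense_n / max(anti_n, 1))
        res = strand_bias_test(sense_n, n_seqs, anti_n, n_seqs)
        if res.p_yates < alpha:
            rej += 1
    return rej / n_cohorts, float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Ortholog evolution along a species ladder
# ---------------------------------------------------------------------------


def evolve_orthologs(
    root_seq: str,
    tree: Sequence[str],
    branch_rates: Sequence[float],
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Accumulate neutral substitutions outward along an ordered species
    ladder.

    ``tree`` lists species from the nearest to the farthest relative of the
    focal species; ``branch_rates[k]`` is the expected number of substitutions
    per site on the branch leading from stratum k to stratum k+1, under the
    uniform (Jukes-Cantor) model with multiple hits: the per-site probability
    of ending in a different base after a branch of rate r is
    ``3/4 * (1 - exp(-4r/3))``, saturating at 3/4 (identity 1/4) as r grows.
    Returns the per-species sequences and, for the truth record, the
    positions at which each species differs from the root.
    """
    if len(tree) == 0:
        raise ValueError("empty species tree")
    if len(branch_rates) != len(tree):
        raise ValueError("branch_rates must match tree length")
    codes = encode(root_seq)
    seqs: dict[str, str] = {}
    subs: dict[str, list[int]] = {}
    current = codes.copy()
    for sp, rate in zip(tree, branch_rates):
        p_change = 0.75 * (1.0 - np.exp(-4.0 * rate / 3.0))
        current = mutate_many_neutral(current[None, :], p_change, rng)[0]
        seqs[sp] = decode(current)
        subs[sp] = np.nonzero(current != codes)[0].tolist()
    return seqs, subs


# ---------------------------------------------------------------------------
# LAIC-seq fraction counts
# ---------------------------------------------------------------------------


def simulate_laic_counts(
    true_level: float,
    depth: float,
    rng: np.random.Generator,
    overdispersion: float = 0.0,
) -> tuple[int, int, int]:
    """Draw (input, eluate, supernatant) read counts for one gene.

    Methylation-informative reads are Poisson(depth); each goes to the eluate
    with probability ``true_level``, else to the supernatant — the generative
    inverse of the level estimator, under which equal eluate and supernatant
    signals mean a 50% m6A level.  Input is an independent Poisson(depth).
    ``overdispersion`` > 0 switches the totals to negative binomial with that
    dispersion (variance = mean + dispersion * mean^2) for robustness checks.
    """
    if not 0.0 <= true_level <= 1.0:
        raise ValueError(f"true_level must lie in [0, 1], got {true_level}")
    if depth <= 0:
        raise ValueError("depth must be > 0")

    def draw_total() -> int:
        if overdispersion > 0:
            r = 1.0 / overdispersion
            p = r / (r + depth)
            return int(rng.negative_binomial(r, p))
        return int(rng.poisson(depth))

    total = draw_total()
    eluate = int(rng.binomial(total, true_level)) if total > 0 else 0
    supernatant = total - eluate
    inp = draw_total()
    return inp, eluate, supernatant


# ---------------------------------------------------------------------------
# Expression: compartments and population matrix
# ---------------------------------------------------------------------------


def simulate_expression(
    pairs: Sequence[GenePair],
    true_levels: dict[str, float],
    decay_coeff: float,
    ceRNA_coupling: float,
    coupling_attenuation: float,
    n_samples: int,
    rng: np.random.Generator,
    export_factor: float = 3.0,
    expression_sd: float = 0.8,
    noise_sd: float = 0.3,
) -> tuple[dict[str, tuple[float, float]], pd.DataFrame]:
    """Draw compartment abundances and a population expression matrix.

    Nuclear abundance is log-normal around a common baseline.  Cytosolic
    abundance is nuclear x export factor x exp(-decay_coeff x m6A level) x
    log-normal noise, with the decay term applied to processed pseudogenes
    (the class the decay pathway acts on; decay_coeff = 0 is the
    METTL3-knockdown analogue).  The population matrix gives each pair a
    shared latent factor with correlation
    ``ceRNA_coupling x (1 - coupling_attenuation x pseudogene m6A level)``
    on the log scale for processed pairs, and unattenuated coupling for
    unprocessed pairs.
    """
    if decay_coeff < 0:
        raise ValueError("decay_coeff must be >= 0")
    if not (0.0 <= ceRNA_coupling <= 1.0 and 0.0 <= coupling_attenuation <= 1.0):
        raise ValueError("coupling parameters must lie in [0, 1]")
    if n_samples < 3:
        raise ValueError("n_samples < 3: correlation undefined downstream")

    compartment: dict[str, tuple[float, float]] = {}
    gene_mu: dict[str, float] = {}
    for pair in pairs:
        for gid in (pair.pseudogene_id, pair.cognate_id):
            mu = float(rng.normal(np.log(50.0), expression_sd))
            gene_mu[gid] = mu
            nuc = float(np.exp(mu + rng.normal(0.0, noise_sd)))
            decay = 0.0
            if gid == pair.pseudogene_id and pair.klass == "processed":
                decay = decay_coeff * true_levels[gid]
            cyt = float(
                nuc * export_factor * np.exp(-decay) * np.exp(rng.normal(0.0, noise_sd))
            )
            compartment[gid] = (nuc, cyt)

    genes: list[str] = []
    rows: list[np.ndarray] = []
    for pair in pairs:
        rho = ceRNA_coupling
        if pair.klass == "processed":
            rho = ceRNA_coupling * (
                1.0 - coupling_attenuation * true_levels[pair.pseudogene_id]
            )
        rho = float(np.clip(rho, 0.0, 1.0))
        z = rng.normal(0.0, 1.0, size=n_samples)
        for gid in (pair.pseudogene_id, pair.cognate_id):
            eps = rng.normal(0.0, 1.0, size=n_samples)
            x = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            rows.append(np.exp(gene_mu[gid] + 0.5 * x))
            genes.append(gid)
    mat = pd.DataFrame(
        np.vstack(rows), index=genes, columns=[f"s{i:03d}" for i in range(n_samples)]
    )
    return compartment, mat


# ---------------------------------------------------------------------------
# Read simulation (for the assignment stage)
# ---------------------------------------------------------------------------


def simulate_reads(
    sequences: dict[str, str],
    snps: dict[str, list[tuple[int, str, str]]],
    read_length: int,
    reads_per_gene: int,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Draw error-free reads of known origin; SNP positions carry the
    alternate allele with probability 0.5 (a heterozygous donor).

    Returns (read_id, sequence, true_origin) triples.
    """
    reads = []
    for gid, seq in sequences.items():
        if len(seq) < read_length:
            continue
        alt_at = {pos: alt for pos, _ref, alt in snps.get(gid, [])}
        offsets = rng.integers(0, len(seq) - read_length + 1, size=reads_per_gene)
        for j, off in enumerate(offsets):
            window = list(seq[off : off + read_length])
            for pos, alt in alt_at.items():
                if off <= pos < off + read_length and rng.random() < 0.5:
                    window[pos - off] = alt
            reads.append((f"{gid}_r{j}", "".join(window), gid))
    return reads


# ---------------------------------------------------------------------------
# Full cohort assembly
# ---------------------------------------------------------------------------


def _choose_methylated_sites(
    codes: np.ndarray,
    level: float,
    mode: str,
    true_ages: dict[int, int] | None,
    n_strata: int,
    rng: np.random.Generator,
) -> list[int]:
    """Pick which sense DRACH central-A positions are truly methylated.

    ``young_biased`` makes methylation probability fall with the site's true
    stratum age (its conservation across the ortholog ladder), so in-peak
    m6A sites come out younger than the out-of-peak DRACH background.
    ``age_increasing`` is the reverse gradient; ``uniform`` ignores age.
    Genes without ortholog ages (cognates) methylate uniformly.
    """
    positions = np.nonzero(drach_central_a_mask(codes))[0]
    chosen: list[int] = []
    k = max(n_strata, 1)
    for pos in positions:
        if true_ages is None:
            p = level * 0.4
        elif mode == "young_biased":
            age = true_ages.get(int(pos), 0)
            p = level * (0.90 - 0.80 * age / k)
        elif mode == "age_increasing":
            age = true_ages.get(int(pos), 0)
            p = level * (0.15 + 0.75 * age / k)
        else:
            p = level * 0.5
        if rng.random() < p:
            chosen.append(int(pos))
    return chosen


def _merge_windows(centers: list[int], halfwidth: int, length: int) -> list[tuple[int, int]]:
    if not centers:
        return []
    intervals = [(max(0, c - halfwidth), min(length, c + halfwidth + 1)) for c in sorted(centers)]
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Assemble the full synthetic cohort from a validated config."""
    config.validate()
    rng_seq = config.rng("sequences")
    rng_laic = config.rng("laic")
    rng_cov = config.rng("coverage")
    rng_expr = config.rng("expression")
    rng_ortho = config.rng("orthologs")
    rng_snp = config.rng("snps")

    sequences: dict[str, str] = {}
    pairs: list[GenePair] = []
    snps: dict[str, list[tuple[int, str, str]]] = {}
    fraction_counts: dict[str, tuple[int, int, int]] = {}
    coverages: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    orthologs: dict[str, dict[str, str]] = {}
    truth: dict = {
        "config": asdict(config),
        "true_levels": {},
        "divergence": {},
        "methylated_sites": {},
        "true_peaks": {},
        "site_ages": {},
        "ortholog_subs": {},
        "gained_sense": {},
        "gained_antisense": {},
    }
    n_strata = len(config.tree)

    lo, hi = config.seq_length_range
    for i in range(config.n_pairs):
        pid, cid = f"PG{i:04d}", f"CG{i:04d}"
        L = int(rng_seq.integers(lo, hi + 1))
        cognate = decode(rng_seq.integers(0, 4, size=L).astype(np.uint8))
        pair_rate = config.mutation_rate * float(
            rng_seq.uniform(*config.rate_spread)
        )
        pseudo = mutate_with_selection(
            cognate, pair_rate, config.selection_coeff, rng_seq
        )
        klass = "processed" if rng_seq.random() < config.frac_processed else "unprocessed"
        exon_count = 1 if klass == "processed" else int(rng_seq.integers(2, 13))
        sequences[cid] = cognate
        sequences[pid] = pseudo
        pairs.append(GenePair(pid, cid, klass, exon_count))

        p_codes, c_codes = encode(pseudo), encode(cognate)
        divergence = float(np.mean(p_codes != c_codes))
        truth["divergence"][pid] = divergence

        # true m6A levels: pseudogene level increases with divergence (the
        # generative form of the divergence-level correlation), cognate from
        # a low-mean beta
        lvl_p = float(
            np.clip(
                config.level_intercept
                + config.level_slope * divergence
                + rng_seq.normal(0.0, config.level_sd),
                0.0,
                1.0,
            )
        )
        a, b = config.cognate_level_beta
        lvl_c = float(rng_seq.beta(a, b))
        truth["true_levels"][pid] = lvl_p
        truth["true_levels"][cid] = lvl_c

        # SNPs (heterozygous known variants; mismatches there are tolerated
        # by the strict assignment policy)
        for gid, seq in ((pid, pseudo), (cid, cognate)):
            n_snp = int(rng_snp.binomial(len(seq), config.snp_rate))
            pos_list = sorted(
                rng_snp.choice(len(seq), size=n_snp, replace=False).tolist()
            )
            entries = []
            for pos in pos_list:
                ref = seq[pos]
                alt = str(rng_snp.choice([b for b in "ACGT" if b != ref]))
                entries.append((int(pos), ref, alt))
            snps[gid] = entries

        # orthologs of the pseudogene and true site ages
        per_species, subs = evolve_orthologs(
            pseudo, config.tree, config.branch_rates, rng_ortho
        )
        orthologs[pid] = per_species
        truth["ortholog_subs"][pid] = subs
        ortho_masks = {
            sp: drach_central_a_mask(encode(s)) for sp, s in per_species.items()
        }
        ages: dict[int, int] = {}
        mask_focal = drach_central_a_mask(p_codes)
        for pos in np.nonzero(mask_focal)[0]:
            age = 0
            for k, sp in enumerate(config.tree, start=1):
                if ortho_masks[sp][pos]:
                    age = k
            ages[int(pos)] = age
        truth["site_ages"][pid] = {str(k): v for k, v in ages.items()}

        # gained/lost truth relative to the cognate (positional; equal length)
        sense_gain = np.nonzero(
            drach_central_a_mask(p_codes) & ~drach_central_a_mask(c_codes)
        )[0]
        p_rc, c_rc = (3 - p_codes)[::-1], (3 - c_codes)[::-1]
        anti_gain = np.nonzero(
            drach_central_a_mask(p_rc) & ~drach_central_a_mask(c_rc)
        )[0]
        truth["gained_sense"][pid] = sense_gain.tolist()
        truth["gained_antisense"][pid] = anti_gain.tolist()

        # RIP/input coverage with enriched blocks around methylated sites
        for gid, codes_g, lvl in ((pid, p_codes, lvl_p), (cid, c_codes, lvl_c)):
            sites = _choose_methylated_sites(
                codes_g,
                lvl,
                config.site_choice,
                ages if gid == pid else None,
                n_strata,
                rng_cov,
            )
            peaks = _merge_windows(sites, config.peak_halfwidth, len(codes_g))
            lam = np.full(len(codes_g), config.coverage_depth)
            rip_lam = lam.copy()
            for s_, e_ in peaks:
                rip_lam[s_:e_] *= 1.0 + config.rip_enrichment
            rip = rng_cov.poisson(rip_lam).astype(float)
            inp = rng_cov.poisson(lam).astype(float)
            coverages[gid] = (rip, inp)
            truth["methylated_sites"][gid] = sites
            truth["true_peaks"][gid] = peaks

    compartment, population = simulate_expression(
        pairs,
        truth["true_levels"],
        config.decay_coeff,
        config.ceRNA_coupling,
        config.coupling_attenuation,
        config.n_samples,
        rng_expr,
        export_factor=config.export_factor,
        expression_sd=config.expression_sd,
        noise_sd=config.noise_sd,
    )

    # LAIC-seq fraction counts: sequencing depth tracks total abundance, so
    # m6A-driven cytosolic decay shows up as lower input signal
    totals = {g: nuc + cyt for g, (nuc, cyt) in compartment.items()}
    mean_total = float(np.mean(list(totals.values())))
    for gid, lvl in truth["true_levels"].items():
        depth = config.laic_depth * totals[gid] / mean_total
        fraction_counts[gid] = simulate_laic_counts(
            lvl, max(depth, 1e-6), rng_laic, config.overdispersion
        )

    return CohortBundle(
        config=config,
        sequences=sequences,
        pairs=pairs,
        snps=snps,
        fraction_counts=fraction_counts,
        coverages=coverages,
        compartment_expression=compartment,
        population_expression=population,
        orthologs=orthologs,
        truth=truth,
    )
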