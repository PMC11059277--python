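"""Synthetic fixture generator.

Emulates the data structure of the real experiments — inhibitor time-course
count matrices, paired ribo/RNA per-nucleotide coverage, and nucleotide
pileups — with planted, truth-tabled signal so every analysis stage can be
exercised and validated offline. Deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
STOPS = ("TAA", "TAG", "TGA")
ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOPS)  # 61


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    # transcriptome
    n_genes: int = 50
    gene_length_codons: tuple[int, int] = (100, 300)  # inclusive range
    biased_gene_fraction: float = 0.3
    bias_codons: tuple[str, ...] = ("GAA", "GAT", "AAT", "AAA")
    bias_multiplier: float = 3.0
    minus_strand_fraction: float = 0.3
    intron_prob: float = 0.3
    # TDD time course
    k_base: float = 0.1  # /h
    k_tdd: float = 0.2  # /h, active only while translation proceeds
    tdd_gene_fraction: float = 0.3
    stable_gene_fraction: float = 0.1
    times: tuple[float, ...] = (3.0, 5.0)
    n_replicates: int = 3
    lib_size: float = 1e6
    dispersion: float = 0.05  # NB dispersion; 0 -> noiseless expected counts
    # ribo/rna coverage
    pause_codon: str = "GAA"
    pause_intensity: float = 8.0
    pause_footprint_nt: int = 3
    mean_coverage: float = 50.0
    # pileup
    n_sites: int = 5000
    depth: float = 2000.0
    error_rate_control: float = 0.15
    error_rate_treated: float = 0.18
    error_model: str = "per_site"  # or "per_base"
    mut_alt_fraction: float = 0.002
    variant_fraction: float = 0.01
    qual_pass_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise SimConfigError("n_genes must be >= 0")
        lo, hi = self.gene_length_codons
        if lo < 10 or hi < lo:
            raise SimConfigError("gene_length_codons must be (lo, hi) with 10 <= lo <= hi")
        for name in ("biased_gene_fraction", "minus_strand_fraction", "intron_prob",
                     "tdd_gene_fraction", "stable_gene_fraction", "variant_fraction",
                     "qual_pass_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        for name in ("k_base", "k_tdd", "error_rate_control", "error_rate_treated",
                     "dispersion", "mean_coverage", "mut_alt_fraction"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.bias_multiplier < 1:
            raise SimConfigError("bias_multiplier must be >= 1")
        if self.bias_multiplier * len(self.bias_codons) > len(SENSE_CODONS):
            raise SimConfigError("infeasible bias: multiplier forces total codon frequency > 1")
        if self.depth <= 0:
            raise SimConfigError("depth must be > 0")
        if self.pause_intensity < 1:
            raise SimConfigError("pause_intensity must be >= 1")
        if self.error_model not in ("per_site", "per_base"):
            raise SimConfigError("error_model must be 'per_site' or 'per_base'")
        bad = [c for c in self.bias_codons + (self.pause_codon,) if c not in SENSE_CODONS]
        if bad:
            raise SimConfigError(f"not sense codons: {bad}")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]  # genomic, transcription order
    seq: str  # mRNA CDS, 5'->3'

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


@dataclass
class Transcriptome:
    genes: list[SimGene]
    genome: dict[str, str]
    truth: pd.DataFrame  # gene_id, biased, length_codons, strand

    def write(self, fasta_path, gtf_path, truth_path) -> None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(gtf_path, "w") as fh:
            for g in self.genes:
                lo = min(s for s, _ in g.cds_segments)
                hi = max(e for _, e in g.cds_segments)
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write(f"{g.chrom}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                         f'gene_id "{g.gene_id}";\n')
                fh.write(f"{g.chrom}\tsim\ttranscript\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n")
                cum = 0
                for s, e in g.cds_segments:
                    phase = (3 - cum % 3) % 3
                    fh.write(f"{g.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t{attrs}\n")
                    cum += e - s
        self.truth.to_csv(truth_path, sep="\t", index=False)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _codon_probs(cfg: SimConfig, biased: bool) -> np.ndarray:
    n = len(SENSE_CODONS)
    p = np.full(n, 1.0 / n)
    if biased:
        idx = [SENSE_CODONS.index(c) for c in cfg.bias_codons]
        rest = (n - cfg.bias_multiplier * len(idx)) / (n * (n - len(idx)))
        p[:] = rest
        p[idx] = cfg.bias_multiplier / n
    return p


def simulate_transcriptome(cfg: SimConfig) -> Transcriptome:
    """Generate a genome FASTA / GTF pair with planted codon-bias genes.

    Genes start with ATG, end with a stop, contain no internal stop; biased
    genes carry each bias codon at ``bias_multiplier`` times the uniform
    background frequency (in expectation).
    """
    rng = _rng(cfg, 1)
    n_biased = int(round(cfg.biased_gene_fraction * cfg.n_genes))
    biased_flags = np.zeros(cfg.n_genes, dtype=bool)
    biased_flags[:n_biased] = True
    rng.shuffle(biased_flags)

    p_bg = _codon_probs(cfg, False)
    p_bias = _codon_probs(cfg, True)
    sense = np.array(SENSE_CODONS)

    genes: list[SimGene] = []
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    rows = []

    def _gap(n: int) -> None:
        nonlocal cursor
        pieces.append("".join(rng.choice(list(BASES), size=n)))
        cursor += n

    _gap(100)
    lo, hi = cfg.gene_length_codons
    for i in range(cfg.n_genes):
        gid = f"g{i + 1:04d}"
        n_codons = int(rng.integers(lo, hi + 1))
        body = sense[rng.choice(len(sense), size=n_codons - 2, p=p_bias if biased_flags[i] else p_bg)]
        stop = STOPS[int(rng.integers(0, 3))]
        seq = "ATG" + "".join(body) + stop
        L = len(seq)
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        if rng.random() < cfg.intron_prob and L >= 60:
            split = int(rng.integers(30, L - 30))
            intron = "".join(rng.choice(list(BASES), size=20))
            if strand == "+":
                segs = ((cursor, cursor + split), (cursor + split + 20, cursor + L + 20))
                pieces.append(seq[:split] + intron + seq[split:])
            else:
                # genome left->right: revcomp(tail) | intron | revcomp(head)
                tail_len = L - split
                segs = (
                    (cursor + tail_len + 20, cursor + L + 20),  # head, transcribed first
                    (cursor, cursor + tail_len),
                )
                pieces.append(_revcomp(seq[split:]) + intron + _revcomp(seq[:split]))
            cursor += L + 20
        else:
            segs = ((cursor, cursor + L),)
            pieces.append(seq if strand == "+" else _revcomp(seq))
            cursor += L
        genes.append(SimGene(gid, chrom, strand, segs, seq))
        rows.append({"gene_id": gid, "biased": bool(biased_flags[i]),
                     "length_codons": L // 3, "strand": strand})
        _gap(60)

    genome = {chrom: "".join(pieces)} if cfg.n_genes > 0 else {}
    truth = pd.DataFrame(rows, columns=["gene_id", "biased", "length_codons", "strand"])
    return Transcriptome(genes, genome, truth)


# ---------------------------------------------------------------------------
# TDD time-course counts
# ---------------------------------------------------------------------------

def make_design(cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet: condition x {t0, (Tci|Tci+Tli) x times} x replicates."""
    rows = []
    for cond in ("CTRL", "TRT"):
        for rep in range(1, cfg.n_replicates + 1):
            rows.append((f"{cond}_t0_r{rep}", cond, "none", 0.0, rep))
            for t in cfg.times:
                tt = f"{t:g}"
                rows.append((f"{cond}_Tci_t{tt}_r{rep}", cond, "Tci", t, rep))
                rows.append((f"{cond}_TciTli_t{tt}_r{rep}", cond, "TciTli", t, rep))
    return pd.DataFrame(rows, columns=["sample", "condition", "regime", "time_h", "replicate"])


@dataclass
class TddSim:
    counts: pd.DataFrame  # genes x samples (raw counts)
    samples: pd.DataFrame
    truth: pd.DataFrame  # gene_id, class, k_base, k_tdd_ctrl, k_tdd_trt, a0


def simulate_tdd_counts(
    cfg: SimConfig,
    gene_ids: Sequence[str],
    design: pd.DataFrame | None = None,
) -> TddSim:
    """Counts under exponential decay A(t) = A0 exp(-(k_base + k_tdd·[translating])·t).

    TDD genes have k_tdd active only in the treated condition and only while
    translation proceeds (regimes without the translation inhibitor). Stable
    spike genes decay not at all; sequencing depth is held constant so their
    relative abundance (CPM) rises as bulk mRNA decays. NB noise with
    ``cfg.dispersion`` (0 means noiseless expected counts, returned as floats).
    """
    if design is None:
        design = make_design(cfg)
    if not (design["time_h"] == 0).any():
        raise SimConfigError("design lacks t=0 samples; TDD index undefined without R0")
    rng = _rng(cfg, 2)
    n = len(gene_ids)
    classes = np.array(["constitutive"] * n, dtype=object)
    n_stable = int(round(cfg.stable_gene_fraction * n))
    n_tdd = int(round(cfg.tdd_gene_fraction * n))
    order = rng.permutation(n)
    classes[order[:n_stable]] = "stable"
    classes[order[n_stable : n_stable + n_tdd]] = "tdd"

    a0 = rng.lognormal(mean=3.0, sigma=1.0, size=n)
    k_base = np.where(classes == "stable", 0.0, cfg.k_base)
    k_tdd_ctrl = np.zeros(n)
    k_tdd_trt = np.where(classes == "tdd", cfg.k_tdd, 0.0)

    counts = {}
    for row in design.itertuples(index=False):
        translating = row.regime in ("none", "Tci")
        k_tdd_cond = k_tdd_trt if row.condition == "TRT" else k_tdd_ctrl
        k_eff = k_base + (k_tdd_cond if translating else 0.0)
        abundance = a0 * np.exp(-k_eff * row.time_h)
        mean = cfg.lib_size * abundance / abundance.sum()
        if cfg.dispersion > 0:
            r = 1.0 / cfg.dispersion
            counts[row.sample] = rng.negative_binomial(r, r / (r + mean))
        else:
            counts[row.sample] = mean
    counts_df = pd.DataFrame(counts, index=list(gene_ids))
    counts_df.index.name = "gene_id"
    truth = pd.DataFrame({
        "gene_id": list(gene_ids), "class": classes, "a0": a0,
        "k_base": k_base, "k_tdd_ctrl": k_tdd_ctrl, "k_tdd_trt": k_tdd_trt,
    })
    return TddSim(counts_df, design.copy(), truth)


def expected_tdd_index(k_base: float, k_tdd: float, t: float) -> float:
    """Closed-form index for noiseless exponential decay."""
    return float(np.exp(-k_base * t) - np.exp(-(k_base + k_tdd) * t))


# ---------------------------------------------------------------------------
# ribo / rna coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageSim:
    test: dict[str, "object"]  # gene_id -> CoverageBundle (TRT)
    ctrl: dict[str, "object"]  # gene_id -> CoverageBundle (CTRL)
    truth: pd.DataFrame  # gene_id, codon_ordinal, start_nt, end_nt


def simulate_ribo_rna_coverage(cfg: SimConfig, genes: Sequence[SimGene],
                               n_pause_genes: int | None = None) -> CoverageSim:
    """Flat Poisson RNA coverage; ribo coverage proportional except at one
    planted pause codon per pause gene, multiplied by ``pause_intensity``
    in the treated condition."""
    import warnings as _warnings

    from ribopause.peaks import CoverageBundle

    rng = _rng(cfg, 3)
    eligible = []
    for g in genes:
        hits = [k for k, c in enumerate(g.codons[1:-1], start=1) if c == cfg.pause_codon]
        if hits:
            eligible.append((g.gene_id, hits))
        else:
            _warnings.warn(f"{g.gene_id}: pause codon {cfg.pause_codon} absent; skipped in truth")
    if n_pause_genes is not None:
        eligible = eligible[:n_pause_genes]
    pause_at = {gid: hits[int(rng.integers(0, len(hits)))] for gid, hits in eligible}

    half_extra = max(0, (cfg.pause_footprint_nt - 3) // 2)
    test, ctrl, rows = {}, {}, []
    for g in genes:
        L = len(g.seq)
        rate = np.full(L, cfg.mean_coverage)
        trt_rate = rate.copy()
        if g.gene_id in pause_at:
            k = pause_at[g.gene_id]
            s = max(0, 3 * k - half_extra)
            e = min(L, 3 * k + 3 + half_extra)
            trt_rate[s:e] *= cfg.pause_intensity
            rows.append({"gene_id": g.gene_id, "codon_ordinal": k, "start_nt": s, "end_nt": e})
        shape = (cfg.n_replicates, L)
        ctrl[g.gene_id] = CoverageBundle(
            g.gene_id,
            ribo=rng.poisson(rate, size=shape).astype(float),
            rna=rng.poisson(rate, size=shape).astype(float),
        )
        test[g.gene_id] = CoverageBundle(
            g.gene_id,
            ribo=rng.poisson(trt_rate, size=shape).astype(float),
            rna=rng.poisson(rate, size=shape).astype(float),
        )
    truth = pd.DataFrame(rows, columns=["gene_id", "codon_ordinal", "start_nt", "end_nt"])
    return CoverageSim(test, ctrl, truth)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

@dataclass
class PileupSim:
    tables: dict[str, pd.DataFrame]  # condition -> pileup table
    truth: pd.DataFrame  # site_id, ref, is_variant, mutated_CTRL, mutated_TRT


def simulate_pileup(cfg: SimConfig, genes: Sequence[SimGene] | None = None) -> PileupSim:
    """Per-condition pileups: REF from gene sequence (or random), low-frequency
    transcriptional errors at condition-specific rates, planted ~50%-fraction
    genomic variants, and a QUAL column.

    ``error_model='per_site'``: each non-variant site independently carries a
    transcriptional mutation with probability ``error_rate_<condition>``; a
    mutated site gets 1 + Binomial(depth-1, mut_alt_fraction) reads of one
    random non-REF base, so the per-site SNP probability equals the planted
    rate exactly. ``'per_base'``: every read independently miscalls with the
    given rate, spread uniformly over the three non-REF bases.
    """
    rng = _rng(cfg, 4)
    n = cfg.n_sites
    if genes:
        pool = "".join(g.seq for g in genes)
        refs = np.array(list(pool))[rng.integers(0, len(pool), size=n)]
    else:
        refs = np.array(list(BASES))[rng.integers(0, 4, size=n)]
    site_ids = np.array([f"s{i + 1:06d}" for i in range(n)])
    is_variant = rng.random(n) < cfg.variant_fraction
    variant_alt_choice = rng.integers(0, 3, size=n)
    qual = np.where(rng.random(n) < cfg.qual_pass_fraction, 30.0, 5.0)

    base_idx = {b: i for i, b in enumerate(BASES)}
    nonref = {b: [x for x in BASES if x != b] for b in BASES}

    tables: dict[str, pd.DataFrame] = {}
    mutated_flags: dict[str, np.ndarray] = {}
    for cond, err in (("CTRL", cfg.error_rate_control), ("TRT", cfg.error_rate_treated)):
        depth = np.maximum(1, rng.poisson(cfg.depth, size=n))
        counts = np.zeros((n, 4), dtype=np.int64)
        mutated = np.zeros(n, dtype=bool)
        if cfg.error_model == "per_site":
            mutated = (~is_variant) & (rng.random(n) < err)
            alt_n = np.where(mutated, 1 + rng.binomial(np.maximum(depth - 1, 0),
                                                       cfg.mut_alt_fraction), 0)
            which = rng.integers(0, 3, size=n)
            for i in np.flatnonzero(mutated):
                alt = nonref[refs[i]][which[i]]
                counts[i, base_idx[alt]] = min(alt_n[i], depth[i])
        else:  # per_base
            err_total = rng.binomial(depth, min(err, 1.0))
            for i in range(n):
                if err_total[i] == 0:
                    continue
                parts = rng.multinomial(err_total[i], [1 / 3] * 3)
                for j, alt in enumerate(nonref[refs[i]]):
                    counts[i, base_idx[alt]] = parts[j]
                mutated[i] = True
        # genomic variants override: alt fraction ~ 0.5, same alt in both conditions
        for i in np.flatnonzero(is_variant):
            alt = nonref[refs[i]][variant_alt_choice[i]]
            counts[i, :] = 0
            counts[i, base_idx[alt]] = rng.binomial(depth[i], 0.5)
        alt_total = counts.sum(axis=1)
        over = alt_total > depth
        if over.any():  # clamp pathological draws
            for i in np.flatnonzero(over):
                counts[i] = (counts[i] * depth[i]) // max(alt_total[i], 1)
            alt_total = counts.sum(axis=1)
        ref_col = np.array([base_idx[b] for b in refs])
        counts[np.arange(n), ref_col] += depth - alt_total
        tables[cond] = pd.DataFrame({
            "site_id": site_ids, "ref": refs, "depth": depth,
            "A": counts[:, 0], "C": counts[:, 1], "G": counts[:, 2], "T": counts[:, 3],
            "qual": qual,
        })
        mutated_flags[cond] = mutated
    truth = pd.DataFrame({
        "site_id": site_ids, "ref": refs, "is_variant": is_variant,
        "mutated_CTRL": mutated_flags["CTRL"], "mutated_TRT": mutated_flags["TRT"],
    })
    return PileupSim(tables, truth)
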