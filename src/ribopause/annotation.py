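"""Gene-model curation: parse GTF/GFF3 + genome FASTA into filtered,
frame-validated, one-mRNA-per-gene concatenated CDS models.

Every downstream stage (peak calling, compositional statistics, window
profiles) works in concatenated-CDS nucleotide coordinates, so the models
built here are the coordinate backbone of the whole pipeline.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

START_CODONS = {"ATG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One gene, one mRNA: strand-resolved concatenation of its CDS."""

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, transcription order
    cds_seq: str

    @property
    def length_nt(self) -> int:
        return len(self.cds_seq)

    @property
    def codons(self) -> list[str]:
        return [self.cds_seq[i : i + 3] for i in range(0, len(self.cds_seq), 3)]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        seg_len = sum(e - s for s, e in self.cds_segments)
        if seg_len != len(self.cds_seq):
            raise AnnotationError(f"{self.gene_id}: segment/sequence length mismatch")


@dataclass
class FilterReport:
    """Per-rule drop counts produced by :func:`load_gene_models`."""

    n_input: int = 0
    n_retained: int = 0
    dropped: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "dropped": dict(self.dropped),
        }


@dataclass(frozen=True)
class CodonIndex:
    """Nucleotide-position -> codon mapping with segment-boundary flags."""

    codon_of_position: np.ndarray  # (L,), int
    codons: tuple[str, ...]
    amino_acids: tuple[str, ...]
    boundary: np.ndarray  # (n_codons,), bool: codon spans two CDS segments


def _validate_lines(annotation_file: str | Path) -> None:
    with open(annotation_file) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 8:
                raise AnnotationError(
                    f"{annotation_file}: malformed record at line {i}: {line.strip()!r}")


def _open_db(annotation_file: str | Path) -> gffutils.FeatureDB:
    _validate_lines(annotation_file)
    try:
        return gffutils.create_db(
            str(annotation_file),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted exceptions on bad lines
        raise AnnotationError(f"failed to parse {annotation_file}: {exc}") from exc


def _feature_ids(db: gffutils.FeatureDB, feat: gffutils.Feature) -> tuple[str | None, str | None]:
    """(gene_id, transcript_id) for a CDS feature, GTF or GFF3 dialect."""
    gid = feat.attributes.get("gene_id", [None])[0]
    tid = feat.attributes.get("transcript_id", [None])[0]
    if tid is None:
        parents = feat.attributes.get("Parent", [])
        tid = parents[0] if parents else None
    if gid is None and tid is not None:
        try:
            tx = db[tid]
        except gffutils.FeatureNotFoundError:
            tx = None
        if tx is not None:
            gid = tx.attributes.get("gene_id", [None])[0]
            if gid is None:
                parents = tx.attributes.get("Parent", [])
                gid = parents[0] if parents else None
    return gid, tid


def _transcription_order(segments: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    return sorted(segments, key=lambda s: s[0], reverse=(strand == "-"))


def _extract_seq(genome: Mapping[str, str], chrom: str, strand: str,
                 segments: Sequence[tuple[int, int]]) -> str:
    parts = []
    for s, e in segments:
        raw = genome[chrom][s:e]
        parts.append(str(Seq(raw).reverse_complement()) if strand == "-" else raw)
    return "".join(parts).upper()


def _structural_check(seq: str) -> str | None:
    """Return a drop-reason code, or None if the concatenated CDS is valid."""
    if len(seq) % 3 != 0:
        return "ambiguous_frame"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if not codons or codons[0] not in START_CODONS:
        return "no_start"
    if codons[-1] not in STOP_CODONS:
        return "no_stop"
    if any(c in STOP_CODONS for c in codons[:-1]):
        return "internal_stop"
    return None


def _union_segments(segment_sets: Iterable[Sequence[tuple[int, int]]]) -> list[tuple[int, int]]:
    ivs = sorted({iv for segs in segment_sets for iv in segs})
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def load_gene_models(
    annotation_file: str | Path,
    genome_fasta: str | Path,
    drop_merged: bool = True,
) -> tuple[list[GeneModel], FilterReport]:
    """Load gene models, applying structural filters.

    Retains only genes with at least one CDS whose one-mRNA concatenation
    starts with ATG, ends with a stop codon, has an unambiguous frame
    (length divisible by 3) and no internal stop. Genes whose CDS footprint
    overlaps another gene's CDS on the same strand are treated as merged and
    both are dropped (``drop_merged=False`` disables this). Multi-transcript
    genes use the union-of-CDS concatenation when it is frame-consistent,
    otherwise the longest frame-consistent transcript.

    Returns the retained models and a :class:`FilterReport` of drop counts.
    """
    db = _open_db(annotation_file)
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}

    # group CDS segments by gene -> transcript
    per_gene: dict[str, dict[str, list[tuple[int, int]]]] = defaultdict(lambda: defaultdict(list))
    meta: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    for feat in db.features_of_type("CDS"):
        gid, tid = _feature_ids(db, feat)
        if gid is None:
            raise AnnotationError(
                f"CDS without resolvable gene id at {feat.seqid}:{feat.start}-{feat.end}"
            )
        tid = tid or f"{gid}.t"
        per_gene[gid][tid].append((feat.start - 1, feat.end))  # GTF/GFF 1-based closed -> 0-based half-open
        meta[gid] = (feat.seqid, feat.strand)

    report = FilterReport()
    gene_features = {f.id for f in db.features_of_type("gene")}
    report.n_input = len(gene_features | set(per_gene))
    for gid in gene_features - set(per_gene):
        report.dropped["no_cds"] += 1

    # merged-gene filter on raw CDS footprints (same chrom and strand)
    merged_drop: set[str] = set()
    if drop_merged:
        by_loc: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
        for gid, txs in per_gene.items():
            chrom, strand = meta[gid]
            lo = min(s for segs in txs.values() for s, _ in segs)
            hi = max(e for segs in txs.values() for _, e in segs)
            by_loc[(chrom, strand)].append((lo, hi, gid))
        for spans in by_loc.values():
            spans.sort()
            for (lo1, hi1, g1), (lo2, hi2, g2) in zip(spans, spans[1:]):
                if lo2 < hi1:  # footprint overlap
                    merged_drop.update((g1, g2))

    models: list[GeneModel] = []
    for gid in sorted(per_gene):
        if gid in merged_drop:
            report.dropped["merged_gene"] += 1
            continue
        chrom, strand = meta[gid]
        if chrom not in genome:
            warnings.warn(f"{gid}: chromosome {chrom} absent from FASTA; gene dropped")
            report.dropped["unknown_sequence"] += 1
            continue
        txs = per_gene[gid]
        if any(e > len(genome[chrom]) for segs in txs.values() for _, e in segs):
            warnings.warn(f"{gid}: CDS extends past end of {chrom}; gene dropped")
            report.dropped["out_of_bounds"] += 1
            continue

        # candidate concatenations: union of CDS first, then transcripts by length
        candidates: list[list[tuple[int, int]]] = []
        if len(txs) > 1:
            candidates.append(_union_segments(txs.values()))
        for segs in sorted(txs.values(), key=lambda s: -sum(e - b for b, e in s)):
            candidates.append(sorted(set(segs)))

        chosen = None
        reason = None
        for segs in candidates:
            ordered = _transcription_order(segs, strand)
            seq = _extract_seq(genome, chrom, strand, ordered)
            reason = _structural_check(seq)
            if reason is None:
                chosen = (tuple(ordered), seq)
                break
        if chosen is None:
            report.dropped[reason or "invalid"] += 1
            continue
        models.append(GeneModel(gid, chrom, strand, chosen[0], chosen[1]))

    report.n_retained = len(models)
    return models, report


def codon_index(gene: GeneModel) -> CodonIndex:
    """Map each CDS nucleotide to its codon ordinal and flag codons that
    span a CDS-segment junction (window analyses can exclude those)."""
    L = gene.length_nt
    if L % 3 != 0:
        raise AnnotationError(f"{gene.gene_id}: CDS length {L} not divisible by 3")
    pos_codon = np.arange(L) // 3
    seg_lengths = [e - s for s, e in gene.cds_segments]
    seg_of_pos = np.repeat(np.arange(len(seg_lengths)), seg_lengths)
    n_codons = L // 3
    seg_mat = seg_of_pos.reshape(n_codons, 3)
    boundary = seg_mat.min(axis=1) != seg_mat.max(axis=1)
    codons = tuple(gene.codons)
    aas = tuple(str(Seq(c).translate()) for c in codons)
    return CodonIndex(pos_codon, codons, aas, boundary)


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write retained models back out as GFF3 (gene/mRNA/CDS records)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            lo = min(s for s, _ in g.cds_segments)
            hi = max(e for _, e in g.cds_segments)
            fh.write(
                f"{g.chrom}\tribopause\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tribopause\tmRNA\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id};gene_id={g.gene_id};transcript_id={tid}\n"
            )
            cum = 0
            for s, e in g.cds_segments:  # transcription order
                phase = (3 - cum % 3) % 3
                fh.write(
                    f"{g.chrom}\tribopause\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={tid}.cds;Parent={tid};gene_id={g.gene_id};transcript_id={tid}\n"
                )
                cum += e - s


def write_cds_fasta(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.cds_seq), 60):
                fh.write(g.cds_seq[i : i + 60] + "\n")
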