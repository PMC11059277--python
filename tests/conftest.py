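"""Shared fixtures: hand-built toy annotations and small simulation configs."""

from __future__ import annotations

from pathlib import Path

import pytest

from ribopause.synthetic import SimConfig


def write_fasta(path: Path, seqs: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_gtf(path: Path, genes: list[dict]) -> Path:
    """genes: dicts with gene_id, chrom, strand, segments [(start, end), ...]
    (0-based half-open, transcription order)."""
    with open(path, "w") as fh:
        for g in genes:
            segs = g["segments"]
            lo = min(s for s, _ in segs)
            hi = max(e for _, e in segs)
            attrs = f'gene_id "{g["gene_id"]}"; transcript_id "{g["gene_id"]}.t1";'
            fh.write(f'{g["chrom"]}\ttest\tgene\t{lo + 1}\t{hi}\t.\t{g["strand"]}\t.\t'
                     f'gene_id "{g["gene_id"]}";\n')
            fh.write(f'{g["chrom"]}\ttest\ttranscript\t{lo + 1}\t{hi}\t.\t{g["strand"]}\t.\t{attrs}\n')
            for s, e in segs:
                fh.write(f'{g["chrom"]}\ttest\tCDS\t{s + 1}\t{e}\t.\t{g["strand"]}\t0\t{attrs}\n')
    return path


@pytest.fixture
def toy_annotation(tmp_path):
    """Factory: (genome dict, genes list) -> (gtf_path, fasta_path)."""
    def _make(genome: dict[str, str], genes: list[dict]):
        fa = write_fasta(tmp_path / "genome.fa", genome)
        gtf = write_gtf(tmp_path / "toy.gtf", genes)
        return gtf, fa
    return _make


@pytest.fixture
def small_cfg():
    return SimConfig(n_genes=20, gene_length_codons=(60, 120), seed=11)
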