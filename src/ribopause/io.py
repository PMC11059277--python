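"""Small text-format helpers: bedGraph coverage tracks (in concatenated-CDS
coordinates, one 'chromosome' per gene), count matrices and BED6 peaks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_bedgraph(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encoded bedGraph; keys are gene ids (CDS coordinates)."""
    with open(path, "w") as fh:
        for gid in sorted(tracks):
            v = np.asarray(tracks[gid], dtype=float)
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                fh.write(f"{gid}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(path: str | Path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph back to dense per-nt vectors of the given lengths."""
    out = {gid: np.zeros(L, dtype=float) for gid, L in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            gid, s, e, v = line.rstrip("\n").split("\t")
            if gid in out:
                out[gid][int(s):int(e)] = float(v)
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_peaks_bed(peaks, path: str | Path) -> None:
    """BED6: name=gene:direction, score=score_mean (kept peaks only)."""
    with open(path, "w") as fh:
        for p in peaks:
            if not p.kept:
                continue
            score = 0.0 if not np.isfinite(p.score_mean) else p.score_mean
            fh.write(f"{p.gene_id}\t{p.start}\t{p.end}\t{p.gene_id}:{p.direction}\t"
                     f"{score:.3f}\t+\n")


def peaks_to_frame(peaks) -> pd.DataFrame:
    rows = []
    for p in peaks:
        rows.append({
            "gene_id": p.gene_id, "start": p.start, "end": p.end,
            "direction": p.direction, "mean_cmean": p.mean_cmean,
            "score_mean": p.score_mean,
            "score_reps": ",".join(f"{s:.4g}" for s in p.score_reps),
            "rna_mean_coverage": p.rna_mean_coverage,
            "kept": p.kept, "reasons": ";".join(p.reasons),
        })
    cols = ["gene_id", "start", "end", "direction", "mean_cmean", "score_mean",
            "score_reps", "rna_mean_coverage", "kept", "reasons"]
    return pd.DataFrame(rows, columns=cols)
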