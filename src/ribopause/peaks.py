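"""Differential ribosome-density peak calling.

Per gene: cNorm = ribo/rna coverage per replicate (positions with zero RNA
coverage masked), cDiff = test - control per replicate, cMean = replicate
mean, threshold T = MeanCov + 3*StdMean over defined positions (population
SD). Peaks are maximal runs with cMean strictly above T, scored as
(sum/( (e-s)*T ) - 1)*100, and kept when the region's mean RNA coverage is
>= 3 and the per-replicate score exceeds 3 in at least two replicates. The
procedure is run in both directions (test>control = TC, control>test = CC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PeakError(ValueError):
    pass


@dataclass
class CoverageBundle:
    """Per-gene coverage for one condition: (n_replicates, L) arrays."""

    gene_id: str
    ribo: np.ndarray
    rna: np.ndarray

    def __post_init__(self) -> None:
        self.ribo = np.asarray(self.ribo, dtype=float)
        self.rna = np.asarray(self.rna, dtype=float)
        if self.ribo.ndim == 1:
            self.ribo = self.ribo[None, :]
        if self.rna.ndim == 1:
            self.rna = self.rna[None, :]
        if self.ribo.shape != self.rna.shape:
            raise PeakError(f"{self.gene_id}: ribo/rna shape mismatch")
        if (self.ribo < 0).any() or (self.rna < 0).any():
            raise PeakError(f"{self.gene_id}: negative coverage")

    @property
    def n_replicates(self) -> int:
        return self.ribo.shape[0]

    @property
    def length(self) -> int:
        return self.ribo.shape[1]


@dataclass
class DiffTrack:
    gene_id: str
    cdiff: np.ndarray  # (n_reps, L); NaN at masked positions
    cmean: np.ndarray  # (L,); NaN at masked positions
    meancov: float
    stdmean: float
    threshold: float
    n_defined: int


@dataclass
class Peak:
    gene_id: str
    start: int
    end: int  # half-open over CDS nt
    direction: str  # "TC" or "CC"
    mean_cmean: float
    score_mean: float
    score_reps: tuple[float, ...]
    rna_mean_coverage: float
    kept: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_coverage(bundle: CoverageBundle) -> np.ndarray:
    """cNorm = ribo / rna per replicate; NaN where rna == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        cnorm = np.where(bundle.rna > 0, bundle.ribo / np.where(bundle.rna > 0, bundle.rna, 1.0), np.nan)
    return cnorm


def diff_track(test: CoverageBundle, ctrl: CoverageBundle) -> DiffTrack:
    """Replicate-wise cNorm difference and its mean track with threshold.

    A position is defined only when RNA coverage is nonzero in every
    replicate of both conditions; masked positions stay NaN throughout.
    """
    if test.length != ctrl.length:
        raise PeakError(f"{test.gene_id}: test/ctrl length mismatch")
    if test.n_replicates != ctrl.n_replicates:
        raise PeakError(f"{test.gene_id}: unequal replicate counts (pass a pairing)")
    cn_t = normalize_coverage(test)
    cn_c = normalize_coverage(ctrl)
    cdiff = cn_t - cn_c
    mask = np.isnan(cdiff).any(axis=0)
    cdiff[:, mask] = np.nan
    cmean = cdiff.mean(axis=0)
    defined = ~mask
    n_def = int(defined.sum())
    if n_def == 0:
        return DiffTrack(test.gene_id, cdiff, cmean, np.nan, np.nan, np.nan, 0)
    vals = cmean[defined]
    meancov = float(vals.mean())
    stdmean = float(np.sqrt(((vals - meancov) ** 2).mean()))  # population SD
    return DiffTrack(test.gene_id, cdiff, cmean, meancov, stdmean,
                     meancov + 3.0 * stdmean, n_def)


def call_peaks(track: DiffTrack) -> list[tuple[int, int]]:
    """Maximal runs of defined positions with cMean strictly above threshold."""
    if track.n_defined == 0 or not np.isfinite(track.threshold):
        return []
    above = np.zeros(len(track.cmean), dtype=bool)
    defined = ~np.isnan(track.cmean)
    above[defined] = track.cmean[defined] > track.threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def peak_score(values: np.ndarray, threshold: float) -> float:
    """(sum(values) / (len * T) - 1) * 100; undefined (NaN) when T <= 0."""
    if len(values) == 0:
        raise PeakError("empty peak region")
    if not np.isfinite(threshold) or threshold <= 0:
        return float("nan")
    return (float(np.sum(values)) / (len(values) * threshold) - 1.0) * 100.0


def _keep_rule(score_reps: tuple[float, ...], rna_mean: float,
               min_rna: float = 3.0, min_score: float = 3.0,
               min_reps: int = 2) -> tuple[bool, tuple[str, ...]]:
    reasons = []
    if not (rna_mean >= min_rna):
        reasons.append("low_rna_coverage")
    finite = [s for s in score_reps if np.isfinite(s)]
    if not finite:  # T <= 0: score undefined, keep on the coverage rule alone
        reasons_t = tuple(reasons + ["score_undefined"])
        return (len(reasons) == 0, reasons_t)
    if sum(s > min_score for s in finite) < min_reps:
        reasons.append("score_rule")
    return (len(reasons) == 0, tuple(reasons))


def score_and_filter(
    raw_peaks: list[tuple[int, int]],
    track: DiffTrack,
    rna_tracks: np.ndarray,
    direction: str = "TC",
    min_rna: float = 3.0,
    min_score: float = 3.0,
    min_replicates_above: int = 2,
) -> list[Peak]:
    """Score peaks on cMean (report) and per-replicate cDiff (filter).

    ``rna_tracks``: (n_tracks, L) raw RNA coverage from all replicates of
    both conditions; a peak's RNA coverage is the mean over tracks and
    positions of its region.
    """
    rna_tracks = np.atleast_2d(np.asarray(rna_tracks, dtype=float))
    out = []
    for s, e in raw_peaks:
        if e <= s:
            raise PeakError(f"{track.gene_id}: empty peak [{s}, {e})")
        region = track.cmean[s:e]
        score_m = peak_score(region, track.threshold)
        score_reps = tuple(peak_score(track.cdiff[i, s:e], track.threshold)
                           for i in range(track.cdiff.shape[0]))
        rna_mean = float(rna_tracks[:, s:e].mean())
        kept, reasons = _keep_rule(score_reps, rna_mean, min_rna, min_score,
                                   min_replicates_above)
        out.append(Peak(track.gene_id, int(s), int(e), direction,
                        float(np.nanmean(region)), score_m, score_reps,
                        rna_mean, kept, reasons))
    return out


def call_gene_peaks(test: CoverageBundle, ctrl: CoverageBundle,
                    direction: str = "TC", **filter_kw) -> tuple[DiffTrack, list[Peak]]:
    track = diff_track(test, ctrl)
    raw = call_peaks(track)
    rna_tracks = np.vstack([test.rna, ctrl.rna])
    return track, score_and_filter(raw, track, rna_tracks, direction=direction, **filter_kw)


def bidirectional_call(test: CoverageBundle, ctrl: CoverageBundle,
                       **filter_kw) -> dict[str, list[Peak]]:
    """Run the caller in both directions: TC (test > control) and CC."""
    _, tc = call_gene_peaks(test, ctrl, direction="TC", **filter_kw)
    _, cc = call_gene_peaks(ctrl, test, direction="CC", **filter_kw)
    return {"TC": tc, "CC": cc}
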