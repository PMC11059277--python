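"""Codon / amino-acid compositional statistics.

Matched-control randomization tests on peak regions, zero-inflated beta
regression contrasts between gene sets, relative frequencies, codon window
profiles around peaks, and protein hydropathy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess1

BASES = "ACGT"
CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))  # 64, lexicographic
CODON_ID = {c: i for i, c in enumerate(CODONS)}
AA_OF_CODON = tuple(str(Seq(c).translate()) for c in CODONS)
AMINO_ACIDS = tuple(sorted(set(AA_OF_CODON)))  # 20 aa + '*'
AA_ID = {a: i for i, a in enumerate(AMINO_ACIDS)}
CODON_TO_AA_ID = np.array([AA_ID[a] for a in AA_OF_CODON])


class CompositionError(ValueError):
    pass


def encode_codons(codons: list[str] | tuple[str, ...]) -> np.ndarray:
    return np.array([CODON_ID[c] for c in codons], dtype=np.int32)


def _features(family: str) -> tuple[str, ...]:
    if family == "codon":
        return CODONS
    if family == "amino_acid":
        return AMINO_ACIDS
    raise CompositionError("family must be 'codon' or 'amino_acid'")


def _feature_ids(codon_ids: np.ndarray, family: str) -> np.ndarray:
    return codon_ids if family == "codon" else CODON_TO_AA_ID[codon_ids]


def peak_to_codon_range(start_nt: int, end_nt: int) -> tuple[int, int]:
    """Codon ordinals overlapped by a half-open nt interval (any overlap counts)."""
    if end_nt <= start_nt:
        raise CompositionError(f"empty peak [{start_nt}, {end_nt})")
    return start_nt // 3, (end_nt - 1) // 3 + 1


def feature_frequencies(
    units: dict[str, np.ndarray],
    family: str = "codon",
) -> pd.DataFrame:
    """Tidy table of per-unit feature frequencies.

    ``units`` maps unit id -> encoded codon-id array (gene CDS, or the codons
    a peak overlaps). Absent features get frequency 0.
    """
    feats = _features(family)
    rows = []
    for uid, codon_ids in units.items():
        fids = _feature_ids(np.asarray(codon_ids), family)
        n = len(fids)
        if n == 0:
            raise CompositionError(f"unit {uid} maps to zero codons")
        counts = np.bincount(fids, minlength=len(feats))
        for f, c in zip(feats, counts):
            rows.append((uid, f, int(c), n, c / n))
    return pd.DataFrame(rows, columns=["unit_id", "feature", "count", "n_codons", "freq"])


# ---------------------------------------------------------------------------
# matched-control randomization test
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    table: pd.DataFrame
    n_control_sets_drawn: int


def _prefix_counts(codon_ids: np.ndarray, family: str, n_feats: int) -> np.ndarray:
    fids = _feature_ids(codon_ids, family)
    onehot = np.zeros((len(fids) + 1, n_feats), dtype=np.int32)
    onehot[np.arange(1, len(fids) + 1), fids] = 1
    return np.cumsum(onehot, axis=0)


def peak_randomization_test(
    peaks: list[tuple[str, int, int]],
    gene_codons: dict[str, np.ndarray],
    family: str = "codon",
    n_controls: int = 10_000,
    seed: int = 0,
    control_pool: dict[str, np.ndarray] | None = None,
) -> RandomizationResult:
    """Empirical compositional test of observed peaks against matched controls.

    ``peaks`` are (gene_id, start_nt, end_nt) over concatenated CDS;
    ``gene_codons`` maps expressed-gene ids to encoded codon arrays. Each of
    ``n_controls`` control sets has the same number of peaks with identical
    per-peak codon lengths, placed uniformly over eligible codon start
    positions (genes weighted by their number of eligible positions). The
    statistic is the mean per-peak feature frequency; p = min(k, l) /
    n_controls where k (l) counts control means >= (<=) the observed mean,
    ties in both; floored at 1/n_controls; BH-adjusted across features.

    ``control_pool`` restricts where control peaks may be placed; it defaults
    to the expressed annotation ``gene_codons`` itself.
    """
    if not peaks:
        raise CompositionError("no peaks supplied")
    feats = _features(family)
    nf = len(feats)
    rng = np.random.default_rng(seed)

    pool = gene_codons if control_pool is None else control_pool
    gids = sorted(pool)
    lengths = np.array([len(pool[g]) for g in gids])
    prefixes = [_prefix_counts(np.asarray(pool[g]), family, nf) for g in gids]
    obs_prefix = {g: _prefix_counts(np.asarray(ids), family, nf)
                  for g, ids in gene_codons.items()}

    # observed per-peak frequencies
    obs = np.zeros((len(peaks), nf))
    peak_m = np.zeros(len(peaks), dtype=int)
    for j, (gid, s_nt, e_nt) in enumerate(peaks):
        if gid not in gene_codons:
            raise CompositionError(f"peak gene {gid} not in expressed annotation")
        cs, ce = peak_to_codon_range(s_nt, e_nt)
        ce = min(ce, len(gene_codons[gid]))
        m = ce - cs
        if m < 1:
            raise CompositionError(f"peak {gid}:{s_nt}-{e_nt} shorter than one codon")
        pref = obs_prefix[gid]
        obs[j] = (pref[ce] - pref[cs]) / m
        peak_m[j] = m
    mean_obs = obs.mean(axis=0)

    # control sets: sum of per-peak control frequencies, one vectorized pass per peak
    ctrl_sum = np.zeros((n_controls, nf))
    for j in range(len(peaks)):
        m = peak_m[j]
        w = np.maximum(lengths - m + 1, 0).astype(float)
        if w.sum() == 0:
            raise CompositionError(f"no CDS can host a control peak of {m} codons")
        g_draw = rng.choice(len(gids), size=n_controls, p=w / w.sum())
        starts = (rng.random(n_controls) * w[g_draw]).astype(int)
        for gi in np.unique(g_draw):
            sel = g_draw == gi
            pref = prefixes[gi]
            st = starts[sel]
            ctrl_sum[sel] += (pref[st + m] - pref[st]) / m
    ctrl_mean = ctrl_sum / len(peaks)

    k = (ctrl_mean >= mean_obs).sum(axis=0)
    l = (ctrl_mean <= mean_obs).sum(axis=0)
    p_emp = np.maximum(np.minimum(k, l) / n_controls, 1.0 / n_controls)
    p_adj = multipletests(p_emp, method="fdr_bh")[1]
    table = pd.DataFrame({
        "feature": feats, "mean_obs": mean_obs, "k": k, "l": l,
        "n_controls": n_controls, "p_emp": p_emp, "p_adj": p_adj,
        "direction": np.where(k < l, "enriched", np.where(k > l, "depleted", "tie")),
    })
    return RandomizationResult(table, n_controls)


def relative_frequency(freq_test: float, freq_control: float) -> float:
    """(Freq_t - Freq_c) / Freq_c; NaN when the control frequency is zero."""
    if freq_control == 0:
        return float("nan")
    return (freq_test - freq_control) / freq_control


# ---------------------------------------------------------------------------
# zero-inflated beta regression set contrasts
# ---------------------------------------------------------------------------

def _zib_nll(params: np.ndarray, y: np.ndarray, Xz: np.ndarray, Xm: np.ndarray) -> float:
    kz = Xz.shape[1]
    km = Xm.shape[1]
    eta_z = Xz @ params[:kz]
    eta_m = Xm @ params[kz : kz + km]
    log_phi = params[kz + km]
    phi = np.exp(log_phi)
    # zero part: P(y=0) = pi
    log_pi = -np.logaddexp(0.0, -eta_z)
    log_1mpi = -np.logaddexp(0.0, eta_z)
    zero = y == 0
    ll = log_pi[zero].sum()
    yp = y[~zero]
    mu = special.expit(eta_m[~zero])
    a = mu * phi
    b = (1 - mu) * phi
    ll += (log_1mpi[~zero]
           + special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
           + (a - 1) * np.log(yp) + (b - 1) * np.log1p(-yp)).sum()
    return -ll


@dataclass
class ZibFit:
    params: np.ndarray
    cov: np.ndarray | None
    sets: list[str]
    converged: bool
    n: int
    n_params: int


def _fit_zib(y: np.ndarray, set_codes: np.ndarray, size: np.ndarray,
             n_sets: int) -> ZibFit | None:
    n = len(y)
    Xset = np.zeros((n, n_sets))
    Xset[np.arange(n), set_codes] = 1.0
    Xset[:, 0] = 1.0  # reference-coded: col0 intercept, cols 1.. set offsets
    Xz = Xset
    size_std = (size - size.mean()) / (size.std() if size.std() > 0 else 1.0)
    Xm = np.column_stack([Xset, size_std])
    pos = y > 0
    if pos.sum() < n_sets + 2:
        return None
    # moment-based starting values
    p0_zero = np.clip((y == 0).mean(), 0.01, 0.99)
    mu0 = np.clip(y[pos].mean(), 1e-4, 1 - 1e-4)
    start = np.concatenate([
        [special.logit(p0_zero)], np.zeros(Xz.shape[1] - 1),
        [special.logit(mu0)], np.zeros(Xm.shape[1] - 1),
        [np.log(10.0)],
    ])
    res = optimize.minimize(_zib_nll, start, args=(y, Xz, Xm), method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    cov = None
    try:
        hess = approx_hess1(res.x, _zib_nll, args=(y, Xz, Xm))
        cov = np.linalg.inv(hess)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    # BFGS with numeric gradients often reports spurious "precision loss";
    # accept the optimum when the gradient is flat and the information
    # matrix is positive definite
    grad = optimize.approx_fprime(res.x, _zib_nll, 1e-7, y, Xz, Xm)
    flat = np.max(np.abs(grad)) < 1e-2 * (1.0 + abs(res.fun))
    return ZibFit(res.x, cov, [], bool((res.success or flat) and cov is not None),
                  n, len(res.x))


def _tukey_p(z: float, n_groups: int, df: float) -> float:
    """Family-wise p for a pairwise contrast via the studentized range."""
    if not np.isfinite(z):
        return float("nan")
    if n_groups < 2:
        raise CompositionError("need >= 2 sets")
    return float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), n_groups, df))


def zib_set_comparison(freq_table: pd.DataFrame, shrink_ones: bool = True) -> pd.DataFrame:
    """Per-feature pairwise set contrasts under a zero-inflated beta model.

    ``freq_table`` columns: ``feature``, ``set``, ``size`` (codon count of
    the unit) and ``freq`` in [0, 1]. Positive part: Beta(mu*phi, (1-mu)*phi)
    with logit(mu) ~ set + size; zero part: logit(pi) ~ set; joint ML fit.
    Pairwise Wald contrasts on the set levels, family-adjusted with the
    studentized range (Tukey), then BH across features per contrast.
    Frequencies equal to 1 are shrunk by the (y(n-1)+0.5)/n transform.
    """
    required = {"feature", "set", "size", "freq"}
    if not required <= set(freq_table.columns):
        raise CompositionError(f"freq_table must have columns {sorted(required)}")
    sets = sorted(freq_table["set"].unique())
    if len(sets) < 2:
        raise CompositionError("need >= 2 sets")
    set_code = {s: i for i, s in enumerate(sets)}
    rows = []
    for feature, grp in freq_table.groupby("feature", sort=True):
        y = grp["freq"].to_numpy(dtype=float)
        if shrink_ones and (y >= 1).any():
            n = len(y)
            y = np.where(y >= 1, (y * (n - 1) + 0.5) / n, y)
        codes = grp["set"].map(set_code).to_numpy()
        size = grp["size"].to_numpy(dtype=float)
        zero_frac = {s: float((y[codes == set_code[s]] == 0).mean()) for s in sets}
        pos_counts = {s: int((y[codes == set_code[s]] > 0).sum()) for s in sets}
        fit = _fit_zib(y, codes, size, len(sets))
        df_resid = len(y) - (2 * len(sets) + 2)
        for a, b in itertools.combinations(range(len(sets)), 2):
            sa, sb = sets[a], sets[b]
            est = se = p_pos = p_zero = float("nan")
            converged = fit is not None and fit.converged
            degenerate = pos_counts[sa] == 0 or pos_counts[sb] == 0
            if converged and not degenerate:
                kz = len(sets)
                # positive-part contrast (mu, link scale): coefficient diff
                ca = np.zeros(fit.n_params)
                if a > 0:
                    ca[kz + a] = 1.0
                if b > 0:
                    ca[kz + b] = -1.0
                est = float(ca @ fit.params)
                se = float(np.sqrt(ca @ fit.cov @ ca))
                if se > 0:
                    p_pos = _tukey_p(est / se, len(sets), max(df_resid, 1))
                cz = np.zeros(fit.n_params)
                if a > 0:
                    cz[a] = 1.0
                if b > 0:
                    cz[b] = -1.0
                est_z = float(cz @ fit.params)
                se_z = float(np.sqrt(cz @ fit.cov @ cz))
                if se_z > 0:
                    p_zero = _tukey_p(est_z / se_z, len(sets), max(df_resid, 1))
            elif degenerate:
                # one set has no positive observations: the positive part is
                # inestimable; test the zero proportions exactly instead
                za = int((y[codes == a] == 0).sum()); na = int((codes == a).sum())
                zb = int((y[codes == b] == 0).sum()); nb = int((codes == b).sum())
                _, p_zero = stats.fisher_exact([[za, na - za], [zb, nb - zb]])
            rows.append({
                "feature": feature, "contrast": f"{sa}-{sb}",
                "estimate": est, "se": se, "p_positive": p_pos, "p_zero": p_zero,
                "converged": bool(converged),
                "zero_frac_a": zero_frac[sa], "zero_frac_b": zero_frac[sb],
            })
    out = pd.DataFrame(rows)
    # BH across features, per contrast, on the primary (positive-part) p;
    # non-converged / NA features are excluded from the FDR denominator
    out["p_adj"] = np.nan
    for _, idx in out.groupby("contrast").groups.items():
        sub = out.loc[idx]
        ok = sub["p_positive"].notna()
        if ok.any():
            out.loc[sub.index[ok], "p_adj"] = multipletests(
                sub.loc[ok, "p_positive"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# codon window profiles
# ---------------------------------------------------------------------------

def codon_window_profile(
    peaks: list[tuple[str, int, int]],
    gene_codons: dict[str, np.ndarray],
    boundary: dict[str, np.ndarray] | None = None,
    window: int = 10,
    n_windows: int = 50,
    step: int = 1,
    family: str = "codon",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature frequencies in sliding windows around peak centers.

    Offset 0 is the within-peak frequency; offset +j (-j) is a ``window``-codon
    window starting ``j`` codons downstream (ending ``j`` codons upstream) of
    the peak center (center = start + ceil((end-start)/2) in codons).
    Windows truncated by CDS ends contribute their available codons; codons
    spanning a CDS-segment junction are dropped when ``boundary`` is given.
    Returns (mean-frequency matrix offsets x features, contributing-peak
    counts per offset).
    """
    feats = _features(family)
    nf = len(feats)
    offsets = list(range(-n_windows * step, n_windows * step + 1, step))
    sums = np.zeros((len(offsets), nf))
    counts = np.zeros(len(offsets), dtype=int)

    for gid, s_nt, e_nt in peaks:
        ids = np.asarray(gene_codons[gid])
        keep = np.ones(len(ids), dtype=bool)
        if boundary is not None and gid in boundary:
            keep = ~np.asarray(boundary[gid], dtype=bool)
        cs, ce = peak_to_codon_range(s_nt, e_nt)
        ce = min(ce, len(ids))
        center = cs + -(-(ce - cs) // 2)  # ceil
        for oi, off in enumerate(offsets):
            if off == 0:
                w0, w1 = cs, ce
            elif off > 0:
                w0, w1 = center + off, center + off + window
            else:
                w0, w1 = center + off - window + 1, center + off + 1
            w0 = max(w0, 0)
            w1 = min(w1, len(ids))
            if w1 <= w0:
                continue
            sel = ids[w0:w1][keep[w0:w1]]
            if len(sel) == 0:
                continue
            fids = _feature_ids(sel, family)
            sums[oi] += np.bincount(fids, minlength=nf) / len(sel)
            counts[oi] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts[:, None] > 0, sums / np.maximum(counts[:, None], 1), np.nan)
    freq = pd.DataFrame(means, index=pd.Index(offsets, name="offset"), columns=feats)
    n = pd.DataFrame({"offset": offsets, "n_peaks": counts})
    return freq, n


def gravy_index(protein: str) -> float:
    """Mean Kyte-Doolittle hydropathy; stop/unknown residues excluded."""
    vals = [KYTE_DOOLITTLE[r] for r in protein.upper() if r in KYTE_DOOLITTLE]
    if not vals:
        return float("nan")
    return float(np.mean(vals))
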