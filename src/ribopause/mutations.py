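"""Transcriptional-mutation tallies from per-site nucleotide pileups.

Sites are depth-subsampled to the smallest library, filtered on quality,
depth and alternative-allele fraction (high-fraction sites are genomic
variants, not transcriptional errors), tallied into per REF>ALT SNP
proportions, and compared between conditions with logistic regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

BASES = ("A", "C", "G", "T")


class MutationError(ValueError):
    pass


def _check(table: pd.DataFrame) -> None:
    required = {"site_id", "ref", "depth", "A", "C", "G", "T", "qual"}
    if not required <= set(table.columns):
        raise MutationError(f"pileup must have columns {sorted(required)}")
    bad = ~table["ref"].isin(BASES)
    if bad.any():
        raise MutationError(f"ref base not in ACGT at {table.loc[bad, 'site_id'].iloc[0]}")


def subsample_depth(tables: dict[str, pd.DataFrame], seed: int = 0) -> dict[str, pd.DataFrame]:
    """Binomially thin per-base counts so every condition matches the
    smallest library's total depth (approximately); deterministic per seed."""
    for t in tables.values():
        _check(t)
    totals = {c: int(t["depth"].sum()) for c, t in tables.items()}
    target = min(totals.values())
    rng = np.random.default_rng(seed)
    out = {}
    for cond, t in tables.items():
        frac = target / totals[cond]
        if frac >= 1.0:
            out[cond] = t.copy()
            continue
        thinned = t.copy()
        for b in BASES:
            thinned[b] = rng.binomial(t[b].to_numpy(), frac)
        thinned["depth"] = thinned[list(BASES)].sum(axis=1)
        out[cond] = thinned
    return out


def filter_sites(
    table: pd.DataFrame,
    min_qual: float = 10.0,
    min_depth: int = 700,
    max_alt_frac: float = 0.05,
    depth_cmp: str = ">=",
    use_qual: bool = True,
) -> pd.DataFrame:
    """Eligible sites with per-ALT SNP flags.

    A site is eligible when qual >= ``min_qual`` (unless ``use_qual=False``)
    and depth passes ``min_depth`` under ``depth_cmp``. Sites where any
    non-REF base reaches ``max_alt_frac`` of the depth are excluded entirely
    (genomic variants). An eligible site carries SNP REF>ALT when the ALT
    count is positive (its fraction is then necessarily below the cutoff).
    """
    _check(table)
    if depth_cmp not in (">=", ">"):
        raise MutationError("depth_cmp must be '>=' or '>'")
    t = table.copy()
    depth = t["depth"].to_numpy(dtype=float)
    ok = depth >= min_depth if depth_cmp == ">=" else depth > min_depth
    if use_qual:
        ok &= t["qual"].to_numpy(dtype=float) >= min_qual
    counts = t[list(BASES)].to_numpy(dtype=float)
    ref_idx = t["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    alt_counts = counts.copy()
    alt_counts[np.arange(len(t)), ref_idx] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = alt_counts / depth[:, None]
    is_variant = (frac >= max_alt_frac).any(axis=1)
    keep = ok & ~is_variant
    out = t.loc[keep].reset_index(drop=True)
    kept_frac = frac[keep]
    kept_alt = alt_counts[keep]
    for j, b in enumerate(BASES):
        out[f"snp_{b}"] = (kept_alt[:, j] > 0) & (kept_frac[:, j] < max_alt_frac)
    out["has_snp"] = out[[f"snp_{b}" for b in BASES]].any(axis=1)
    return out


def snp_proportions(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per REF>ALT and per REF>* SNP-site proportions over eligible REF sites."""
    rows = []
    for ref in BASES:
        sub = filtered[filtered["ref"] == ref]
        denom = len(sub)
        for alt in BASES:
            if alt == ref:
                continue
            num = int(sub[f"snp_{alt}"].sum()) if denom else 0
            rows.append((ref, alt, denom, num, num / denom if denom else np.nan))
        num_any = int(sub["has_snp"].sum()) if denom else 0
        rows.append((ref, "*", denom, num_any, num_any / denom if denom else np.nan))
    denom = len(filtered)
    num = int(filtered["has_snp"].sum()) if denom else 0
    rows.append(("*", "*", denom, num, num / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["ref", "alt", "n_sites", "n_snp", "proportion"])


def _logistic_p(n_snp_a: int, n_a: int, n_snp_b: int, n_b: int) -> float:
    """Wald p for the condition coefficient of a logistic regression of the
    SNP indicator on condition.

    With condition as the only covariate the MLE is saturated, so the
    coefficient is the log odds ratio and its Wald SE has the closed form
    sqrt(sum of reciprocal cell counts).
    """
    if min(n_a, n_b) == 0:
        return float("nan")
    if 0 in (n_snp_a, n_snp_b) or n_snp_a == n_a or n_snp_b == n_b:
        return float("nan")  # separation / boundary: Wald test undefined
    coef = (np.log(n_snp_a / (n_a - n_snp_a)) - np.log(n_snp_b / (n_b - n_snp_b)))
    se = np.sqrt(1.0 / n_snp_a + 1.0 / (n_a - n_snp_a)
                 + 1.0 / n_snp_b + 1.0 / (n_b - n_snp_b))
    return float(2.0 * stats.norm.sf(abs(coef) / se))


def compare_conditions(filtered_test: pd.DataFrame, filtered_ctrl: pd.DataFrame) -> pd.DataFrame:
    """Per REF>ALT (plus REF>* and overall) logistic-regression comparison of
    SNP-site proportions, with the relative frequency (test vs control, %)."""
    pa = snp_proportions(filtered_test).set_index(["ref", "alt"])
    pb = snp_proportions(filtered_ctrl).set_index(["ref", "alt"])
    rows = []
    for key in pa.index:
        a = pa.loc[key]
        b = pb.loc[key]
        p = _logistic_p(int(a["n_snp"]), int(a["n_sites"]), int(b["n_snp"]), int(b["n_sites"]))
        prop_t, prop_c = a["proportion"], b["proportion"]
        refreq = np.nan
        if np.isfinite(prop_c) and prop_c > 0 and np.isfinite(prop_t):
            refreq = (prop_t - prop_c) / prop_c * 100.0
        rows.append({
            "ref": key[0], "alt": key[1],
            "prop_test": prop_t, "prop_ctrl": prop_c,
            "n_test": int(a["n_sites"]), "n_ctrl": int(b["n_sites"]),
            "refreq_pct": refreq, "p_value": p,
        })
    return pd.DataFrame(rows)
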