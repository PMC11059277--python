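"""Amino-acid composition enrichment of labeled protein lists against
proteome-sampled control sets, with the signed heatmap transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_POS = {a: i for i, a in enumerate(STANDARD_AA)}

ACCEPTED_QUALIFIERS = frozenset({"involved_in", "located_in", "is_active_in", "part_of"})


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinList:
    list_id: str
    proteins: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.proteins:
            raise EnrichmentError(f"protein list {self.list_id} is empty")


# ---------------------------------------------------------------------------
# GO ontology / association handling
# ---------------------------------------------------------------------------

def parse_obo(path: str | Path) -> dict[str, set[str]]:
    """term id -> set of parent ids reached via is_a or part_of."""
    parents: dict[str, set[str]] = {}
    term_id = None
    in_term = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                in_term = True
                term_id = None
            elif line.startswith("["):
                in_term = False
            elif in_term and line.startswith("id:"):
                term_id = line.split("id:", 1)[1].strip()
                parents.setdefault(term_id, set())
            elif in_term and term_id and line.startswith("is_a:"):
                parents[term_id].add(line.split("is_a:", 1)[1].strip().split("!")[0].strip())
            elif in_term and term_id and line.startswith("relationship: part_of"):
                tgt = line.split("part_of", 1)[1].strip().split("!")[0].strip()
                parents[term_id].add(tgt)
    return parents


def term_descendants(parents: dict[str, set[str]], root: str) -> set[str]:
    """Root plus every term from which the root is reachable via is_a/part_of."""
    if root not in parents and root not in {p for ps in parents.values() for p in ps}:
        raise EnrichmentError(f"unknown ontology term {root}")
    children: dict[str, set[str]] = {}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, set()).add(child)
    out = {root}
    stack = [root]
    while stack:
        for c in children.get(stack.pop(), ()):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def parse_gaf(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise EnrichmentError(f"malformed GAF line: {line.strip()!r}")
            rows.append((f[1], f[3], f[4]))
    return pd.DataFrame(rows, columns=["protein_id", "qualifier", "go_id"])


def collect_go_proteins(
    gaf_path: str | Path,
    obo_path: str | Path,
    root_term: str,
    qualifiers: frozenset[str] = ACCEPTED_QUALIFIERS,
) -> ProteinList:
    """Proteins annotated to the root term or any is_a/part_of descendant,
    restricted to the accepted qualifier set; NOT-qualified rows excluded."""
    parents = parse_obo(obo_path)
    terms = term_descendants(parents, root_term)
    gaf = parse_gaf(gaf_path)
    ok_qual = gaf["qualifier"].isin(qualifiers)  # "NOT|x" fails membership
    hit = gaf[ok_qual & gaf["go_id"].isin(terms)]
    prots = tuple(sorted(hit["protein_id"].unique()))
    return ProteinList(root_term, prots, provenance=f"GO descendants of {root_term}")


# ---------------------------------------------------------------------------
# empirical enrichment
# ---------------------------------------------------------------------------

def aa_frequency_matrix(proteome: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Per-protein amino-acid frequencies (stop / nonstandard residues excluded
    from both numerator and denominator)."""
    ids = sorted(proteome)
    mat = np.zeros((len(ids), len(STANDARD_AA)))
    for i, pid in enumerate(ids):
        seq = proteome[pid].upper().rstrip("*")
        counts = np.zeros(len(STANDARD_AA))
        for r in seq:
            j = AA_POS.get(r)
            if j is not None:
                counts[j] += 1
        total = counts.sum()
        if total == 0:
            raise EnrichmentError(f"protein {pid} has no standard residues")
        mat[i] = counts / total
    return ids, mat


def empirical_aa_enrichment(
    protein_list: ProteinList,
    proteome: dict[str, str],
    n_controls: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Size-matched resampling enrichment of each amino acid.

    Observed statistic: unweighted mean frequency over the list's proteins.
    Controls: ``n_controls`` same-size draws without replacement from the
    proteome. p_emp = (min(k, l) + 1) / (n_controls + 1) with ties counted in
    both k and l; BH across the 20 amino acids; sign s = +1 if k > l else -1;
    t_signed = 1 - p_adj * s.
    """
    ids, mat = aa_frequency_matrix(proteome)
    pos = {pid: i for i, pid in enumerate(ids)}
    missing = [p for p in protein_list.proteins if p not in pos]
    if missing:
        raise EnrichmentError(f"list proteins absent from proteome: {missing[:5]}")
    m = len(protein_list.proteins)
    if m >= len(ids):
        raise EnrichmentError("protein list must be smaller than the proteome")
    # sorted so the float summation order (and thus the result) is
    # independent of how the list happens to be ordered
    obs = mat[sorted(pos[p] for p in protein_list.proteins)].mean(axis=0)

    rng = np.random.default_rng(seed)
    k = np.zeros(len(STANDARD_AA), dtype=int)
    l = np.zeros(len(STANDARD_AA), dtype=int)
    for _ in range(n_controls):
        draw = rng.choice(len(ids), size=m, replace=False)
        cm = mat[draw].mean(axis=0)
        k += cm >= obs
        l += cm <= obs
    p_emp = (np.minimum(k, l) + 1) / (n_controls + 1)
    p_adj = multipletests(p_emp, method="fdr_bh")[1]
    sign = np.where(k > l, 1, -1)
    return pd.DataFrame({
        "list_id": protein_list.list_id, "amino_acid": STANDARD_AA,
        "mean_obs": obs, "k": k, "l": l, "n_controls": n_controls,
        "p_emp": p_emp, "p_adj": p_adj, "sign": sign,
        "t_signed": 1.0 - p_adj * sign,
    })


def signed_heatmap_transform(p_adj: float, k: int, l: int) -> float:
    """t = 1 - p_adj * s with s = +1 if k > l, else -1 (ties take -1)."""
    s = 1 if k > l else -1
    return 1.0 - p_adj * s


def read_keyword_lists(path: str | Path) -> list[ProteinList]:
    """TSV with columns ``list_id`` and ``protein_id`` -> one list per label."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for lid, grp in df.groupby("list_id"):
        out.append(ProteinList(str(lid), tuple(sorted(grp["protein_id"].astype(str))),
                               provenance="keyword"))
    return out
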