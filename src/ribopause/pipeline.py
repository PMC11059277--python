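"""Pipeline orchestration: simulate -> annotate -> tdd -> peaks ->
composition -> enrich -> mutations -> report, driven by one YAML config with
per-stage manifests and deterministic per-stage sub-seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ribopause import __version__, annotation, composition, enrichment, io, mutations, tdd
from ribopause.synthetic import (SimConfig, make_design, simulate_pileup,
                                 simulate_ribo_rna_coverage, simulate_tdd_counts,
                                 simulate_transcriptome)
from ribopause.peaks import CoverageBundle, bidirectional_call

log = logging.getLogger("ribopause")

STAGES = ("simulate", "annotate", "tdd", "peaks", "composition", "enrich",
          "mutations", "report")


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


_DEFAULTS: dict = {
    "outdir": "ribopause_out",
    "seed": 1,
    "log_level": "INFO",
    # SimConfig overrides; bulk decay and dispersion chosen so stable-gene
    # detection is well-powered at this small default gene count
    "simulate": {"n_genes": 40, "k_base": 0.25, "dispersion": 0.02,
                 "stable_gene_fraction": 0.15, "n_sites": 2000},
    "tdd": {"alpha": 0.05, "stable_mode": "literal", "stable_times": "both"},
    "peaks": {"min_rna": 3.0, "min_score": 3.0, "min_replicates_above": 2},
    "composition": {"family": "codon", "n_controls": 10000, "window": 10,
                    "n_windows": 50},
    "enrich": {"n_controls": 10000},
    "mutations": {"min_qual": 10.0, "min_depth": 700, "max_alt_frac": 0.05,
                  "use_qual": True, "subsample": True},
    "report": {},
}

_SIM_FIELDS = {f.name for f in dc_fields(SimConfig)}


def default_config() -> dict:
    return json.loads(json.dumps(_DEFAULTS))  # deep copy


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        bad = set(user) - set(cfg)
        if bad:
            raise ConfigError(f"unknown config section(s): {sorted(bad)}")
        for key, val in user.items():
            if isinstance(cfg.get(key), dict):
                if not isinstance(val, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                if key == "simulate":
                    unknown = set(val) - _SIM_FIELDS
                else:
                    unknown = set(val) - set(cfg[key])
                if unknown:
                    raise ConfigError(f"unknown field(s) in {key!r}: {sorted(unknown)}")
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict,
                    inputs: list[Path], outputs: list[Path], seed: int) -> None:
    mdir = outdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage, "version": __version__, "seed": seed, "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    (mdir / f"{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(stage: str, paths: list[Path]) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise DependencyError(f"stage {stage!r} missing upstream input(s): {missing}")


def _sim_paths(outdir: Path) -> dict[str, Path]:
    d = outdir / "sim"
    names = {
        "genome": "genome.fa", "gtf": "annotation.gtf", "truth_genes": "truth_genes.tsv",
        "counts": "counts.tsv", "samples": "samples.tsv", "truth_tdd": "truth_tdd.tsv",
        "truth_pauses": "truth_pauses.tsv", "gene_lengths": "gene_lengths.tsv",
        "pileup_CTRL": "pileup_CTRL.tsv", "pileup_TRT": "pileup_TRT.tsv",
        "truth_pileup": "truth_pileup.tsv", "protein_lists": "protein_lists.tsv",
    }
    return {k: d / v for k, v in names.items()}


def run_simulate(cfg: dict, outdir: Path) -> list[Path]:
    seed = stage_seed(cfg["seed"], "simulate")
    sim_cfg = SimConfig(**{**cfg["simulate"], "seed": seed})
    paths = _sim_paths(outdir)
    (outdir / "sim").mkdir(parents=True, exist_ok=True)

    tx = simulate_transcriptome(sim_cfg)
    tx.write(paths["genome"], paths["gtf"], paths["truth_genes"])
    pd.DataFrame({"gene_id": [g.gene_id for g in tx.genes],
                  "length_nt": [len(g.seq) for g in tx.genes]}
                 ).to_csv(paths["gene_lengths"], sep="\t", index=False)

    tdd_sim = simulate_tdd_counts(sim_cfg, [g.gene_id for g in tx.genes])
    io.write_counts(tdd_sim.counts, paths["counts"])
    tdd_sim.samples.to_csv(paths["samples"], sep="\t", index=False)
    tdd_sim.truth.to_csv(paths["truth_tdd"], sep="\t", index=False)

    cov = simulate_ribo_rna_coverage(sim_cfg, tx.genes)
    cov.truth.to_csv(paths["truth_pauses"], sep="\t", index=False)
    outputs = list(paths.values())
    for cond, bundles in (("TRT", cov.test), ("CTRL", cov.ctrl)):
        for i in range(sim_cfg.n_replicates):
            for kind in ("ribo", "rna"):
                p = outdir / "sim" / f"{kind}_{cond}_rep{i + 1}.bedgraph"
                io.write_bedgraph(
                    {gid: getattr(b, kind)[i] for gid, b in bundles.items()}, p)
                outputs.append(p)

    pile = simulate_pileup(sim_cfg, tx.genes)
    pile.tables["CTRL"].to_csv(paths["pileup_CTRL"], sep="\t", index=False)
    pile.tables["TRT"].to_csv(paths["pileup_TRT"], sep="\t", index=False)
    pile.truth.to_csv(paths["truth_pileup"], sep="\t", index=False)

    # planted biased genes double as a labeled protein list for enrichment
    biased = tx.truth.loc[tx.truth["biased"], "gene_id"]
    pd.DataFrame({"list_id": "planted_biased", "protein_id": biased}
                 ).to_csv(paths["protein_lists"], sep="\t", index=False)

    _write_manifest(outdir, "simulate", cfg["simulate"], [], outputs, seed)
    return outputs


def run_annotate(cfg: dict, outdir: Path) -> list[Path]:
    paths = _sim_paths(outdir)
    _require("annotate", [paths["gtf"], paths["genome"]])
    d = outdir / "annotate"
    d.mkdir(parents=True, exist_ok=True)
    models, report = annotation.load_gene_models(paths["gtf"], paths["genome"])
    annotation.write_gff3(models, d / "models.gff3")
    annotation.write_cds_fasta(models, d / "cds.fa")
    (d / "filter_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    outputs = [d / "models.gff3", d / "cds.fa", d / "filter_report.json"]
    _write_manifest(outdir, "annotate", {}, [paths["gtf"], paths["genome"]],
                    outputs, stage_seed(cfg["seed"], "annotate"))
    return outputs


def run_tdd(cfg: dict, outdir: Path) -> list[Path]:
    paths = _sim_paths(outdir)
    _require("tdd", [paths["counts"], paths["samples"]])
    d = outdir / "tdd"
    d.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts(paths["counts"])
    samples = pd.read_csv(paths["samples"], sep="\t")
    p = cfg["tdd"]
    res = tdd.run_tdd(counts, samples, alpha=p["alpha"],
                      stable_mode=p["stable_mode"], stable_times=p["stable_times"])
    res.results.to_csv(d / "tdd_results.tsv", sep="\t", index=False)
    pd.Series(res.stable_genes, name="gene_id").to_csv(
        d / "stable_genes.tsv", sep="\t", index=False)
    outputs = [d / "tdd_results.tsv", d / "stable_genes.tsv"]
    _write_manifest(outdir, "tdd", p, [paths["counts"], paths["samples"]],
                    outputs, stage_seed(cfg["seed"], "tdd"))
    return outputs


def _load_bundles(outdir: Path) -> tuple[dict, dict, dict[str, int]]:
    paths = _sim_paths(outdir)
    lengths = dict(pd.read_csv(paths["gene_lengths"], sep="\t")
                   .set_index("gene_id")["length_nt"])
    sim_dir = outdir / "sim"
    reps = sorted({int(p.stem.split("rep")[1]) for p in sim_dir.glob("ribo_TRT_rep*.bedgraph")})
    bundles = {}
    for cond in ("TRT", "CTRL"):
        ribo = [io.read_bedgraph(sim_dir / f"ribo_{cond}_rep{r}.bedgraph", lengths)
                for r in reps]
        rna = [io.read_bedgraph(sim_dir / f"rna_{cond}_rep{r}.bedgraph", lengths)
               for r in reps]
        bundles[cond] = {
            gid: CoverageBundle(gid, np.vstack([t[gid] for t in ribo]),
                                np.vstack([t[gid] for t in rna]))
            for gid in lengths
        }
    return bundles["TRT"], bundles["CTRL"], lengths


def run_peaks(cfg: dict, outdir: Path) -> list[Path]:
    paths = _sim_paths(outdir)
    _require("peaks", [paths["gene_lengths"]])
    sim_dir = outdir / "sim"
    if not list(sim_dir.glob("ribo_*_rep*.bedgraph")):
        raise DependencyError("stage 'peaks' missing coverage bedGraph inputs")
    d = outdir / "peaks"
    d.mkdir(parents=True, exist_ok=True)
    test, ctrl, lengths = _load_bundles(outdir)
    p = cfg["peaks"]
    all_peaks = []
    for gid in sorted(lengths):
        res = bidirectional_call(test[gid], ctrl[gid], min_rna=p["min_rna"],
                                 min_score=p["min_score"],
                                 min_replicates_above=p["min_replicates_above"])
        all_peaks.extend(res["TC"] + res["CC"])
    io.peaks_to_frame(all_peaks).to_csv(d / "peaks.tsv", sep="\t", index=False)
    io.write_peaks_bed([q for q in all_peaks if q.direction == "TC"], d / "peaks_TC.bed")
    io.write_peaks_bed([q for q in all_peaks if q.direction == "CC"], d / "peaks_CC.bed")
    outputs = [d / "peaks.tsv", d / "peaks_TC.bed", d / "peaks_CC.bed"]
    _write_manifest(outdir, "peaks", p, [paths["gene_lengths"]], outputs,
                    stage_seed(cfg["seed"], "peaks"))
    return outputs


def _load_gene_codons(outdir: Path) -> dict[str, np.ndarray]:
    from Bio import SeqIO
    cds = outdir / "annotate" / "cds.fa"
    out = {}
    for rec in SeqIO.parse(str(cds), "fasta"):
        seq = str(rec.seq)
        out[rec.id] = composition.encode_codons(
            [seq[i:i + 3] for i in range(0, len(seq), 3)])
    return out


def run_composition(cfg: dict, outdir: Path) -> list[Path]:
    peaks_tsv = outdir / "peaks" / "peaks.tsv"
    cds = outdir / "annotate" / "cds.fa"
    _require("composition", [peaks_tsv, cds])
    d = outdir / "composition"
    d.mkdir(parents=True, exist_ok=True)
    p = cfg["composition"]
    seed = stage_seed(cfg["seed"], "composition")
    gene_codons = _load_gene_codons(outdir)
    table = pd.read_csv(peaks_tsv, sep="\t")
    kept = table[(table["kept"]) & (table["direction"] == "TC")]
    outputs = []
    if len(kept):
        pk = [(r.gene_id, int(r.start), int(r.end)) for r in kept.itertuples()]
        rand = composition.peak_randomization_test(
            pk, gene_codons, family=p["family"], n_controls=p["n_controls"], seed=seed)
        rand.table.to_csv(d / "randomization.tsv", sep="\t", index=False)
        prof, nmat = composition.codon_window_profile(
            pk, gene_codons, window=p["window"], n_windows=p["n_windows"],
            family=p["family"])
        prof.to_csv(d / "window_profile.tsv", sep="\t")
        nmat.to_csv(d / "window_counts.tsv", sep="\t", index=False)
        outputs = [d / "randomization.tsv", d / "window_profile.tsv",
                   d / "window_counts.tsv"]
    else:
        (d / "randomization.tsv").write_text("feature\tmean_obs\tk\tl\tn_controls\tp_emp\tp_adj\tdirection\n")
        outputs = [d / "randomization.tsv"]
    _write_manifest(outdir, "composition", p, [peaks_tsv, cds], outputs, seed)
    return outputs


def run_enrich(cfg: dict, outdir: Path) -> list[Path]:
    from Bio import SeqIO
    from Bio.Seq import Seq
    cds = outdir / "annotate" / "cds.fa"
    lists_tsv = _sim_paths(outdir)["protein_lists"]
    _require("enrich", [cds, lists_tsv])
    d = outdir / "enrich"
    d.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg["seed"], "enrich")
    proteome = {rec.id: str(Seq(str(rec.seq)).translate()).rstrip("*")
                for rec in SeqIO.parse(str(cds), "fasta")}
    frames = []
    for plist in enrichment.read_keyword_lists(lists_tsv):
        proteins = tuple(p for p in plist.proteins if p in proteome)
        if not proteins or len(proteins) >= len(proteome):
            continue
        plist = enrichment.ProteinList(plist.list_id, proteins, plist.provenance)
        frames.append(enrichment.empirical_aa_enrichment(
            plist, proteome, n_controls=cfg["enrich"]["n_controls"], seed=seed))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(d / "enrichment.tsv", sep="\t", index=False)
    outputs = [d / "enrichment.tsv"]
    _write_manifest(outdir, "enrich", cfg["enrich"], [cds, lists_tsv], outputs, seed)
    return outputs


def run_mutations(cfg: dict, outdir: Path) -> list[Path]:
    paths = _sim_paths(outdir)
    _require("mutations", [paths["pileup_CTRL"], paths["pileup_TRT"]])
    d = outdir / "mutations"
    d.mkdir(parents=True, exist_ok=True)
    p = cfg["mutations"]
    seed = stage_seed(cfg["seed"], "mutations")
    tables = {c: pd.read_csv(paths[f"pileup_{c}"], sep="\t") for c in ("CTRL", "TRT")}
    if p["subsample"]:
        tables = mutations.subsample_depth(tables, seed=seed)
    filt = {c: mutations.filter_sites(t, min_qual=p["min_qual"],
                                      min_depth=p["min_depth"],
                                      max_alt_frac=p["max_alt_frac"],
                                      use_qual=p["use_qual"])
            for c, t in tables.items()}
    for c, t in filt.items():
        mutations.snp_proportions(t).to_csv(d / f"proportions_{c}.tsv", sep="\t",
                                            index=False)
    comp = mutations.compare_conditions(filt["TRT"], filt["CTRL"])
    comp.to_csv(d / "comparison.tsv", sep="\t", index=False)
    outputs = [d / "proportions_CTRL.tsv", d / "proportions_TRT.tsv",
               d / "comparison.tsv"]
    _write_manifest(outdir, "mutations", p,
                    [paths["pileup_CTRL"], paths["pileup_TRT"]], outputs, seed)
    return outputs


def write_report(cfg: dict, outdir: Path) -> list[Path]:
    d = outdir / "report"
    d.mkdir(parents=True, exist_ok=True)
    lines = ["# ribopause run report", ""]
    manifests = sorted((outdir / "manifests").glob("*.json")) \
        if (outdir / "manifests").exists() else []
    if not manifests:
        raise DependencyError("stage 'report' found no manifests; run stages first")
    lines.append("Stages completed: " + ", ".join(m.stem for m in manifests))
    lines.append("")

    tdd_tsv = outdir / "tdd" / "tdd_results.tsv"
    lines.append("## TDD")
    if tdd_tsv.exists():
        res = pd.read_csv(tdd_tsv, sep="\t")
        counts = res["tdd_class"].value_counts().to_dict()
        lines.append(f"Classes: {counts}")
        truth_p = _sim_paths(outdir)["truth_tdd"]
        if truth_p.exists():
            truth = pd.read_csv(truth_p, sep="\t")
            merged = res.merge(truth, on="gene_id")
            tdd_genes = merged[merged["class"] == "tdd"]
            if len(tdd_genes):
                rec = (tdd_genes["tdd_class"] == "increased").mean()
                lines.append(f"Planted-TDD recovery (classified increased): {rec:.2%}")
    else:
        lines.append("no findings")
    lines.append("")

    peaks_tsv = outdir / "peaks" / "peaks.tsv"
    lines.append("## Peaks")
    if peaks_tsv.exists():
        pk = pd.read_csv(peaks_tsv, sep="\t")
        kept = pk[pk["kept"]]
        lines.append(f"Kept peaks per direction: {kept['direction'].value_counts().to_dict()}")
        truth_p = _sim_paths(outdir)["truth_pauses"]
        if truth_p.exists() and len(kept):
            truth = pd.read_csv(truth_p, sep="\t")
            tc = kept[kept["direction"] == "TC"]
            hit = 0
            for r in truth.itertuples():
                sub = tc[(tc["gene_id"] == r.gene_id)
                         & (tc["start"] < r.end_nt) & (tc["end"] > r.start_nt)]
                hit += int(len(sub) > 0)
            if len(truth):
                lines.append(f"Planted-pause recovery by kept TC peaks: {hit / len(truth):.2%}")
    else:
        lines.append("no findings")
    lines.append("")

    rand_tsv = outdir / "composition" / "randomization.tsv"
    lines.append("## Peak composition")
    if rand_tsv.exists():
        rnd = pd.read_csv(rand_tsv, sep="\t")
        if len(rnd):
            top = rnd.nsmallest(5, "p_adj")[["feature", "p_adj", "direction"]]
            lines.append("Top features: " + "; ".join(
                f"{r.feature} (p_adj={r.p_adj:.3g}, {r.direction})"
                for r in top.itertuples()))
        else:
            lines.append("no findings")
    else:
        lines.append("no findings")
    lines.append("")

    enr_tsv = outdir / "enrich" / "enrichment.tsv"
    lines.append("## Protein-list enrichment")
    if enr_tsv.exists() and enr_tsv.stat().st_size > 1:
        enr = pd.read_csv(enr_tsv, sep="\t")
        if len(enr):
            top = enr.nsmallest(5, "p_adj")[["list_id", "amino_acid", "p_adj", "t_signed"]]
            lines.append("Top cells: " + "; ".join(
                f"{r.list_id}/{r.amino_acid} (p_adj={r.p_adj:.3g}, t={r.t_signed:.3f})"
                for r in top.itertuples()))
        else:
            lines.append("no findings")
    else:
        lines.append("no findings")
    lines.append("")

    mut_tsv = outdir / "mutations" / "comparison.tsv"
    lines.append("## Transcriptional mutations")
    if mut_tsv.exists():
        mut = pd.read_csv(mut_tsv, sep="\t")
        overall = mut[(mut["ref"] == "*") & (mut["alt"] == "*")]
        if len(overall):
            r = overall.iloc[0]
            lines.append(f"Overall Refreq = {r['refreq_pct']:.1f}% (p = {r['p_value']:.3g})")
    else:
        lines.append("no findings")
    lines.append("")

    (d / "report.md").write_text("\n".join(lines))
    _write_manifest(outdir, "report", {}, manifests, [d / "report.md"],
                    stage_seed(cfg["seed"], "report"))
    return [d / "report.md"]


_RUNNERS = {
    "simulate": run_simulate, "annotate": run_annotate, "tdd": run_tdd,
    "peaks": run_peaks, "composition": run_composition, "enrich": run_enrich,
    "mutations": run_mutations, "report": write_report,
}


def run_pipeline(cfg: dict, stages: list[str] | None = None) -> dict[str, list[Path]]:
    """Run the requested stages in dependency order. Raises on the first
    failing stage; completed stages leave reusable outputs and manifests."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), 20))
    results = {}
    for stage in ordered:
        log.info("running stage %s", stage)
        results[stage] = _RUNNERS[stage](cfg, outdir)
    return results
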