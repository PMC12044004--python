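"""End-to-end pipeline: simulate -> qc -> diversity -> kmers -> structure
-> topology -> demography, with a manifest and a summary report.

A single :class:`RunConfig` (typically loaded from YAML) drives every
stage; a global seed expands into per-stage seeds through a fixed
derivation (``SeedSequence([global_seed, stage_index])``) so any stage can
be rerun in isolation and reproduce its output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .demographics import four_population_model
from .genotypes import (
    QcThresholds,
    attach_pop_labels,
    filter_genotypes,
    read_pop_labels,
    read_vcf,
    write_vcf,
)

STAGES = ["simulate", "qc", "diversity", "kmers", "structure", "topology",
          "demography"]

logger = logging.getLogger("foniokit")


def _setup_logging(outdir: str) -> None:
    if logger.handlers:
        return
    logger.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(),
                    logging.FileHandler(os.path.join(outdir, "run.log"))):
        handler.setFormatter(fmt)
        logger.addHandler(handler)

__all__ = ["RunConfig", "run_pipeline", "make_report", "STAGES"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults give a small self-contained demo."""

    outdir: str = "fonio_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # external inputs (used when the simulate stage is disabled)
    vcf: str | None = None
    labels: str | None = None
    fasta_dir: str | None = None
    # simulate
    samples: dict = field(default_factory=lambda: {
        "exilis": 6, "longiflora": 4, "iburua": 6, "ternata": 4})
    model: dict = field(default_factory=dict)  # four_population_model kwargs
    n_windows: int = 40
    window_len: int = 50_000
    missing_rate: float = 0.0
    # qc
    qc: dict = field(default_factory=dict)  # QcThresholds kwargs
    # diversity
    window_size: int = 50_000
    window_step: int = 10_000
    # kmers
    kmer_k: int = 31
    kmer_table_size: int = 20_000
    kmer_n_tables: int = 20
    kmer_subtable_size: int = 2_000
    # structure
    snmf_K: int = 2
    snmf_runs: int = 3
    # topology
    groups: dict | None = None  # group name -> population, default = species
    n_boot: int = 20
    # demography
    fit_pair: tuple[str, str] = ("exilis", "longiflora")
    fit_cycles: int = 6
    fit_n_sims: int = 1500
    fit_proposals: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if "simulate" not in self.stages:
            need_geno = {"qc", "diversity", "structure", "topology",
                         "demography"} & set(self.stages)
            if need_geno and not self.vcf:
                raise ConfigError("no simulate stage and no input VCF")
            if need_geno and not self.labels:
                raise ConfigError("population labels required for analysis "
                                  "stages when simulate is disabled")
            if "kmers" in self.stages and not self.fasta_dir:
                raise ConfigError("kmers stage needs FASTA input or the "
                                  "simulate stage")

    def stage_seed(self, stage: str) -> int:
        i = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, i]).generate_state(1)[0]
                   % (2**31 - 1))


def _params_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> str:
    """Execute the enabled stages in order; returns the output directory.

    Each stage writes its artifacts under ``outdir`` and registers itself
    in ``manifest.json`` (version, seed, parameter hash, outputs).  A
    stage failure stops the pipeline with a stage-scoped error; artifacts
    of completed stages are retained.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    _setup_logging(cfg.outdir)
    manifest = {"version": __version__, "seed": cfg.seed, "stages": {}}
    state: dict = {}

    def record(stage, params, outputs):
        manifest["stages"][stage] = {
            "seed": cfg.stage_seed(stage),
            "params_hash": _params_hash(params),
            "outputs": outputs,
        }
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("stage %s: start (seed %d)", stage, cfg.stage_seed(stage))
        try:
            outputs = _STAGE_FUNCS[stage](cfg, state)
        except Exception as exc:
            logger.error("stage %s: failed: %s", stage, exc)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        logger.info("stage %s: done (%d outputs)", stage, len(outputs))
        record(stage, _stage_params(cfg, stage), outputs)
    return cfg.outdir


def _stage_params(cfg: RunConfig, stage: str):
    d = dataclasses.asdict(cfg)
    d.pop("stages", None)
    return {stage: d}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, state: dict):
    from .coalescent import emit_sequences, inject_missingness, simulate_windows

    seed = cfg.stage_seed("simulate")
    model = four_population_model(**cfg.model)
    ds = simulate_windows(model, cfg.samples, cfg.n_windows, cfg.window_len,
                          seed=seed)
    if cfg.missing_rate > 0:
        ds.genotypes = inject_missingness(ds.genotypes, rate=cfg.missing_rate,
                                          seed=seed + 1)
    vcf = os.path.join(cfg.outdir, "simulated.vcf")
    write_vcf(ds.genotypes, vcf)
    labels = os.path.join(cfg.outdir, "labels.tsv")
    with open(labels, "w") as fh:
        for ind, pop in zip(ds.genotypes.individual_ids,
                            ds.genotypes.pop_labels):
            fh.write(f"{ind}\t{pop}\n")
    trees = os.path.join(cfg.outdir, "true_trees.nwk")
    with open(trees, "w") as fh:
        fh.write("\n".join(ds.true_trees) + "\n")
    fasta_dir = os.path.join(cfg.outdir, "fasta")
    emit_sequences(ds, fasta_dir)
    state["dataset"] = ds
    state["genotypes"] = ds.genotypes
    state["fasta_dir"] = fasta_dir
    state["model"] = model
    return [vcf, labels, trees, fasta_dir]


def _load_genotypes(cfg: RunConfig, state: dict):
    if "genotypes" in state:
        return state["genotypes"]
    g = read_vcf(cfg.vcf)
    g = attach_pop_labels(g, read_pop_labels(cfg.labels))
    state["genotypes"] = g
    return g


def _stage_qc(cfg: RunConfig, state: dict):
    g = _load_genotypes(cfg, state)
    filtered, report = filter_genotypes(g, QcThresholds(**cfg.qc))
    state["genotypes_qc"] = filtered
    out_vcf = os.path.join(cfg.outdir, "filtered.vcf")
    write_vcf(filtered, out_vcf)
    rep = os.path.join(cfg.outdir, "qc_report.json")
    with open(rep, "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
    return [out_vcf, rep]


def _qc_or_raw(cfg, state):
    return state.get("genotypes_qc") or _load_genotypes(cfg, state)


def _stage_diversity(cfg: RunConfig, state: dict):
    from .diversity import WindowSpec, dxy_da, window_diversity
    from .sfs import joint_folded_sfs

    g = _qc_or_raw(cfg, state)
    w = WindowSpec(size=cfg.window_size, step=cfg.window_step)
    div = window_diversity(g, w=w)
    div_path = os.path.join(cfg.outdir, "diversity.tsv")
    div.to_csv(div_path, sep="\t", index=False)
    pops = list(dict.fromkeys(g.pop_labels))
    outputs = [div_path]
    state["diversity"] = div
    seed = cfg.stage_seed("diversity")
    state["sfs"] = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            d = dxy_da(g, a, b, w=w)
            p = os.path.join(cfg.outdir, f"dxy_{a}_{b}.tsv")
            d.to_csv(p, sep="\t", index=False)
            outputs.append(p)
            sfs = joint_folded_sfs(g, a, b, seed=seed)
            sp = os.path.join(cfg.outdir, f"sfs_{a}_{b}.txt")
            sfs.to_text(sp)
            state["sfs"][(a, b)] = sfs
            outputs.append(sp)
    return outputs


def _stage_kmers(cfg: RunConfig, state: dict):
    from .kmers import build_kmer_table, jaccard_dissimilarity, sample_kmer_table

    fasta_dir = state.get("fasta_dir") or cfg.fasta_dir
    fastas = {
        os.path.splitext(f)[0]: os.path.join(fasta_dir, f)
        for f in sorted(os.listdir(fasta_dir))
        if f.endswith((".fa", ".fasta"))
    }
    table = build_kmer_table(fastas, k=cfg.kmer_k)
    seed = cfg.stage_seed("kmers")
    table = sample_kmer_table(table, n=cfg.kmer_table_size, seed=seed)
    g = _qc_or_raw(cfg, state)
    groups: dict[str, list[str]] = {}
    for ind, pop in zip(g.individual_ids, g.pop_labels):
        if ind in fastas:
            groups.setdefault(pop, []).append(ind)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    jac = jaccard_dissimilarity(table, groups, n_tables=cfg.kmer_n_tables,
                                table_size=cfg.kmer_subtable_size, seed=seed)
    out = os.path.join(cfg.outdir, "jaccard.tsv")
    jac.to_csv(out, sep="\t", index=False)
    means = os.path.join(cfg.outdir, "jaccard_means.json")
    with open(means, "w") as fh:
        json.dump(jac.attrs["group_means"], fh, indent=2)
    state["kmer_table"] = table
    state["jaccard_means"] = jac.attrs["group_means"]
    return [out, means]


def _stage_structure(cfg: RunConfig, state: dict):
    import pandas as pd

    from .structure import assign_clusters, pca, snmf_ancestry

    g = _qc_or_raw(cfg, state)
    X = g.genotypes.astype(float)
    X[X < 0] = np.nan
    res = pca(X)
    seed = cfg.stage_seed("structure")
    scores = pd.DataFrame(res.scores[:, :4], index=g.individual_ids,
                          columns=[f"PC{i+1}" for i in range(4)])
    pca_path = os.path.join(cfg.outdir, "pca_scores.tsv")
    scores.to_csv(pca_path, sep="\t")
    anc = snmf_ancestry(g, K=cfg.snmf_K, n_runs=cfg.snmf_runs, seed=seed)
    q_path = os.path.join(cfg.outdir, "ancestry_Q.tsv")
    anc.summary().to_csv(q_path, sep="\t")
    clusters = assign_clusters(anc)
    c_path = os.path.join(cfg.outdir, "clusters.tsv")
    clusters.to_csv(c_path, sep="\t")
    state["pca"] = res
    state["ancestry"] = anc
    return [pca_path, q_path, c_path]


def _stage_topology(cfg: RunConfig, state: dict):
    from .diversity import WindowSpec
    from .topology import (
        allele_freq_covariance,
        bootstrap_tree,
        fit_population_tree,
        twisst_weights,
        window_nj_trees,
    )

    g = _qc_or_raw(cfg, state)
    pops = list(dict.fromkeys(g.pop_labels))
    groups = cfg.groups or {
        p: [i for i, q in zip(g.individual_ids, g.pop_labels) if q == p]
        for p in pops
    }
    seed = cfg.stage_seed("topology")
    w = WindowSpec(size=cfg.window_size, step=cfg.window_size)  # non-overlap
    trees = window_nj_trees(g, w=w, min_snps_per_window=5)
    weights = twisst_weights(trees, groups, seed=seed) if len(groups) == 4 \
        else None
    W = allele_freq_covariance(g, pops)
    fit = fit_population_tree(W)
    consensus, support = bootstrap_tree(
        g, pops, block_size=max(2, g.n_loci // 20), n_boot=cfg.n_boot,
        seed=seed)
    out = {
        "population_tree": fit.newick,
        "variance_explained": fit.variance_explained,
        "bootstrap_consensus": consensus,
        "split_support": {",".join(sorted(k)): v for k, v in support.items()},
    }
    if weights is not None:
        out["twisst_mean_weights"] = weights.attrs["mean_weights"]
        out["twisst_max_weight_fraction"] = weights.attrs["max_weight_fraction"]
        wpath = os.path.join(cfg.outdir, "twisst_weights.tsv")
        weights.to_csv(wpath, sep="\t", index=False)
    path = os.path.join(cfg.outdir, "topology.json")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
    state["topology"] = out
    return [path]


def _stage_demography(cfg: RunConfig, state: dict):
    from .demography import (
        PAIR_PRIORS_DEFAULT,
        SFSDemographyModel,
        compare_models,
        pair_model_factory,
    )
    from .sfs import joint_folded_sfs

    g = _qc_or_raw(cfg, state)
    a, b = cfg.fit_pair
    pair = tuple(cfg.fit_pair)
    obs = state.get("sfs", {}).get(pair) or joint_folded_sfs(
        g, a, b, seed=cfg.stage_seed("demography"))
    priors = {k: PAIR_PRIORS_DEFAULT[k]
              for k in ("N_ANC", "T_DIV", "N_BOT")}
    fixed = {"N_CULT": 10_000.0, "N_WILD": 20_000.0, "T_EXP": 2_000.0}
    seed = cfg.stage_seed("demography")
    models = [
        SFSDemographyModel({pair: obs}, pair_model_factory(False, pair),
                           {k: priors[k] for k in ("N_ANC", "T_DIV")},
                           {a: sum(x == a for x in g.pop_labels),
                            b: sum(x == b for x in g.pop_labels)},
                           fixed_params=fixed, model_id="divergence_constant"),
        SFSDemographyModel({pair: obs}, pair_model_factory(True, pair),
                           priors,
                           {a: sum(x == a for x in g.pop_labels),
                            b: sum(x == b for x in g.pop_labels)},
                           fixed_params=fixed,
                           model_id="divergence_bottleneck"),
    ]
    table, results = compare_models(
        models, seed=seed, cycles=cfg.fit_cycles, n_sims=cfg.fit_n_sims,
        proposals_per_cycle=cfg.fit_proposals)
    path = os.path.join(cfg.outdir, "demography.json")
    best_id = table.iloc[0]["model"]
    payload = {
        "aic_table": table.to_dict(orient="records"),
        "best_model": best_id,
        "best_params": dict(results[best_id].params) if best_id in results
        else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    state["demography"] = payload
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "diversity": _stage_diversity,
    "kmers": _stage_kmers,
    "structure": _stage_structure,
    "topology": _stage_topology,
    "demography": _stage_demography,
}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def make_report(outdir: str) -> tuple[str, str]:
    """Summarise a finished run: one JSON, one plain-text report.

    Sections for stages that did not run are marked absent.  Regenerating
    the report from the same directory is idempotent.
    """
    import pandas as pd

    sections = {}
    # diversity per population
    div_path = os.path.join(outdir, "diversity.tsv")
    if os.path.exists(div_path):
        div = pd.read_csv(div_path, sep="\t")
        sections["diversity"] = (
            div.groupby("pop")[["pi", "theta_w", "tajima_d"]]
            .mean().round(8).to_dict(orient="index")
        )
    jm = os.path.join(outdir, "jaccard_means.json")
    if os.path.exists(jm):
        sections["jaccard"] = json.load(open(jm))
    pca_path = os.path.join(outdir, "pca_scores.tsv")
    if os.path.exists(pca_path):
        sections["pca"] = {"scores_file": os.path.basename(pca_path)}
    topo = os.path.join(outdir, "topology.json")
    if os.path.exists(topo):
        sections["topology"] = json.load(open(topo))
    q = os.path.join(outdir, "ancestry_Q.tsv")
    if os.path.exists(q):
        sections["ancestry"] = {"Q_file": os.path.basename(q)}
    dem = os.path.join(outdir, "demography.json")
    if os.path.exists(dem):
        sections["demography"] = json.load(open(dem))
    qc = os.path.join(outdir, "qc_report.json")
    if os.path.exists(qc):
        sections["qc"] = json.load(open(qc))
    all_sections = ["qc", "diversity", "jaccard", "pca", "ancestry",
                    "topology", "demography"]
    report = {s: sections.get(s, "absent") for s in all_sections}
    jpath = os.path.join(outdir, "report.json")
    with open(jpath, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    lines = []
    for s in all_sections:
        lines.append(f"== {s} ==")
        lines.append(json.dumps(report[s], indent=2, sort_keys=True)
                     if report[s] != "absent" else "(absent)")
        lines.append("")
    tpath = os.path.join(outdir, "report.txt")
    with open(tpath, "w") as fh:
        fh.write("\n".join(lines))
    return jpath, tpath
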