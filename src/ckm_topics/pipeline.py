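"""Stage runner binding the pipeline together.

Each stage reads the previous stage's artifacts from the output directory,
writes its own tables, and records a machine-readable manifest (input
hashes, seeds, package version) sufficient to reproduce the run.

Stage order: simulate -> discretize -> fit -> align -> associate -> gwas
-> prs -> report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, gwas as gwas_mod, io as io_mod
from .alignment import align_ensemble, silhouette_filter
from .config import PipelineConfig
from .discretize import BinnedCohort, QuantileBinner
from .synthetic import DiseaseSpec, GenConfig, GeneticEffect, generate_cohort
from .topic_model import ChainSamples, Vocabulary, fit_chain, select_K, tokenize

log = logging.getLogger("ckm_topics")

STAGES = ("simulate", "discretize", "fit", "align", "associate", "gwas", "prs",
          "report")


class PipelineError(RuntimeError):
    pass


class MissingArtifactError(PipelineError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage {stage!r} needs missing artifact {path.name!r}; "
            "run the upstream stage first")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, seed: int, inputs: list[Path],
                    extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
    }
    if extra:
        manifest.update(extra)
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1))


def _gen_config(cfg: PipelineConfig, seed: int, n_override: int | None = None) -> GenConfig:
    s = cfg.simulate
    return GenConfig(
        n_participants=n_override or s.n_participants,
        n_features=s.n_features,
        n_levels_per_feature=s.n_levels_per_feature,
        K_true=s.K_true,
        topic_sharpness=s.topic_sharpness,
        alpha_gen=s.alpha_gen,
        missing_rates=s.missing_rates,
        disease_specs=[DiseaseSpec(d["name"], d["baseline"], np.asarray(d["topic_weights"]))
                       for d in s.disease_specs],
        n_variants=s.n_variants,
        maf_range=(s.maf_min, s.maf_max),
        ld_block_size=s.ld_block_size,
        ld_strength=s.ld_strength,
        platform_fractions=tuple(s.platform_fractions),
        genetic_effects=[GeneticEffect(e["variant"], e["topic"], e["gamma"])
                         for e in s.genetic_effects],
        seed=seed,
    )


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    gc = _gen_config(cfg, cfg.seed)
    from .synthetic import generate_genotypes

    geno = generate_genotypes(gc) if gc.n_variants > 0 else None
    cohort, binned, truth = generate_cohort(gc, geno)
    io_mod.write_cohort_csv(cohort, out / "cohort.csv")
    binned.to_frame().to_csv(out / "binned_true.tsv", sep="\t", index=False)
    if geno is not None:
        io_mod.write_genotypes(geno, out)
    io_mod.write_truth(truth, out)
    _write_manifest(out, "simulate", cfg.seed, [])


def stage_discretize(cfg: PipelineConfig, out: Path) -> None:
    cohort = io_mod.read_cohort_csv(_require(out / "cohort.csv", "discretize"))
    biomarkers = [c for c in cohort.columns if c.startswith("biomarker_")]
    binner = QuantileBinner(percentiles=tuple(cfg.discretize.percentiles))
    binned = binner.fit(cohort[["participant_id", "sex"] + biomarkers]).transform(cohort)
    (out / "binspec.json").write_text(binner.spec_.to_json())
    binned.to_frame().to_csv(out / "binned.tsv", sep="\t", index=False)
    _write_manifest(out, "discretize", cfg.seed, [out / "cohort.csv"])


def _load_binned(out: Path, stage: str) -> BinnedCohort:
    df = pd.read_csv(_require(out / "binned.tsv", stage), sep="\t")
    return BinnedCohort.from_frame(df)


def stage_fit(cfg: PipelineConfig, out: Path) -> None:
    binned = _load_binned(out, "fit")
    f = cfg.fit
    K = f.K
    curve = None
    if f.select_K:
        K, curve = select_K(binned, f.K_grid, split_seed=cfg.seed,
                            train_fraction=f.train_fraction)
        log.info("selected K=%d", K)
    tokens = tokenize(binned)
    chains = []
    for c in range(f.n_chains):
        chain = fit_chain(tokens, K, alpha=f.alpha, beta_h=f.beta_h,
                          n_burn=f.n_burn, n_samples=f.n_samples, thin=f.thin,
                          seed=cfg.seed + c)
        chains.append(chain)
        _write_chain(out, c, chain)
    vocab = [list(e) for e in tokens.vocabulary.entries]
    meta = {
        "K": int(K), "n_chains": f.n_chains, "alpha": chains[0].alpha,
        "beta_h": f.beta_h, "n_burn": f.n_burn, "n_samples": f.n_samples,
        "thin": f.thin, "seeds": [cfg.seed + c for c in range(f.n_chains)],
        "vocabulary": vocab,
        "score_curve": curve,
    }
    (out / "fit.json").write_text(json.dumps(meta, indent=1))
    _write_manifest(out, "fit", cfg.seed, [out / "binned.tsv"])


def _write_chain(out: Path, c: int, chain: ChainSamples) -> None:
    S, K, V = chain.phi_samples.shape
    flat = chain.phi_samples.reshape(S * K, V)
    df = pd.DataFrame(flat)
    df.insert(0, "sample", np.repeat(np.arange(S), K))
    df.insert(1, "topic", np.tile(np.arange(K), S))
    df.to_csv(out / f"phi_samples_chain{c}.tsv", sep="\t", index=False,
              float_format="%.6g")
    pd.DataFrame(chain.theta_mean).to_csv(out / f"theta_mean_chain{c}.tsv",
                                          sep="\t", index=False,
                                          float_format="%.6g")
    np.savetxt(out / f"loglik_chain{c}.tsv", chain.loglik_trace, fmt="%.6f")


def _read_chains(out: Path, stage: str) -> list[ChainSamples]:
    meta = json.loads(_require(out / "fit.json", stage).read_text())
    vocab = Vocabulary([tuple(e) for e in meta["vocabulary"]])
    chains = []
    for c in range(meta["n_chains"]):
        df = pd.read_csv(_require(out / f"phi_samples_chain{c}.tsv", stage), sep="\t")
        S = df["sample"].nunique()
        K = meta["K"]
        phi = df.drop(columns=["sample", "topic"]).to_numpy().reshape(S, K, -1)
        theta_mean = pd.read_csv(out / f"theta_mean_chain{c}.tsv", sep="\t").to_numpy()
        trace = np.loadtxt(out / f"loglik_chain{c}.tsv")
        # theta samples are not persisted; store the mean as a single sample
        chains.append(ChainSamples(
            K=K, alpha=meta["alpha"], beta_h=meta["beta_h"],
            seed=meta["seeds"][c], vocabulary=vocab, phi_samples=phi,
            theta_samples=theta_mean[None], loglik_trace=trace))
    return chains


def stage_align(cfg: PipelineConfig, out: Path) -> None:
    chains = _read_chains(out, "align")
    ens = align_ensemble(chains, ci=cfg.align.credible)
    ens = silhouette_filter(ens, threshold=cfg.align.silhouette_threshold)
    report = {
        "permutations": [p.tolist() for p in ens.permutations],
        "costs": ens.costs,
        "silhouette": ens.silhouette.tolist(),
        "robust_topics": ens.robust_topics.tolist(),
    }
    (out / "alignment.json").write_text(json.dumps(report, indent=1))
    for name, arr in (("pooled_phi_mean", ens.pooled_phi_mean),
                      ("pooled_phi_lower", ens.pooled_phi_lower),
                      ("pooled_phi_upper", ens.pooled_phi_upper)):
        pd.DataFrame(arr).to_csv(out / f"{name}.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    theta_pooled = np.mean([c.theta_samples[0] for c in ens.chains], axis=0)
    pd.DataFrame(theta_pooled).to_csv(out / "theta_mean.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    _write_manifest(out, "align", cfg.seed,
                    [out / "fit.json", out / "phi_samples_chain0.tsv"])


def stage_associate(cfg: PipelineConfig, out: Path) -> None:
    theta = pd.read_csv(_require(out / "theta_mean.tsv", "associate"), sep="\t").to_numpy()
    cohort = io_mod.read_cohort_csv(_require(out / "cohort.csv", "associate"))
    a = cfg.associate
    design_cols = [c for c in (*a.covariates, *a.diseases) if c in cohort.columns]
    missing = [d for d in a.diseases if d not in cohort.columns]
    if missing:
        raise PipelineError(f"cohort lacks disease columns {missing}")
    assoc = association.associate(theta, cohort[design_cols],
                                  alpha_family=a.alpha_family)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    calls = association.classify_subtypes(assoc, diseases=tuple(a.diseases))
    calls.to_csv(out / "subtypes.tsv", sep="\t", index=False)
    candidates = calls.loc[calls["call"] == "candidate_CKM", "topic"].tolist()
    robust = json.loads((out / "alignment.json").read_text())["robust_topics"] \
        if (out / "alignment.json").exists() else list(range(theta.shape[1]))
    candidates = [t for t in candidates if t in robust]
    prev_topics = candidates or robust
    prev = association.prevalence(theta, prev_topics,
                                  threshold=a.loading_threshold,
                                  sweep=tuple(a.sensitivity))
    prev.sensitivity.to_csv(out / "prevalence.tsv", sep="\t", index=False)
    (out / "prevalence.json").write_text(json.dumps({
        "threshold": prev.threshold,
        "topics": prev_topics,
        "per_topic_cases": {str(k): v for k, v in prev.per_topic_cases.items()},
        "overall_cases": prev.overall_cases,
        "overall_fraction": prev.overall_fraction,
    }, indent=1))
    _write_manifest(out, "associate", cfg.seed,
                    [out / "theta_mean.tsv", out / "cohort.csv"])


def _gwas_covariates(cohort: pd.DataFrame, cols) -> pd.DataFrame:
    return cohort[list(cols)]


def stage_gwas(cfg: PipelineConfig, out: Path) -> None:
    theta = pd.read_csv(_require(out / "theta_mean.tsv", "gwas"), sep="\t").to_numpy()
    cohort = io_mod.read_cohort_csv(_require(out / "cohort.csv", "gwas"))
    dosages, variants = io_mod.read_dosage_tsv(_require(out / "dosages.tsv", "gwas"))
    platforms = io_mod.read_platforms_tsv(_require(out / "platforms.tsv", "gwas"))
    calls = pd.read_csv(_require(out / "subtypes.tsv", "gwas"), sep="\t")
    g = cfg.gwas
    targets = calls.loc[calls["call"] == "candidate_CKM", "topic"].tolist() or [0]
    models = {
        "demographics": list(g.demographics),
        "anthropometrics": list(g.demographics) + list(g.anthropometrics),
    }
    all_leads = []
    lambdas = {}
    for topic in targets:
        y_all = association.rank_transform(theta[:, topic], inverse_normal=True)
        for model_name, cov_cols in models.items():
            per_platform = []
            for plat in (1, 2, 3):
                sel = platforms == plat
                if sel.sum() < len(cov_cols) + 5:
                    continue
                tab = gwas_mod.gwas_platform(
                    y_all[sel], dosages[sel],
                    _gwas_covariates(cohort.loc[sel], cov_cols))
                tab.to_csv(out / f"gwas_topic{topic}_{model_name}_platform{plat}.tsv",
                           sep="\t", index=False)
                per_platform.append(tab)
            meta = gwas_mod.meta_analyze(per_platform, variants)
            meta["log10p"] = np.log10(np.maximum(meta["p"], 1e-300))
            lam = gwas_mod.lambda_gc(meta["p"].dropna().to_numpy())
            lambdas[f"topic{topic}_{model_name}"] = lam
            leads = gwas_mod.clump_leads(meta, dosages,
                                         r2_threshold=g.r2_threshold,
                                         window_bp=g.window_bp,
                                         p_threshold=g.p_threshold)
            meta["lead"] = meta.index.isin(leads.index)
            cols = ["id", "chrom", "pos", "ea", "nea", "maf", "beta", "se",
                    "p", "log10p", "n", "lead"]
            meta[cols].rename(columns={
                "id": "rsID", "chrom": "CHR", "pos": "POS", "ea": "EA",
                "nea": "NEA", "maf": "MAF", "beta": "BETA", "se": "SE",
                "p": "P", "log10p": "LOG10P", "n": "N", "lead": "LEAD",
            }).to_csv(out / f"gwas_topic{topic}_{model_name}_meta.tsv",
                      sep="\t", index=False)
            if model_name == "anthropometrics" and len(leads):
                lead_out = leads.assign(topic=topic)
                all_leads.append(lead_out)
    leads_df = (pd.concat(all_leads, ignore_index=True)
                if all_leads else pd.DataFrame(
                    columns=["id", "chrom", "pos", "beta", "se", "p", "topic"]))
    leads_df.to_csv(out / "leads.tsv", sep="\t", index=False)
    (out / "lambda_gc.json").write_text(json.dumps(lambdas, indent=1))
    _write_manifest(out, "gwas", cfg.seed,
                    [out / "theta_mean.tsv", out / "dosages.tsv"],
                    extra={"targets": [int(t) for t in targets]})


def stage_prs(cfg: PipelineConfig, out: Path) -> None:
    leads = pd.read_csv(_require(out / "leads.tsv", "prs"), sep="\t")
    p = cfg.prs
    val_seed = cfg.seed + p.validation_seed_offset
    gc = _gen_config(cfg, val_seed, n_override=p.validation_n)
    from .synthetic import generate_genotypes

    geno = generate_genotypes(gc)
    cohort, _, _ = generate_cohort(gc, geno)
    a = cfg.associate
    rows = []
    for topic, grp in leads.groupby("topic") if len(leads) else []:
        model = gwas_mod.build_prs(grp, subtype=f"topic{topic}", adjusted=True)
        scores, n_drop = gwas_mod.score_prs(model, geno.dosages,
                                            list(geno.variants["id"]))
        val = gwas_mod.validate_prs(
            scores, cohort[list(a.diseases)],
            cohort[["age", "sex", "smoking"]], method=p.method)
        val.insert(0, "topic", topic)
        val["n_leads"] = len(grp)
        val["n_dropped"] = n_drop
        rows.append(val)
    res = (pd.concat(rows, ignore_index=True) if rows
           else pd.DataFrame(columns=["topic", "outcome", "beta", "se", "p",
                                      "direction", "n_leads", "n_dropped"]))
    res.to_csv(out / "prs_validation.tsv", sep="\t", index=False)
    _write_manifest(out, "prs", cfg.seed, [out / "leads.tsv"])


def stage_report(cfg: PipelineConfig, out: Path) -> None:
    subtypes = pd.read_csv(_require(out / "subtypes.tsv", "report"), sep="\t")
    prevalence = json.loads(_require(out / "prevalence.json", "report").read_text())
    alignment = json.loads(_require(out / "alignment.json", "report").read_text())
    leads = pd.read_csv(_require(out / "leads.tsv", "report"), sep="\t")
    prs = pd.read_csv(_require(out / "prs_validation.tsv", "report"), sep="\t")
    lambdas = json.loads(_require(out / "lambda_gc.json", "report").read_text())
    report = {
        "n_topics": len(subtypes),
        "robust_topics": alignment["robust_topics"],
        "subtype_calls": subtypes.to_dict(orient="records"),
        "n_candidate_subtypes": int((subtypes["call"] == "candidate_CKM").sum()),
        "n_protective": int((subtypes["call"] == "protective").sum()),
        "prevalence": prevalence,
        "lambda_gc": lambdas,
        "n_lead_variants": int(len(leads)),
        "prs_validation": prs.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    lines = [
        f"Topics fitted: {report['n_topics']} "
        f"(robust: {len(report['robust_topics'])})",
        f"Candidate CKM subtypes: {report['n_candidate_subtypes']}; "
        f"protective profiles: {report['n_protective']}",
        f"Overall prevalence at threshold {prevalence['threshold']:.0%}: "
        f"{prevalence['overall_fraction']:.1%} ({prevalence['overall_cases']} cases)",
        f"Genome-wide significant lead variants: {report['n_lead_variants']}",
    ]
    for rec in report["prs_validation"]:
        lines.append(
            f"PRS topic {rec['topic']} vs {rec['outcome']}: "
            f"beta={rec['beta']:.3f} p={rec['p']:.2e}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    _write_manifest(out, "report", cfg.seed, [out / "subtypes.tsv"])


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "discretize": stage_discretize,
    "fit": stage_fit,
    "align": stage_align,
    "associate": stage_associate,
    "gwas": stage_gwas,
    "prs": stage_prs,
    "report": stage_report,
}


def run_stage(name: str, cfg: PipelineConfig, out) -> None:
    """Run one pipeline stage, writing artifacts + manifest under ``out``."""
    if name not in _STAGE_FUNCS:
        raise PipelineError(f"unknown stage {name!r}; stages are {STAGES}")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    log.info("running stage %s (seed %d)", name, cfg.seed)
    _STAGE_FUNCS[name](cfg, out)


def run_all(cfg: PipelineConfig, out) -> None:
    for name in STAGES:
        run_stage(name, cfg, out)
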