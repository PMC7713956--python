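"""One-command orchestration: simulate/load -> validate -> screen ->
count -> test -> report.

A run is driven by a config mapping (YAML file or dict) with either a
``simulate:`` block (CrossConfig fields) or a ``data:`` block with paths
to the three TSVs; optional ``sites:`` (path) or ``simulate_sites: true``
adds the introgression window scan.  Outputs are plain TSV/JSON files in
the output directory plus a manifest with config snapshot, seed and
output digests; a fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, anomaly, inference, introgression
from .data_model import Dataset, check_mendelian_consistency, read_dataset, write_dataset
from .simulate import CrossConfig, simulate_cross, simulate_snp_sites

log = logging.getLogger("meiodrive")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return out
        return inner
    return wrap


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


@_stage("input")
def _obtain_dataset(cfg: dict, seed):
    if "simulate" in cfg:
        sim = dict(cfg["simulate"] or {})
        if seed is not None:
            sim["rng_seed"] = int(seed)
        ccfg = CrossConfig.from_dict(sim)
        ds, truth = simulate_cross(ccfg)
        return ds, truth, ccfg
    if "data" in cfg:
        d = cfg["data"]
        ds = read_dataset(d["genotypes"], d["pedigree"], d["markers"])
        return ds, None, None
    raise ValueError("config needs a 'simulate' or 'data' block")


def _group_estimates(records: pd.DataFrame, p0: float) -> pd.DataFrame:
    """Exact-binomial/offset-GLM estimates for the standard pooled scopes
    and for every marker x parent sex."""
    rows = []

    def add(scope, subset, sub):
        if not len(sub):
            return
        s, n = int(sub["transmitted"].sum()), int(len(sub))
        est = inference.estimate_k(s, n, p0=p0, scope=scope)
        glm = inference.glm_offset_fit(s, n, p0)
        rows.append(
            dict(
                scope=scope, subset=subset, n=n, successes=s,
                k=est.k, k_rel_background=inference.EXPIT(
                    inference.LOGIT(0.5)
                    + (glm.beta0 if np.isfinite(glm.beta0) else 0.0)
                ),
                ci_low=est.ci95[0], ci_high=est.ci95[1],
                p_binomial=est.p_binomial, p_wald=est.p_wald, p0=p0,
            )
        )

    add("all", "all", records)
    for sex in ("F", "M"):
        add(f"sex={sex}", "all", records[records["parent_sex"] == sex])
    for (sex, pos), sub in records.groupby(["parent_sex", "position_class"]):
        add(f"sex={sex},position={pos}", "all", sub)
    for (sex, gen, pos), sub in records.groupby(
        ["parent_sex", "parent_cohort", "position_class"]
    ):
        add(f"sex={sex},generation={gen},position={pos}", "all", sub)
    for (marker, sex), sub in records.groupby(["marker_id", "parent_sex"]):
        add(f"marker={marker},sex={sex}", "all", sub)
    return pd.DataFrame(rows)


def _marker_counts(records: pd.DataFrame, by_level=False) -> pd.DataFrame:
    if by_level:
        grp = records.groupby(
            ["marker_id", "parent_cohort", "position_class", "parent_sex"]
        )["transmitted"].agg(["sum", "size"]).reset_index()
        grp["level"] = (
            grp["parent_cohort"] + ":" + grp["position_class"] + ":" + grp["parent_sex"]
        )
        out = grp.rename(
            columns={"marker_id": "group", "sum": "successes", "size": "n"}
        )[["group", "level", "successes", "n"]]
    else:
        grp = records.groupby("marker_id")["transmitted"].agg(["sum", "size"]).reset_index()
        out = grp.rename(
            columns={"marker_id": "group", "sum": "successes", "size": "n"}
        )
    return out.sort_values(["group"] + (["level"] if by_level else [])).reset_index(drop=True)


def _fit_to_dict(fit: inference.RandomInterceptFit) -> dict:
    return {
        "beta": [float(b) for b in fit.beta],
        "levels": list(fit.levels),
        "sigma": fit.sigma,
        "loglik": fit.loglik,
        "loglik_sigma0": fit.loglik_sigma0,
        "k_population": [float(k) for k in np.atleast_1d(fit.k_population)],
        "p0": fit.p0,
        "n_nodes": fit.n_nodes,
        "converged": fit.converged,
    }


@_stage("test")
def _run_models(records: pd.DataFrame, cfg: dict) -> dict:
    models: dict = {}
    stats_cfg = cfg.get("stats", {}) or {}
    p0_setting = stats_cfg.get("p0", "auto")
    background_mode = stats_cfg.get("background_mode", "glmm")

    males = records[records["parent_sex"] == "M"]
    if p0_setting == "auto":
        try:
            p0 = inference.background_rate(records, mode=background_mode)
        except inference.EstimateError:
            p0 = 0.5
    else:
        p0 = float(p0_setting)
    models["background"] = {"p0": p0, "mode": background_mode,
                            "n_male": int(len(males))}

    # pooled GLMMs with marker as random intercept
    for name, sub in (
        ("females", records[records["parent_sex"] == "F"]),
        ("males", males),
        ("combined", records),
    ):
        if sub["marker_id"].nunique() < 2:
            continue
        fit = inference.glmm_fit(_marker_counts(sub), p0=p0)
        models[f"glmm_{name}"] = _fit_to_dict(fit)

    # eight-level generation x position x sex fixed effect, marker RE
    if records["marker_id"].nunique() >= 2:
        counts8 = _marker_counts(records, by_level=True)
        if counts8["level"].nunique() >= 2:
            fit8 = inference.glmm_fit(counts8, p0=p0, fixed="eight_level")
            models["glmm_eight_level"] = _fit_to_dict(fit8)
            focal = "BC1:centromeric:F"
            if focal in fit8.levels:
                con = inference.contrast_level(fit8, focal)
                models["contrast_focal_level"] = {
                    "level": focal, "estimate": con.estimate, "se": con.se,
                    "z": con.z, "p": con.p, "contrast": con.contrast,
                }

    # among-individual heterogeneity in BC1 parents (drive-enabling
    # background hypothesis): individual identity as random intercept
    bc1f = records[(records["parent_cohort"] == "BC1") & (records["parent_sex"] == "F")]
    for pos in ("centromeric", "distal"):
        sub = bc1f[bc1f["position_class"] == pos]
        if sub["parent_id"].nunique() < 2:
            continue
        counts = sub.groupby("parent_id")["transmitted"].agg(["sum", "size"]).reset_index()
        counts.columns = ["group", "successes", "n"]
        fit = inference.glmm_fit(counts, p0=p0)
        lrt = inference.lrt_random_effect(fit.loglik_sigma0, fit.loglik)
        models[f"lrt_individual_bc1_female_{pos}"] = {
            "sigma": fit.sigma, "lr": lrt.lr,
            "p_nominal": lrt.p_nominal, "p_boundary": lrt.p_boundary,
            "n_individuals": int(sub["parent_id"].nunique()),
        }
    return models


def run_pipeline(config, out_dir, seed=None) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        manifest = _run(cfg, out, seed)
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest


def _run(cfg: dict, out: Path, seed) -> dict:
    seed = cfg.get("seed") if seed is None else seed
    ds, truth, ccfg = _obtain_dataset(cfg, seed)
    write_dataset(ds, out / "dataset")

    violations = check_mendelian_consistency(ds)
    log.info("mendelian check: %d flagged trios", len(violations))

    ds = ancestry.apply_w_coding(ds)
    calls = anomaly.detect_anomalies(ds)
    excl = anomaly.exclusion_set(calls, ds)
    anomaly.calls_to_frame(calls).to_csv(out / "anomalies.tsv", sep="\t", index=False)
    log.info("anomaly screen: %d calls", len(calls))

    ds, null_calls = ancestry.infer_null_alleles(ds)
    log.info("null inference: %d calls", len(null_calls))

    policy = (cfg.get("counting", {}) or {}).get("ambiguous_policy", "exclude")
    registry = ancestry.build_origin_registry(ds, policy=policy)
    result = ancestry.count_transmissions(
        ds, registry, excluded_offspring_chromosomes=excl
    )
    records = result.records
    records.to_csv(out / "transmissions.tsv", sep="\t", index=False)
    ledger = dict(result.ledger)
    ledger["null_calls"] = len(null_calls)
    ledger["anomaly_calls"] = len(calls)
    ledger["mendelian_flags"] = len(violations)
    log.info("counted %d informative of %d transmissions",
             ledger["informative"], ledger["total"])

    models = _run_models(records, cfg)
    p0 = models["background"]["p0"]

    frames = [_group_estimates(records, p0).assign(subset="all")]
    for which in ("heterozygous_parents", "no_inbreeding"):
        sub = ancestry.subset_transmissions(records, ds, registry, which)
        ledger[f"subset_{which}_n"] = int(len(sub))
        if len(sub):
            frames.append(_group_estimates(sub, p0).assign(subset=which))
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False,
                   float_format="%.8g")

    # power: pooled within generation x sex, plus per-marker female
    power_rows = []
    for (gen, sex), sub in records.groupby(["parent_cohort", "parent_sex"]):
        spec = inference.power_detectable_k(len(sub))
        power_rows.append((f"generation={gen},sex={sex}", len(sub), spec.k_bound))
    for marker, sub in records[records["parent_sex"] == "F"].groupby("marker_id"):
        spec = inference.power_detectable_k(len(sub))
        power_rows.append((f"marker={marker},sex=F", len(sub), spec.k_bound))
    pd.DataFrame(power_rows, columns=["scope", "n", "k_bound_80pct"]).to_csv(
        out / "power.tsv", sep="\t", index=False, float_format="%.8g"
    )

    # sex ratio in the backcross generations
    sexed = ds.individuals[ds.individuals["cohort"].isin(("BC1", "BC2"))]
    sexes = {}
    for name, sub in (("BC1", sexed[sexed["cohort"] == "BC1"]),
                      ("BC2", sexed[sexed["cohort"] == "BC2"]),
                      ("BC1+BC2", sexed)):
        nf = int((sub["sex"] == "F").sum())
        nm = int((sub["sex"] == "M").sum())
        if nf and nm:
            res = inference.sex_ratio_test(nf, nm)
            sexes[name] = {"n_f": nf, "n_m": nm, "fmr": res.fmr,
                           "ci95": list(res.ci95), "p": res.p}
    models["sex_ratio"] = sexes

    n_markers = ds.markers["marker_id"].nunique()
    models["bonferroni"] = inference.bonferroni_ledger((n_markers, 2, 2, 2))

    with open(out / "informativeness_ledger.json", "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
    with open(out / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, sort_keys=True, default=float)

    # optional introgression scan
    if cfg.get("simulate_sites") or cfg.get("sites"):
        rng = np.random.default_rng(
            int(seed if seed is not None else 0) + 10_007
        )
        if cfg.get("sites"):
            sites = introgression.read_sites(cfg["sites"])
            chrom_lengths = {
                c: int(g["position"].max()) + 1
                for c, g in sites.groupby("chromosome")
            }
            chrom_lengths.update(cfg.get("chrom_lengths", {}))
        else:
            sites, chrom_lengths, _ = simulate_snp_sites(rng)
        calls_w = introgression.scan_windows(sites, chrom_lengths)
        summary = introgression.flag_introgressed(calls_w)
        introgression.windows_to_frame(calls_w).to_csv(
            out / "windows.tsv", sep="\t", index=False
        )
        introgression.regions_to_frame(summary.regions).to_csv(
            out / "regions.tsv", sep="\t", index=False
        )
        models["introgression"] = {
            "n_regions": summary.n_regions,
            "admixed_diploid_fraction": summary.admixed_diploid_fraction,
        }
        with open(out / "models.json", "w") as fh:
            json.dump(models, fh, indent=2, sort_keys=True, default=float)

    manifest = {
        "seed": seed,
        "config": cfg if ccfg is None else {**cfg, "simulate": ccfg.to_dict()},
        "n_tests_registered": models["bonferroni"]["m"],
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json"))
            if p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
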