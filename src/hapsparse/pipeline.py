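"""End-to-end orchestration: simulate/load -> QC -> blocks -> features ->
kinship -> BLUEs -> sparse CV -> report, driven by a single YAML config.

Every stage writes its artifacts plus a manifest (parameters, seeds, input
checksums), so re-running an identical config is bit-identical.  Stages can
be toggled; disabling ``blocks`` restricts the run to the marker coding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_qc, kinship, ld_blocks, sparse_cv
from .gp_models import ModelSpec
from .hap_features import build_variant_set, enumerate_haplotypes, filter_rare_alleles
from .pheno_two_stage import EnvBLUEs, stage1_all_envs
from .synthetic_data import PRESETS, SimConfig, simulate_population

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "report"]

#: Study defaults, all overridable from the YAML config.
DEFAULT_CONFIG = {
    "seed": 1,
    "stages": ["simulate", "qc", "blocks", "features", "kinship", "blues", "cv", "report"],
    "simulate": {"preset": None},  # SimConfig fields may be given directly
    "qc": {"maf_min": 0.05, "miss_max": 0.1},
    "blocks": {
        "window_bp": 200_000,
        "strong_low": 0.70,
        "strong_high": 0.98,
        "recomb_high": 0.90,
        "strong_frac": 0.95,
    },
    "features": {"freq_min": 0.05, "codings": ["marker", "hap_complete", "hap_2snp", "hap_3snp"]},
    "blues": {"design": ["replicate", "row", "column"]},
    "cv": {
        "models": ["VG", "VGR", "FA"],
        "missing_rates": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
        "cv_repeats": 10,
        "mask_repeats": 10,
        "n_folds": 5,
        "n_iter": 10_000,
        "burn_in": 4_000,
    },
    "genotypes": None,  # path, used when "simulate" not in stages
    "plots": None,
    "blues_csv": None,  # precomputed BLUEs bypass stage 1
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else _merge(DEFAULT_CONFIG, config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "stages": stages, "config": cfg, "artifacts": {}}

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["artifacts"][name] = _sha256(path)

    try:
        g = None
        plots = None
        blues = None
        if "simulate" in stages:
            sim_kwargs = {k: v for k, v in (cfg.get("simulate") or {}).items() if k != "preset"}
            preset = (cfg.get("simulate") or {}).get("preset")
            if preset:
                sim_kwargs = {**PRESETS[preset], **sim_kwargs}
            sim = SimConfig(seed=seed, **sim_kwargs)
            g, plots, truth_blues, truth = simulate_population(sim)
            save("genotypes.vcf", lambda p: io_qc.write_vcf(g, p))
            save("plots.csv", lambda p: plots.to_csv(p, index=False))
            save("truth_blues.csv", lambda p: truth_blues.to_csv(p))
        else:
            if cfg.get("genotypes"):
                g = io_qc.read_genotypes(cfg["genotypes"])
            if cfg.get("plots"):
                plots = pd.read_csv(cfg["plots"])
            if cfg.get("blues_csv"):
                blues = EnvBLUEs(values=pd.read_csv(cfg["blues_csv"], index_col=0))

        if "qc" in stages and g is not None:
            g = io_qc.het_to_missing(g)
            g, rep = io_qc.qc_filter(g, **cfg["qc"])
            save("qc_report.tsv", rep.to_tsv)
            save("genotypes_qc.csv", lambda p: io_qc.write_dosage_csv(g, p))

        blocks = []
        if "blocks" in stages and g is not None:
            blocks = ld_blocks.find_blocks(g, **cfg["blocks"])
            save("blocks.tsv", lambda p: ld_blocks.write_blocks(blocks, g, p))

        codings = list(cfg["features"]["codings"]) if "features" in stages else ["marker"]
        if not blocks:
            codings = ["marker"]
        kinships = {}
        if "kinship" in stages and g is not None:
            for coding in codings:
                if coding == "marker":
                    vs = build_variant_set(g, None, "marker")
                else:
                    k = {"hap_complete": 0, "hap_2snp": 2, "hap_3snp": 3}[coding]
                    frags = blocks if k == 0 else ld_blocks.segment_blocks(blocks, k, g)
                    h = filter_rare_alleles(
                        enumerate_haplotypes(g, frags), cfg["features"]["freq_min"]
                    )
                    vs = build_variant_set(g, h, coding)
                K = kinship.compute_K(vs)
                kinships[coding] = K
                save(f"kinship_{coding}.csv", K.to_csv)

        if "blues" in stages and blues is None and plots is not None:
            blues = stage1_all_envs(plots, tuple(cfg["blues"]["design"]))
            save("blues.csv", blues.to_csv)
            save(
                "repeatability.csv",
                lambda p: pd.Series(blues.repeatability, name="repeatability").to_csv(p),
            )

        if "cv" in stages and blues is not None and kinships:
            cvc = cfg["cv"]
            spec = ModelSpec(n_iter=int(cvc["n_iter"]), burn_in=int(cvc["burn_in"]))
            result = sparse_cv.run_cv(
                blues,
                kinships,
                models=tuple(cvc["models"]),
                missing_rates=tuple(cvc["missing_rates"]),
                cv_repeats=int(cvc["cv_repeats"]),
                mask_repeats=int(cvc["mask_repeats"]),
                n_folds=int(cvc["n_folds"]),
                spec=spec,
                seed=seed,
            )
            save("cv_results.csv", lambda p: result.records.to_csv(p, index=False))

        if "report" in stages and (out / "cv_results.csv").exists():
            report(out)
            manifest["artifacts"]["cv_summary.csv"] = _sha256(out / "cv_summary.csv")
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def report(run_dir: str | Path) -> pd.DataFrame:
    """Summaries and the accuracy-vs-missing-rate figure for a finished run."""
    run_dir = Path(run_dir)
    records = pd.read_csv(run_dir / "cv_results.csv")
    if records.empty:
        raise ValueError("empty CV results")
    cvres = sparse_cv.CVResult(records=records)
    summary = cvres.summary()

    # significance of each haplotype coding against the marker coding
    sig_rows = []
    for model in records["model"].unique():
        base = records[(records["model"] == model) & (records["coding"] == "marker")]
        for coding in records["coding"].unique():
            if coding == "marker" or base.empty:
                continue
            other = records[(records["model"] == model) & (records["coding"] == coding)]
            try:
                t, p = sparse_cv.compare_models(other, base)
            except ValueError:
                t, p = np.nan, np.nan
            sig_rows.append(
                {"model": model, "coding": coding, "t": t, "p": p,
                 "significant": bool(p < 0.05) if np.isfinite(p) else False}
            )
    comparison = pd.DataFrame(sig_rows)
    summary.to_csv(run_dir / "cv_summary.csv", index=False)
    comparison.to_csv(run_dir / "cv_comparison.csv", index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    width = 0.8 / max(summary.groupby(["model", "coding"]).ngroups, 1)
    for i, ((model, coding), grp) in enumerate(summary.groupby(["model", "coding"])):
        ax.bar(
            grp["missing_rate"] + i * width * 0.1,
            grp["accuracy_mean"],
            width=width * 0.09,
            yerr=grp["accuracy_sd"].fillna(0.0),
            label=f"{model}/{coding}",
            capsize=2,
        )
    ax.set_xlabel("training-set missing rate")
    ax.set_ylabel("prediction accuracy (Pearson r)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(run_dir / "accuracy_vs_missing_rate.png", dpi=120)
    plt.close(fig)
    return summary
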