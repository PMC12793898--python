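"""End-to-end orchestration of the monitoring / transplant analyses.

``run_full`` chains the stages in their analysis order —

    score -> diversity -> permanova (+permdisp) -> pcoa -> dbrda
          -> dapc -> plasticity -> fieldmetrics

— writing one TSV/JSON report per stage plus a reproducibility manifest
(config snapshot, input digests, seeds, per-stage row/locus counts).
A rerun over an existing output directory skips stages whose outputs
already exist under an identical config digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dapc_mod, epidiversity, msap_scoring, multivariate, plasticity, synthetic_data
from .errors import ConfigError, EpimsapError
from .peak_io import (
    read_fragment_matrix,
    read_metadata,
    read_peak_table,
    read_phenotypes,
    write_state_matrix,
)
from .types import SampleMetadata

log = logging.getLogger(__name__)

STAGES = ("score", "diversity", "permanova", "pcoa", "dbrda", "dapc", "plasticity", "fieldmetrics")

DEFAULT_CONFIG = {
    "seed": 0,
    "size_min": msap_scoring.SIZE_MIN,
    "size_max": msap_scoring.SIZE_MAX,
    "rfu_min": msap_scoring.RFU_MIN,
    "prevalence": msap_scoring.MIN_PREVALENCE,
    "meth_threshold": msap_scoring.METH_THRESHOLD,
    "encoding": "METH_BINARY",
    "metric": "EUCLIDEAN",
    "n_perm": 999,
    "dapc_percentile": 0.90,
    "pairing": "WITHIN_SITE_ACROSS_SEASON",
    "terms": ["site", "season"],
    "group_by": "site:season",
}


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full(config: str | Path | dict, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the output directory.

    ``config`` is a YAML path or an equivalent dict.  Inputs are either
    file paths (``peaks``/``fragments``, ``metadata``, ``phenotypes``)
    or a ``simulate`` block with a preset name (``monitoring`` or
    ``transplant``) and generator overrides.
    """
    cfg = load_config(config) if not isinstance(config, dict) else {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = _config_digest(cfg)

    manifest_path = outdir / "manifest.json"
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_digest": digest,
        "inputs": {},
        "stages": {},
    }
    # resume: an output directory produced under the identical config is
    # left untouched (stage outputs are written atomically at the end)
    if manifest_path.exists():
        prior = json.loads(manifest_path.read_text())
        if prior.get("config_digest") == digest and all(
            (outdir / name).exists()
            for name in ("states.csv", "permanova.tsv", "pcoa.tsv")
        ):
            log.info("outputs for config %s already present; skipping rerun", digest)
            return outdir

    seed = int(cfg["seed"])

    # ---- inputs ---------------------------------------------------------
    truth = None
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        preset = sim.pop("preset", "monitoring")
        sim_cfg = synthetic_data.SimConfig(seed=seed, **sim)
        design = (
            synthetic_data.monitoring_design() if preset == "monitoring"
            else synthetic_data.transplant_design() if preset == "transplant"
            else None
        )
        if design is None:
            raise ConfigError(f"unknown simulation preset {preset!r}")
        fm, truth = synthetic_data.gen_msap(sim_cfg, design)
        meta = truth.meta
        env = synthetic_data.gen_environment()
        pheno, _ = synthetic_data.gen_phenotypes(sim_cfg, meta, truth, env)
        (outdir / "truth.json").write_text(json.dumps(truth.manifest(), indent=2))
        manifest["inputs"]["simulate"] = {"preset": preset, "seed": seed}
    else:
        if "fragments" in cfg:
            fm = read_fragment_matrix(cfg["fragments"], cfg.get("fragments_msp"))
            manifest["inputs"]["fragments"] = _file_digest(Path(cfg["fragments"]))
        elif "peaks" in cfg:
            peaks = read_peak_table(cfg["peaks"], cfg.get("dialect"))
            manifest["inputs"]["peaks"] = _file_digest(Path(cfg["peaks"]))
            fm = msap_scoring.binarize_peaks(
                peaks, cfg["size_min"], cfg["size_max"], cfg["rfu_min"]
            )
        else:
            raise ConfigError("config must provide 'simulate', 'fragments' or 'peaks'")
        if "metadata" not in cfg:
            raise ConfigError("config missing 'metadata' input")
        meta = read_metadata(cfg["metadata"])
        manifest["inputs"]["metadata"] = _file_digest(Path(cfg["metadata"]))
        pheno = None
        if "phenotypes" in cfg:
            pheno = read_phenotypes(cfg["phenotypes"])
            manifest["inputs"]["phenotypes"] = _file_digest(Path(cfg["phenotypes"]))
        env = None

    # ---- score ----------------------------------------------------------
    fm = msap_scoring.filter_prevalence(fm, cfg["prevalence"])
    sm = msap_scoring.classify_states(fm)
    sm, report = msap_scoring.partition_msl(sm, cfg["meth_threshold"])
    write_state_matrix(sm, outdir / "states.csv")
    (outdir / "score.json").write_text(json.dumps(report.as_dict(), indent=2))
    manifest["stages"]["score"] = {"n_samples": sm.n_samples, **report.as_dict()}

    # ---- diversity ------------------------------------------------------
    div = epidiversity.shannon_per_locus(sm)
    freqs = epidiversity.state_frequencies(sm, meta, cfg["group_by"])
    freqs.to_csv(outdir / "state_frequencies.tsv", sep="\t", index=False)
    (outdir / "diversity.json").write_text(json.dumps(div.as_dict(), indent=2))
    manifest["stages"]["diversity"] = div.as_dict()

    # ---- distances / permanova -----------------------------------------
    x = msap_scoring.encode_matrix(sm, cfg["encoding"])
    d = multivariate.pairwise_distances(x, cfg["metric"], samples=sm.samples)
    terms = {t: meta.factor(t, sm.samples) for t in cfg["terms"]}
    perm = multivariate.permanova(d, terms, n_perm=cfg["n_perm"], seed=seed)
    perm.as_frame().to_csv(outdir / "permanova.tsv", sep="\t", index=False)
    disp_groups = meta.factor(cfg["terms"][-1], sm.samples)
    f_disp, p_disp = multivariate.permdisp(d, disp_groups, n_perm=cfg["n_perm"], seed=seed)
    (outdir / "permanova.json").write_text(json.dumps({
        "terms": {t.name: {"R2": t.R2, "F": t.F, "p": t.p} for t in perm.terms},
        "permdisp": {"F": f_disp, "p": p_disp},
    }, indent=2))
    manifest["stages"]["permanova"] = {t.name: t.R2 for t in perm.terms}

    # ---- pcoa -----------------------------------------------------------
    ordn = multivariate.pcoa(d)
    pd.DataFrame(
        ordn.coordinates, index=ordn.samples,
        columns=[f"PCo{i + 1}" for i in range(ordn.n_axes)],
    ).to_csv(outdir / "pcoa.tsv", sep="\t")
    manifest["stages"]["pcoa"] = {"n_axes": ordn.n_axes, "explained_1": float(ordn.explained[0])}

    # ---- dbrda ----------------------------------------------------------
    if pheno is not None:
        ph = pheno.aligned(sm.samples)
        predictors = pd.DataFrame({
            "log_righting": np.log1p(ph["righting_time"].to_numpy(float)),
            "log_diameter": np.log1p(ph["test_diameter"].to_numpy(float)),
        })
        db = multivariate.dbrda(d, predictors, n_perm=cfg["n_perm"], seed=seed)
        (outdir / "dbrda.json").write_text(json.dumps({
            "constrained_fraction": db.constrained_fraction,
            "p_overall": db.p_overall,
            "p_per_predictor": db.p_per_predictor,
        }, indent=2))
        manifest["stages"]["dbrda"] = {"constrained_fraction": db.constrained_fraction}

    # ---- dapc -----------------------------------------------------------
    groups = meta.factor(cfg["group_by"], sm.samples)
    k = len(pd.unique(groups))
    msl_names = [sm.loci[j] for j in sm.msl_indices()]
    dapc = dapc_mod.fit_dapc(
        x, groups, n_pc=k - 1, n_da=2,
        feature_names=msl_names if len(msl_names) == x.shape[1] else None,
        samples=sm.samples,
    )
    dapc.loadings.to_csv(outdir / "dapc_loadings.tsv", sep="\t")
    influential = dapc_mod.select_influential(dapc, cfg["dapc_percentile"])
    (outdir / "dapc_influential.txt").write_text("\n".join(influential) + "\n")
    manifest["stages"]["dapc"] = {"n_influential": len(influential), "n_pc": dapc.n_pc_retained}

    # ---- plasticity -----------------------------------------------------
    if pheno is not None:
        try:
            pc = plasticity.coupling(ordn, pheno, meta, pairing=cfg["pairing"])
            pc.pairs.to_csv(outdir / "plasticity_pairs.tsv", sep="\t", index=False)
            (outdir / "plasticity.json").write_text(json.dumps(pc.as_dict(), indent=2))
            manifest["stages"]["plasticity"] = pc.as_dict()
        except EpimsapError as exc:
            log.warning("plasticity stage skipped: %s", exc)

    # ---- fieldmetrics ---------------------------------------------------
    if env is not None:
        env.to_csv(outdir / "fieldmetrics.tsv", sep="\t", index=False)
        manifest["stages"]["fieldmetrics"] = {"n_sites": len(env)}

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
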