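"""End-to-end experiment orchestration on synthetic cohorts.

``run_experiment`` reproduces the evaluation design of the method on
phantoms: simulate an atlas cohort and a held-out test cohort, build the
atlas database, segment every test subject with both the multi-atlas and
the single-template method, and score the results three ways —

* per-structure Dice against the ground-truth labels,
* consistency ICC between pipeline SUVRs and truth-mask SUVRs per
  subregion,
* healthy-vs-parkinsonian group statistics (t, p, Cohen's d) per subregion.

Everything derives from one master seed; held-out test subjects always get
fresh seeds, never recycled atlas-cohort seeds. Outputs are TSV + JSON
stamped with the config hash and package version.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlasdb import AtlasBuildSettings, build_database
from .phantom import (
    ACCUMBENS,
    CAUDATE,
    PUTAMEN,
    PhantomSpec,
    default_spec,
    synthesize_subject,
)
from .quantify import suvr_table
from .segment import FusionParams, segment_multiatlas, segment_template_based
from .stats import compare_groups, dice_table, icc_consistency
from .subregions import SUBREGION_NAMES, build_subregions

log = logging.getLogger("striatseg")

DICE_REGIONS = {
    "accumbens": (ACCUMBENS,),
    "caudate": (CAUDATE,),
    "putamen": (PUTAMEN,),
    "striatum": (CAUDATE, PUTAMEN, ACCUMBENS),
}

_SPEC_DEFAULTS = PhantomSpec()

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {
        "shape": list(_SPEC_DEFAULTS.shape),
        "spacing": list(_SPEC_DEFAULTS.spacing),
        "psf_fwhm": _SPEC_DEFAULTS.psf_fwhm,
        "noise_sd": _SPEC_DEFAULTS.noise_sd,
        "uptake_jitter_sd": _SPEC_DEFAULTS.uptake_jitter_sd,
        "deform_amplitude": _SPEC_DEFAULTS.deform_amplitude,
    },
    "cohort": {"n_atlas_hc": 10, "n_atlas_pd": 10, "n_test_hc": 10, "n_test_pd": 10},
    "atlas": {
        "template_iterations": 2,
        "smooth_fwhm_mm": [3.7, 3.7, 6.6],
        "pvc_psf_fwhm_mm": 6.0,
        "pvc_alpha": 1.5,
        "pvc_max_iter": 10,
        "pvc_tol": 0.01,
        "n_quantiles": 256,
    },
    "selection": {"k1": 10, "k2": 5},
    "fusion": {"patch_radius": 2, "search_radius": 2, "beta": 2.0, "lam": 0.1},
    "quantify": {"bilateral": True},
    "stats": {"variance": "pooled"},
}


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"expected a mapping for {where}")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def validate_config(config: dict | None) -> dict:
    """Inject defaults, reject unknown keys, sanity-check value ranges."""
    cfg = _merge(DEFAULT_CONFIG, config or {})

    def _num(section, key, minimum=None, strict=False, integer=False):
        v = cfg[section][key]
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ConfigError(f"{section}.{key} must be a number, got {v!r}")
        if integer and int(v) != v:
            raise ConfigError(f"{section}.{key} must be an integer, got {v!r}")
        if minimum is not None and (v <= minimum if strict else v < minimum):
            op = ">" if strict else ">="
            raise ConfigError(f"{section}.{key} must be {op} {minimum}, got {v!r}")

    for key in ("n_atlas_hc", "n_atlas_pd", "n_test_hc", "n_test_pd"):
        _num("cohort", key, minimum=0, integer=True)
    _num("atlas", "pvc_alpha", minimum=0, strict=True)
    _num("atlas", "pvc_tol", minimum=0, strict=True)
    _num("atlas", "pvc_max_iter", minimum=0, integer=True)
    _num("atlas", "template_iterations", minimum=1, integer=True)
    _num("atlas", "n_quantiles", minimum=2, integer=True)
    _num("selection", "k1", minimum=1, integer=True)
    _num("selection", "k2", minimum=1, integer=True)
    _num("fusion", "patch_radius", minimum=0, integer=True)
    _num("fusion", "search_radius", minimum=0, integer=True)
    _num("fusion", "lam", minimum=0)
    for key in ("psf_fwhm", "noise_sd", "uptake_jitter_sd", "deform_amplitude"):
        _num("phantom", key, minimum=0)
    if cfg["selection"]["k2"] > cfg["selection"]["k1"]:
        raise ConfigError("selection.k2 must not exceed selection.k1")
    if cfg["stats"]["variance"] not in ("pooled", "welch"):
        raise ConfigError("stats.variance must be 'pooled' or 'welch'")
    if not isinstance(cfg["quantify"]["bilateral"], bool):
        raise ConfigError("quantify.bilateral must be a boolean")
    if len(cfg["phantom"]["shape"]) != 3:
        raise ConfigError("phantom.shape must have 3 entries")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _phantom_spec(cfg: dict) -> PhantomSpec:
    p = cfg["phantom"]
    return default_spec(
        shape=tuple(int(s) for s in p["shape"]),
        spacing=tuple(float(s) for s in p["spacing"]),
        psf_fwhm=float(p["psf_fwhm"]),
        noise_sd=float(p["noise_sd"]),
        uptake_jitter_sd=float(p["uptake_jitter_sd"]),
        deform_amplitude=float(p["deform_amplitude"]),
        seed=int(cfg["seed"]),
    )


def _cohorts(cfg: dict, spec: PhantomSpec):
    """Atlas and held-out test cohorts with disjoint seed streams."""
    c = cfg["cohort"]
    atlas_ss, test_ss = np.random.SeedSequence(int(cfg["seed"])).spawn(2)

    def _make(ss, n_hc, n_pd, tag):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_hc + n_pd)]
        subjects = []
        for i in range(n_hc):
            subjects.append(synthesize_subject(spec, "HC", seeds[i], f"{tag}_hc{i:02d}"))
        for i in range(n_pd):
            subjects.append(
                synthesize_subject(spec, "PD", seeds[n_hc + i], f"{tag}_pd{i:02d}")
            )
        return subjects

    atlas_cohort = _make(atlas_ss, c["n_atlas_hc"], c["n_atlas_pd"], "atlas")
    test_cohort = _make(test_ss, c["n_test_hc"], c["n_test_pd"], "test")
    return atlas_cohort, test_cohort


def run_experiment(config: dict | None = None, out_dir=None) -> dict:
    """Run the full synthetic evaluation; return (and optionally write) the report."""
    cfg = validate_config(config)
    spec = _phantom_spec(cfg)
    fusion = FusionParams(
        patch_radius=int(cfg["fusion"]["patch_radius"]),
        search_radius=int(cfg["fusion"]["search_radius"]),
        beta=float(cfg["fusion"]["beta"]),
        lam=float(cfg["fusion"]["lam"]),
    )
    atlas_settings = AtlasBuildSettings(
        template_iterations=int(cfg["atlas"]["template_iterations"]),
        smooth_fwhm_mm=tuple(cfg["atlas"]["smooth_fwhm_mm"]),
        pvc_psf_fwhm_mm=float(cfg["atlas"]["pvc_psf_fwhm_mm"]),
        pvc_alpha=float(cfg["atlas"]["pvc_alpha"]),
        pvc_max_iter=int(cfg["atlas"]["pvc_max_iter"]),
        pvc_tol=float(cfg["atlas"]["pvc_tol"]),
        n_quantiles=int(cfg["atlas"]["n_quantiles"]),
    )
    bilateral = bool(cfg["quantify"]["bilateral"])

    t0 = time.time()
    stage = "simulate"
    try:
        atlas_cohort, test_cohort = _cohorts(cfg, spec)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    log.info("simulated %d atlas + %d test subjects (%.1fs)",
             len(atlas_cohort), len(test_cohort), time.time() - t0)

    stage = "build-atlases"
    try:
        db = build_database(
            [(s.pet, s.truth, s.group) for s in atlas_cohort],
            atlas_settings,
            ids=[s.subject_id for s in atlas_cohort],
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    log.info("atlas database built (%.1fs elapsed)", time.time() - t0)

    dice_rows, suvr_frames, selections = [], [], {}
    for subj in test_cohort:
        sid = subj.subject_id
        try:
            stage = "register-target"
            from .registration import register

            tx = register(subj.pet, db.template, "deformable")
            stage = "segment-multiatlas"
            ma_labels, sel = segment_multiatlas(
                subj.pet, db, fusion,
                k1=int(cfg["selection"]["k1"]), k2=int(cfg["selection"]["k2"]),
                transform=tx,
            )
            selections[sid] = sel.to_jsonable()
            stage = "segment-template"
            tp_labels = segment_template_based(subj.pet, db, transform=tx)
            stage = "subregions"
            subregions = {
                "multiatlas": build_subregions(ma_labels),
                "template": build_subregions(tp_labels),
                "truth": build_subregions(subj.truth),
            }
            stage = "dice"
            for method, labels in (("multiatlas", ma_labels), ("template", tp_labels)):
                d = dice_table(labels, subj.truth, DICE_REGIONS)
                d.insert(0, "subject", sid)
                d.insert(1, "method", method)
                dice_rows.append(d)
            stage = "suvr"
            for method, sub in subregions.items():
                suvr_frames.append(
                    suvr_table(subj.pet, sub, bilateral=bilateral,
                               subject=sid, method=method)
                )
        except Exception as exc:
            raise PipelineError(f"stage {stage}, subject {sid}: {exc}") from exc
        log.info("segmented %s (%.1fs elapsed)", sid, time.time() - t0)

    dice_df = pd.concat(dice_rows, ignore_index=True)
    suvr_df = pd.concat(suvr_frames, ignore_index=True)

    stage = "evaluate"
    try:
        icc_rows = []
        wide = suvr_df.pivot_table(
            index=["subject", "region"], columns="method", values="suvr"
        ).reset_index()
        for region in SUBREGION_NAMES:
            sub = wide[wide["region"] == region]
            for method in ("multiatlas", "template"):
                icc_rows.append(
                    dict(region=region, method=method,
                         icc=icc_consistency(zip(sub[method], sub["truth"])))
                )
        icc_df = pd.DataFrame(icc_rows)
        group_map = {s.subject_id: s.group for s in test_cohort}
        groups = compare_groups(
            suvr_df[suvr_df["method"] == "multiatlas"], group_map,
            variance=cfg["stats"]["variance"],
        ).table
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    mean_dice = (
        dice_df.groupby(["method", "region"], sort=True)["dice"].mean().reset_index()
    )
    report = {
        "version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "n_atlases": len(db.atlases),
        "mean_dice": {
            f"{r['method']}:{r['region']}": float(r["dice"])
            for _, r in mean_dice.iterrows()
        },
        "icc": {f"{r['method']}:{r['region']}": float(r["icc"]) for _, r in icc_df.iterrows()},
        "selections": selections,
        "elapsed_s": round(time.time() - t0, 1),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stamp = {"version": __version__, "config_hash": report["config_hash"]}
        for name, df in (("dice", dice_df), ("suvr", suvr_df),
                         ("icc", icc_df), ("group_stats", groups)):
            df = df.copy()
            for key, value in stamp.items():
                df[key] = value
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    report["dice_table"] = dice_df
    report["suvr_table"] = suvr_df
    report["icc_table"] = icc_df
    report["group_stats"] = groups
    return report
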