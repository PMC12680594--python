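"""End-to-end orchestration: phantom cohort studies and controller studies.

Binds the generator, morphometry, drug quantification and statistics stages
into reproducible runs driven by one structured configuration, and records a
run manifest (config hash, seeds, inputs, outputs, stage timings) so a rerun
with the same configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import drugmap, fuscontrol, statkit, synthgen, vesselmap

__all__ = [
    "RunManifest",
    "load_config",
    "analyze_phantom",
    "run_phantom_study",
    "run_controller_study",
    "DEFAULT_PHANTOM_CONFIG",
    "DEFAULT_CONTROLLER_CONFIG",
]

log = logging.getLogger("fusvasc")

DEFAULT_PHANTOM_CONFIG: dict[str, Any] = {
    "tissues": ["GM", "WM"],
    "conditions": ["TTX1"],
    "drugs": ["BVZ"],
    "replicates": 1,
    "seed": 0,
    "shape": [32, 96, 96],
    "spacing_um": [2.0, 1.0, 1.0],
    "noise_sd": 3.0,
    "psf_sigma_um": 0.5,
    "mode": "2d",
    "save_volumes": False,
}

DEFAULT_CONTROLLER_CONFIG: dict[str, Any] = {
    "grid": [3, 3],
    "event_model": "none",
    "seed": 0,
    "noise_sd": 1.0,
}


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config_hash: str
    seeds: list[int]
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True)
        )


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, skimage

    from . import __version__

    return {
        "fusvasc": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
    }


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML (or JSON) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def _validate_phantom_config(config: Mapping[str, Any]) -> dict[str, Any]:
    cfg = {**DEFAULT_PHANTOM_CONFIG, **dict(config)}
    for t in cfg["tissues"]:
        preset = synthgen.get_preset(t)  # raises for unknown tissue
        for cond in cfg["conditions"]:
            if cond not in synthgen.CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            for drug in cfg["drugs"]:
                if drug not in synthgen.DRUGS:
                    raise ValueError(f"unknown drug {drug!r}")
                if (cond, drug) not in preset.enhancement_factor:
                    raise ValueError(
                        f"preset {t!r} does not define condition/drug "
                        f"({cond}, {drug})"
                    )
    if int(cfg["replicates"]) < 1:
        raise ValueError("replicates must be >= 1")
    return cfg


def analyze_phantom(
    tissue: str,
    condition: str,
    drug: str,
    seed: int,
    shape=(32, 96, 96),
    spacing_um=(2.0, 1.0, 1.0),
    noise_sd: float = 3.0,
    psf_sigma_um: float = 0.5,
    mode: str = "2d",
    return_volumes: bool = False,
) -> dict[str, Any]:
    """Generate one phantom and run the full vessel + drug quantification.

    Returns the scalar morphometry (density, inter-vessel distance), the
    stratified fold-change table, the extravasation summary and per-class
    attribution for a single (tissue, condition, drug, seed) cell.
    """
    preset = synthgen.get_preset(tissue)
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing_um)
    box = tuple((n - 1) * s for n, s in zip(shape, spacing))

    network = synthgen.generate_vessel_network(preset, box, seed=seed)
    lumen_true = synthgen.rasterize_vessels(network, shape, spacing)
    vascular = synthgen.render_vascular_channel(
        lumen_true, preset, psf_sigma_um=psf_sigma_um,
        noise_sd=noise_sd, seed=seed + 1,
    )
    drug_img = synthgen.render_drug_channel(
        lumen_true, network, preset, condition, drug,
        seed=seed + 2, noise_sd=noise_sd, psf_sigma_um=psf_sigma_um,
    )
    tissue_mask = np.ones(shape, dtype=bool)

    # vascular morphometry
    pre = vesselmap.preprocess_vascular(vascular)
    lumen = vesselmap.segment_vessels(pre)
    lumen_bool = lumen.voxels.astype(bool)
    diam = vesselmap.estimate_diameters(lumen, spacing)
    classes = vesselmap.classify_vessels(diam)
    density = vesselmap.vascular_density(lumen, tissue_mask)
    dist_um, ivd_um = vesselmap.intervessel_distance_map(
        lumen, tissue_mask, spacing
    )
    comp = vesselmap.compartmentalize(dist_um, diam, ivd_um, tissue_mask)

    # drug quantification
    drug_pre = drugmap.preprocess_drug(drug_img)
    thr, flat = drugmap.tissue_threshold(drug_pre, tissue_mask, tissue=tissue)
    signal = flat.voxels > thr.threshold_value
    # per-voxel vessel class of the nearest segment, for stratified tables
    cls_lut = classes.set_index("segment_id")["vessel_class"]
    seg_of = _nearest_segment_labels(diam)
    voxel_class = np.full(shape, "", dtype=object)
    known = seg_of > 0
    voxel_class[known] = cls_lut.reindex(seg_of[known]).fillna("").to_numpy()
    quant = drugmap.fold_change(
        drug_pre, signal, tissue_mask, thr.background_mean,
        compartments=comp, voxel_class=voxel_class,
    )
    extrav = drugmap.extravasation_distance(
        signal, lumen_bool, tissue_mask, spacing,
        cap_um=0.5 * ivd_um, mode=mode,
    )
    per_class = drugmap.attribute_to_vessel_class(
        extrav["coords"], extrav["distances_um"], diam, classes
    )

    result: dict[str, Any] = {
        "tissue": tissue,
        "condition": condition,
        "drug": drug,
        "seed": seed,
        "density": density,
        "intervessel_distance_um": ivd_um,
        "mean_diameter_um": float(classes["diameter_um"].mean()),
        "n_segments": int(len(classes)),
        "fold_change_all": float(
            quant.loc[quant["compartment"] == "all", "fold_change"].iloc[0]
        ),
        "extravasation_mean_um": extrav["mean_um"],
        "extravasation_n": extrav["n"],
        "threshold": thr,
        "quant": quant,
        "per_class": per_class,
        "audit": synthgen.audit_network(network, preset),
    }
    if return_volumes:
        result["volumes"] = {
            "lumen_true": lumen_true,
            "vascular": vascular,
            "drug": drug_img,
            "lumen": lumen,
        }
    return result


def _nearest_segment_labels(diam: vesselmap.DiameterMap) -> np.ndarray:
    from scipy import ndimage

    lumen = diam.segment_labels > 0
    if not lumen.any():
        return np.zeros_like(diam.segment_labels)
    _, idx = ndimage.distance_transform_edt(
        ~lumen, sampling=diam.spacing_um, return_indices=True
    )
    return diam.segment_labels[tuple(idx)]


def run_phantom_study(
    config: Mapping[str, Any], out_dir: str | Path
) -> Path:
    """Run the phantom cohort study described by ``config``.

    Generates one phantom per (tissue, condition, drug, replicate) cell,
    runs the morphometry and drug pipelines, writes the tidy quantification
    table, per-stratum fold changes, group statistics and the run manifest.
    """
    cfg = _validate_phantom_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(cfg), seeds=[], versions=_versions()
    )
    t0 = time.perf_counter()

    rows = []
    strata_tables = []
    cell = 0
    for tissue in cfg["tissues"]:
        for cond in cfg["conditions"]:
            for drug in cfg["drugs"]:
                for rep in range(int(cfg["replicates"])):
                    seed = int(cfg["seed"]) + 1000 * cell + rep * 10
                    manifest.seeds.append(seed)
                    t_cell = time.perf_counter()
                    res = analyze_phantom(
                        tissue, cond, drug, seed,
                        shape=cfg["shape"],
                        spacing_um=cfg["spacing_um"],
                        noise_sd=cfg["noise_sd"],
                        psf_sigma_um=cfg["psf_sigma_um"],
                        mode=cfg["mode"],
                    )
                    log.info(
                        "cell %s/%s/%s rep %d seed %d: density=%.4f "
                        "ivd=%.1fum fc=%.2f extrav=%.1fum (%.1fs)",
                        tissue, cond, drug, rep, seed, res["density"],
                        res["intervessel_distance_um"],
                        res["fold_change_all"],
                        res["extravasation_mean_um"],
                        time.perf_counter() - t_cell,
                    )
                    rows.append(
                        {
                            "tissue": tissue,
                            "condition": cond,
                            "drug": drug,
                            "replicate": rep,
                            "seed": seed,
                            "density": res["density"],
                            "intervessel_distance_um": res[
                                "intervessel_distance_um"
                            ],
                            "mean_diameter_um": res["mean_diameter_um"],
                            "n_segments": res["n_segments"],
                            "fold_change": res["fold_change_all"],
                            "extravasation_mean_um": res[
                                "extravasation_mean_um"
                            ],
                        }
                    )
                    strata = res["quant"].copy()
                    strata.insert(0, "tissue", tissue)
                    strata.insert(1, "condition", cond)
                    strata.insert(2, "drug", drug)
                    strata.insert(3, "replicate", rep)
                    strata_tables.append(strata)
                cell += 1

    quant = pd.DataFrame(rows)
    quant_path = out / "quant_table.csv"
    quant.to_csv(quant_path, index=False)
    strata = pd.concat(strata_tables, ignore_index=True)
    strata_path = out / "fold_change_strata.csv"
    strata.to_csv(strata_path, index=False)
    manifest.outputs += [str(quant_path), str(strata_path)]

    stats_path = out / "group_stats.csv"
    stats_df = _study_statistics(quant)
    stats_df.to_csv(stats_path, index=False)
    manifest.outputs.append(str(stats_path))

    manifest.timings_s["total"] = round(time.perf_counter() - t0, 3)
    manifest_path = out / "manifest.json"
    manifest.outputs.append(str(manifest_path))
    manifest.save(manifest_path)
    return out


def _study_statistics(quant: pd.DataFrame) -> pd.DataFrame:
    """Between-tissue comparisons of the study table, BH-adjusted."""
    rows = []
    tissues = sorted(quant["tissue"].unique())
    for metric in ("fold_change", "extravasation_mean_um", "density"):
        for i, a in enumerate(tissues):
            for b in tissues[i + 1 :]:
                xa = quant.loc[quant["tissue"] == a, metric].to_numpy()
                xb = quant.loc[quant["tissue"] == b, metric].to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    continue
                try:
                    res = statkit.compare_groups(
                        [xa, xb], "independent-factorial"
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "metric": metric,
                        "group_a": a,
                        "group_b": b,
                        "test": res.test_name,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["metric", "group_a", "group_b", "test", "statistic", "p_value"],
    )
    if len(df):
        decisions, thr = statkit.bh_adjust(df["p_value"].to_numpy(), q=0.05)
        df["significant"] = decisions
        df["bh_threshold"] = thr
    return df


def run_controller_study(
    config: Mapping[str, Any], out_dir: str | Path
) -> Path:
    """Simulate a controller treatment described by ``config`` and write
    the per-pulse series, summaries and manifest."""
    cfg = {**DEFAULT_CONTROLLER_CONFIG, **dict(config)}
    ctrl_keys = {
        f.name for f in fuscontrol.ControllerConfig.__dataclass_fields__.values()
    }
    ctrl_cfg = fuscontrol.ControllerConfig(
        **{
            k: (tuple(v) if k == "grid" else v)
            for k, v in cfg.items()
            if k in ctrl_keys
        }
    )
    model = cfg["event_model"]
    if isinstance(model, list):
        model = tuple(model) if model and model[0] != "none" else "none"
        if isinstance(model, tuple) and len(model) == 1:
            model = model[0]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seeds=[int(cfg["seed"])],
        versions=_versions(),
    )
    t0 = time.perf_counter()
    series, schedule = fuscontrol.simulate_treatment(
        ctrl_cfg, model, seed=int(cfg["seed"]), noise_sd=float(cfg["noise_sd"])
    )
    sched_path = out / "pressure_series.csv"
    schedule.to_csv(sched_path, index=False)
    summaries = [s.summary(ctrl_cfg) for s in series]
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summaries, indent=2, sort_keys=True))
    manifest.outputs += [str(sched_path), str(summary_path)]
    manifest.timings_s["total"] = round(time.perf_counter() - t0, 3)
    manifest_path = out / "manifest.json"
    manifest.outputs.append(str(manifest_path))
    manifest.save(manifest_path)
    return out
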