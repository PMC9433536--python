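"""End-to-end pipeline: simulate -> preprocess -> kinematics -> activation ->
connectivity -> network metrics -> group statistics.

Every stage reads only the artifacts written by earlier stages into the run
directory and writes its own, so a run can be restarted at any stage.  A
manifest records per-stage wall time and SHA-256 hashes of inputs, outputs
and the effective configuration; rerunning with the same config and inputs
reproduces identical CSV outputs.
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
import yaml

from . import io as nio
from .connectivity import BandSpec, LF_BAND, HF_BAND, condition_networks
from .glm import activation_integral, build_design, fit_glm
from .kinematics import metrics_table
from .netmetrics import compute_metrics
from .preprocess import preprocess_recording
from .stats import anova_factorial, channel_activation_tests, correlate, paired_t
from .synthetic_data import (
    CohortDesign,
    condition_hands,
    default_effect_spec,
    gen_cohort,
    is_bilateral,
    is_in_phase,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "n_subjects": 21,
        "n_blocks_per_condition": 10,
        "task_duration_s": 12.0,
        "rest_duration_s": 15.0,
        "nirs_rate_hz": 11.0,
        "traj_rate_hz": 28.5,
        "n_channels": 30,
    },
    "effects": {
        "amplitude": 0.5,
        "radius_noise_sd": 0.05,
        "angvel_noise_sd": 0.1,
        "left_hand_noise_scale": 1.4,
        "rpfc_coupling_ip": 0.8,
        "rpfc_coupling_ap": 0.3,
        "noise_sd": 0.1,
        "artifact_rate": 1.0,
    },
    "cohort": {
        "subject_jitter_frac": 0.1,
        "bias_subject_sd": 0.0,
        "activation_bias_coupling": 0.0,
    },
    "preprocess": {
        "dpf": 6.0,
        "distance_mm": 30.0,
        "window": 10,
        "threshold": 5.0,
        "pad_s": 0.5,
        "bandpass": [0.021, 0.6],
        "bandstop": [0.08, 0.12],
    },
    "kinematics": {"trim_s": 0.5},
    "connectivity": {"band": "LF", "n_freqs": 20, "omega0": 6.0, "amplitude_weighted": False},
    "metrics": {"sigma_nulls": 0},
    "stats": {"fdr_q": 0.05},
}


def validate_config(cfg: dict, defaults: dict | None = None, path: str = "") -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    defaults = DEFAULT_CONFIG if defaults is None else defaults
    merged = copy.deepcopy(defaults)
    for key, value in cfg.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path + key!r}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise ValueError(f"config key {path + key!r} must be a mapping")
        if isinstance(defaults[key], dict):
            merged[key] = validate_config(value, defaults[key], path + key + ".")
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the defaults (defaults if path is None)."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path, cfg: dict):
        self.path = run_dir / "manifest.json"
        self.data = {"config_hash": _config_hash(cfg), "stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            self.data["config_hash"] = _config_hash(cfg)

    def record(self, stage: str, inputs: list[Path], outputs: list[Path], wall_s: float,
               status: str = "complete"):
        self.data["stages"][stage] = {
            "status": status,
            "wall_s": round(wall_s, 3),
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def _design_from_cfg(cfg: dict) -> CohortDesign:
    return CohortDesign(seed=cfg["seed"], **cfg["design"])


def _subject_paths(folder: Path, pattern: str = "sub-*.csv") -> list[Path]:
    return sorted(p for p in folder.glob(pattern) if not p.name.endswith("_artifacts.csv"))


def stage_simulate(cfg: dict, run_dir: Path) -> list[Path]:
    design = _design_from_cfg(cfg)
    eff = dict(cfg["effects"])
    spec = default_effect_spec(
        design,
        n_channels=cfg["design"]["n_channels"],
        amplitude=eff.pop("amplitude"),
        radius_noise_sd=eff.pop("radius_noise_sd"),
        angvel_noise_sd=eff.pop("angvel_noise_sd"),
        left_hand_noise_scale=eff.pop("left_hand_noise_scale"),
        rpfc_coupling_ip=eff.pop("rpfc_coupling_ip"),
        rpfc_coupling_ap=eff.pop("rpfc_coupling_ap"),
        **eff,
    )
    cohort = gen_cohort(design, spec, **cfg["cohort"],
                        left_hand_noise_scale=cfg["effects"]["left_hand_noise_scale"])
    raw = run_dir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    outputs = []
    all_traces = []
    for sub in cohort.subjects:
        outputs.append(nio.write_recording(sub.recording, raw / f"sub-{sub.subject:02d}.csv"))
        all_traces.extend(sub.trajectories)
    if all_traces:
        outputs.append(nio.write_trajectories(all_traces, raw / "trajectories.csv"))
    gt_path = raw / "ground_truth.csv"
    cohort.ground_truth.to_csv(gt_path, index=False)
    outputs.append(gt_path)
    return outputs


def stage_preprocess(cfg: dict, run_dir: Path) -> list[Path]:
    raw = run_dir / "raw"
    clean = run_dir / "clean"
    clean.mkdir(parents=True, exist_ok=True)
    pc = cfg["preprocess"]
    outputs = []
    for path in _subject_paths(raw):
        rec = nio.read_recording(path)
        h, mask = preprocess_recording(
            rec, dpf=pc["dpf"], distance_mm=pc["distance_mm"], window=pc["window"],
            threshold=pc["threshold"], pad_s=pc["pad_s"],
            bandpass=tuple(pc["bandpass"]),
            bandstop=tuple(pc["bandstop"]) if pc["bandstop"] else None,
        )
        outputs.append(nio.write_hemoglobin(h, clean / path.name))
        outputs.append(nio.write_artifact_mask(mask, clean / f"{path.stem}_artifacts.tsv"))
    return outputs


def stage_kinematics(cfg: dict, run_dir: Path) -> list[Path]:
    traces = nio.read_trajectories(run_dir / "raw" / "trajectories.csv")
    table = metrics_table(traces, trim_s=cfg["kinematics"]["trim_s"])
    out = run_dir / "kinematics.csv"
    table.to_csv(out, index=False)
    return [out]


def stage_activation(cfg: dict, run_dir: Path) -> list[Path]:
    clean = run_dir / "clean"
    frames = []
    for path in _subject_paths(clean):
        h = nio.read_hemoglobin(path)
        design = build_design(h.events, h.t)
        res = fit_glm(h, design)
        integ, conds = activation_integral(h)
        order = [conds.index(c) for c in res.conditions]
        res.activation_integral = integ[:, order]
        df = res.to_frame(h.channel_regions)
        df.insert(0, "subject", int(path.stem.split("-")[1]))
        frames.append(df)
    out = run_dir / "activation.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return [out]


def _band_from_cfg(cc: dict) -> BandSpec:
    base = {"LF": LF_BAND, "HF": HF_BAND}[cc["band"]]
    return BandSpec(base.name, base.f_lo, base.f_hi, cc["n_freqs"])


def stage_connectivity(cfg: dict, run_dir: Path) -> list[Path]:
    clean = run_dir / "clean"
    netdir = run_dir / "networks"
    netdir.mkdir(parents=True, exist_ok=True)
    cc = cfg["connectivity"]
    band = _band_from_cfg(cc)
    outputs = []
    index_rows = []
    regions_path = netdir / "channel_regions.json"
    for path in _subject_paths(clean):
        h = nio.read_hemoglobin(path)
        if not regions_path.exists():
            regions_path.write_text(json.dumps(h.channel_regions))
            outputs.append(regions_path)
        nets = condition_networks(h, band=band, omega0=cc["omega0"],
                                  amplitude_weighted=cc["amplitude_weighted"])
        subject = int(path.stem.split("-")[1])
        for cond, net in nets.items():
            plv_path = netdir / f"{path.stem}_{cond}_plv.tsv"
            edge_path = netdir / f"{path.stem}_{cond}_edges.tsv"
            outputs.append(nio.write_plv_matrix(net, plv_path))
            outputs.append(nio.write_adjacency(net, edge_path))
            index_rows.append(dict(subject=subject, condition=cond,
                                   threshold=net.threshold,
                                   n_edges=int(net.adjacency.sum() // 2),
                                   plv=plv_path.name, edges=edge_path.name))
    idx_path = netdir / "index.csv"
    pd.DataFrame(index_rows).to_csv(idx_path, index=False)
    outputs.append(idx_path)
    return outputs


def stage_metrics(cfg: dict, run_dir: Path) -> list[Path]:
    netdir = run_dir / "networks"
    index = pd.read_csv(netdir / "index.csv")
    regions = json.loads((netdir / "channel_regions.json").read_text())
    frames = []
    for _, row in index.iterrows():
        plv = nio.read_plv_matrix(netdir / row["plv"])
        edges = pd.read_csv(netdir / row["edges"], sep="\t")
        adj = np.zeros(plv.shape, dtype=bool)
        adj[edges["node_i"], edges["node_j"]] = True
        adj |= adj.T
        ms = compute_metrics(adj, channel_regions=regions,
                             sigma_nulls=cfg["metrics"]["sigma_nulls"], seed=cfg["seed"])
        df = ms.to_frame()
        df.insert(0, "condition", row["condition"])
        df.insert(0, "subject", row["subject"])
        df.insert(2, "band", cfg["connectivity"]["band"])
        frames.append(df)
    out = run_dir / "network_metrics.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return [out]


def _kin_factors(kin: pd.DataFrame) -> pd.DataFrame:
    """Subject x condition x hand means with handedness/orientation/phase factors."""
    direction = {}
    for cond in kin["condition"].unique():
        for hand, d in condition_hands(cond):
            direction[(cond, hand)] = d
    agg = (kin.groupby(["subject", "condition", "hand"], sort=False)
              [["sdr", "re", "sdav", "ave"]].mean().reset_index())
    agg["orientation"] = [direction[(c, h)] for c, h in zip(agg["condition"], agg["hand"])]
    agg["bilateral"] = [is_bilateral(c) for c in agg["condition"]]
    agg["phase"] = [("IP" if is_in_phase(c) else "AP") if is_bilateral(c) else "NA"
                    for c in agg["condition"]]
    return agg


def stage_stats(cfg: dict, run_dir: Path) -> list[Path]:
    statdir = run_dir / "stats"
    statdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    summary: list[str] = []

    kin = pd.read_csv(run_dir / "kinematics.csv")
    agg = _kin_factors(kin)
    anova_rows = []
    for metric in ("sdr", "re", "sdav", "ave"):
        uni = agg[~agg["bilateral"]]
        if uni["hand"].nunique() > 1 and uni["orientation"].nunique() > 1:
            res = anova_factorial(uni, metric, ["hand", "orientation"])
            res.insert(0, "metric", metric)
            res.insert(0, "analysis", "unilateral_2way")
            anova_rows.append(res)
        bil = agg[agg["bilateral"]]
        if len(bil) and bil["phase"].nunique() > 1:
            res = anova_factorial(bil, metric, ["hand", "orientation", "phase"])
            res.insert(0, "metric", metric)
            res.insert(0, "analysis", "bilateral_3way")
            anova_rows.append(res)
    if anova_rows:
        anova_df = pd.concat(anova_rows, ignore_index=True)
        p = statdir / "kinematics_anova.csv"
        anova_df.to_csv(p, index=False)
        outputs.append(p)
        for _, r in anova_df[anova_df["p"] < 0.05].iterrows():
            summary.append(f"ANOVA {r['analysis']} {r['metric']}: {r['effect']} "
                           f"F={r['F']:.2f} p={r['p']:.4g}")

    act_path = run_dir / "activation.csv"
    act = pd.read_csv(act_path) if act_path.exists() else None
    if act is not None:
        tests = channel_activation_tests(act, q=cfg["stats"]["fdr_q"])
        p = statdir / "activation_tests.csv"
        tests.to_csv(p, index=False)
        outputs.append(p)
        n_sig = int(tests["significant"].sum())
        summary.append(f"activation: {n_sig} significant channel x condition cells after FDR")

    net_path = run_dir / "network_metrics.csv"
    if net_path.exists():
        net = pd.read_csv(net_path)
        paired_rows = []
        bilateral_conds = [c for c in net["condition"].unique() if is_bilateral(c)]
        ip = [c for c in bilateral_conds if is_in_phase(c)]
        ap = [c for c in bilateral_conds if not is_in_phase(c)]
        if ip and ap:
            def subj_mean(scope, name, conds, region=None):
                sel = net[(net["scope"] == scope) & (net["name"] == name)
                          & net["condition"].isin(conds)]
                if region is not None:
                    sel = sel[sel["region"] == region]
                return sel.groupby("subject")["value"].mean()

            targets = [("global", "global_efficiency", None),
                       ("global", "clustering_coefficient", None)]
            for reg in ("RPFC", "RMC"):
                targets += [("region", "clustering_coefficient", reg),
                            ("region", "node_efficiency", reg),
                            ("region", "node_local_efficiency", reg)]
            for scope, name, region in targets:
                x = subj_mean(scope, name, ip, region)
                y = subj_mean(scope, name, ap, region)
                common = x.index.intersection(y.index)
                if len(common) >= 2:
                    rep = paired_t(x.loc[common].to_numpy(), y.loc[common].to_numpy())
                    paired_rows.append(dict(scope=scope, name=name, region=region,
                                            t=rep.statistic, dof=rep.dof, p=rep.p,
                                            direction=rep.effect_direction, n=rep.n))
        if paired_rows:
            pr = pd.DataFrame(paired_rows)
            p = statdir / "network_paired.csv"
            pr.to_csv(p, index=False)
            outputs.append(p)
            for _, r in pr[pr["p"] < 0.05].iterrows():
                summary.append(f"paired IP-vs-AP {r['name']} ({r['region'] or 'global'}): "
                               f"t={r['t']:.2f} p={r['p']:.4g} ({r['direction']})")

        # pooled correlations: kinematics vs activation and vs network metrics
        corr_rows = []
        kin_sc = (agg.groupby(["subject", "condition"])[["sdr", "re"]].mean().reset_index())
        if act is not None:
            mc = act[act["region"].isin(["LMC", "RMC"])]
            act_sc = (mc.groupby(["subject", "condition"])["integral"].mean()
                        .reset_index(name="mc_integral"))
            m = kin_sc.merge(act_sc, on=["subject", "condition"])
            if len(m) >= 3 and m["mc_integral"].std() > 0 and m["re"].std() > 0:
                r, pv = correlate(m["mc_integral"].to_numpy(), m["re"].to_numpy())
                corr_rows.append(dict(x="mc_activation_integral", y="radius_error",
                                      r=r, p=pv, n=len(m)))
        for reg, kmetric in (("RMC", "sdr"), ("RPFC", "re")):
            for name in ("clustering_coefficient", "node_efficiency", "node_local_efficiency"):
                sel = net[(net["scope"] == "region") & (net["name"] == name)
                          & (net["region"] == reg)]
                nm = sel.groupby(["subject", "condition"])["value"].mean().reset_index()
                m = kin_sc.merge(nm, on=["subject", "condition"])
                if len(m) >= 3 and m["value"].std() > 0 and m[kmetric].std() > 0:
                    r, pv = correlate(m["value"].to_numpy(), m[kmetric].to_numpy())
                    corr_rows.append(dict(x=f"{reg}_{name}", y=kmetric, r=r, p=pv, n=len(m)))
        if corr_rows:
            cr = pd.DataFrame(corr_rows)
            p = statdir / "correlations.csv"
            cr.to_csv(p, index=False)
            outputs.append(p)
            for _, r in cr.iterrows():
                summary.append(f"corr {r['x']} vs {r['y']}: r={r['r']:.3f} p={r['p']:.4g} n={r['n']}")

    sp = statdir / "summary.txt"
    sp.write_text("\n".join(summary) + "\n")
    outputs.append(sp)
    return outputs


STAGES: dict = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "kinematics": stage_kinematics,
    "activation": stage_activation,
    "connectivity": stage_connectivity,
    "metrics": stage_metrics,
    "stats": stage_stats,
}


def run_pipeline(cfg: dict, run_dir: str | Path, stages: list[str] | None = None) -> Path:
    """Run the requested stages (all by default) into ``run_dir``.

    The effective config is written next to the outputs; a failing stage
    aborts with its name while earlier artifacts are retained and the
    manifest marks the failure.
    """
    cfg = validate_config(cfg)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    manifest = _Manifest(run_dir, cfg)
    stages = list(STAGES) if stages is None else stages
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    for name in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            outputs = STAGES[name](cfg, run_dir)
        except Exception:
            manifest.record(name, [], [], time.perf_counter() - t0, status="failed")
            logger.exception("stage %s failed; partial artifacts retained", name)
            raise
        manifest.record(name, [], outputs, time.perf_counter() - t0)
        logger.info("stage %s: %d artifact(s) in %.1f s", name, len(outputs),
                    time.perf_counter() - t0)
    return run_dir
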