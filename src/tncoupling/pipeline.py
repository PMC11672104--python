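"""End-to-end orchestration: synthetic bundles -> study-shaped report.

The pipeline replays the three-tier recoupling study on synthetic data
whose planted statistics are the shipped reference conditions:

* trajectory tier - per troponin variant x ligand x phosphorylation
  state, generate trajectories realizing the condition's helix A/B
  angle, hinge angle, interdomain distance, salt-bridge occupancy and
  ligand attachment; re-measure them with the geometry/contact
  modules; summarize, difference P vs uP and classify recoupling
  against the wild-type response.
* motility tier - generate paired P/unP Ca2+-activation curves at the
  condition's EC50s, refit, and make the coupling call from the EC50
  ratio.
* myocyte tier - generate paired baseline/dobutamine shortening
  records at the condition's lusitropy, re-extract beat features and
  test the paired response.

Every threshold lives in :class:`RunConfig`; the report carries the
package version and a hash of the analysis-relevant configuration, and
is deterministic given (config, seed).  Externally computed MMPBSA
binding energies are echoed into the attachment table, never computed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import attachment as run_attachment
from .diststats import DistributionSummary, classify_recoupling, delta, summarize
from .geometry import (
    ab_angle_series,
    hinge_angle_series,
    interdomain_distance_series,
    pair_bond_occupancy,
)
from .motility import coupling_call, fit_hill
from .refdata import load_table
from .synthetic import (
    CurveSpec,
    GaussianMixture1D,
    LigandSpec,
    TrajectorySpec,
    TransientSpec,
    gen_activation_curves,
    gen_paired_transients,
    gen_trajectory,
)
from .transients import lusitropy as lusitropy_fn
from .transients import paired_response, trace_features

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "cross_level_summary"]

_ANALYSIS_FIELDS = (
    "contact_cutoff_a",
    "saltbridge_cutoff_a",
    "open_state_threshold_deg",
    "hotspot_threshold",
    "coupling_ratio_threshold",
    "dead_band_angle_deg",
    "dead_band_distance_a",
    "dead_band_pct",
    "n_frames",
    "n_runs",
    "n_cells",
    "curve_noise_sd",
    "curve_replicates",
    "seed",
    "stages",
)


@dataclass
class RunConfig:
    """Thresholds, problem sizes and stage selection for one pipeline run."""

    contact_cutoff_a: float = 2.5
    saltbridge_cutoff_a: float = 4.0
    open_state_threshold_deg: float = 110.0
    hotspot_threshold: float = 0.10
    coupling_ratio_threshold: float = 1.5
    dead_band_angle_deg: float = 0.5
    dead_band_distance_a: float = 0.25
    dead_band_pct: float = 1.0
    # synthetic problem sizes for report assembly (the generators' own
    # defaults, 5 x 3750 frames, remain available per condition)
    n_frames: int = 1500
    n_runs: int = 2
    n_cells: int = 12
    curve_noise_sd: float = 0.03
    curve_replicates: int = 3
    seed: int = 0
    stages: tuple = ("trajectory", "motility", "myocyte")
    mmpbsa_csv: Optional[str] = None   # optional external binding-energy side input
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("contact_cutoff_a", "saltbridge_cutoff_a", "open_state_threshold_deg",
                     "coupling_ratio_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.stages = tuple(self.stages)

    def config_hash(self) -> str:
        payload = {k: getattr(self, k) for k in _ANALYSIS_FIELDS}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame]
    config_hash: str
    version: str
    seed: int

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
            long = df.melt(
                id_vars=[c for c in ("troponin", "ligand", "condition", "model", "mutation")
                         if c in df.columns]
            )
            long.to_csv(os.path.join(out_dir, f"{name}_long.csv"), index=False)
        meta = {"version": self.version, "config_hash": self.config_hash, "seed": self.seed,
                "tables": sorted(self.tables)}
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def _cond_seed(base_seed: int, tag: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _traj_spec_for(row_ab, row_hinge, row_dom, attach_fraction, state: str,
                   config: RunConfig, tag: str) -> TrajectorySpec:
    pre = "up_" if state == "uP" else "p_"
    variant = "WT" if row_ab["troponin"] == "WT" else "G159D"
    occ_col = "saltbridge_occupancy_up" if state == "uP" else "saltbridge_occupancy_p"
    lig = None
    if row_ab["ligand"] != "apo" and attach_fraction is not None and 0 < attach_fraction < 1:
        lig = LigandSpec.for_bound_fraction(attach_fraction)
    return TrajectorySpec(
        n_frames=config.n_frames,
        n_runs=config.n_runs,
        ab_angle=GaussianMixture1D.normal(row_ab[pre + "mean_deg"], row_ab[pre + "std_deg"]),
        hinge_angle=GaussianMixture1D.normal(row_hinge[pre + "mean_deg"], row_hinge[pre + "std_deg"]),
        interdomain_distance=(row_dom[pre + "mean_a"], row_dom[pre + "std_a"]),
        saltbridge_occupancy=float(row_dom[occ_col]),
        variant=variant,
        ligand=lig,
        seed=_cond_seed(config.seed, tag),
    )


def _analyze_condition(spec: TrajectorySpec, config: RunConfig):
    """Generate one condition and pool re-measured metrics across runs."""
    bundle = gen_trajectory(spec)
    regions = bundle.regions
    ab_vals, hinge_vals, dist_vals = [], [], []
    sb_bound = []
    attach_bound = 0
    for traj in bundle.runs:
        ab_vals.append(ab_angle_series(traj, bundle.topology, regions["helix_a"], regions["helix_b"]).values)
        hinge_vals.append(
            hinge_angle_series(traj, bundle.topology, regions["nc_lobe"], regions["itc_domain"],
                               regions["pivot"]).values
        )
        dist_vals.append(
            interdomain_distance_series(traj, bundle.topology, regions["nc_lobe"],
                                        regions["itc_domain"]).values
        )
        _, occ = pair_bond_occupancy(
            traj, bundle.topology, regions["asp159_carboxylate"], regions["arg83_guanidinium"],
            cutoff=config.saltbridge_cutoff_a,
        )
        sb_bound.append(occ.bound)
        if "ligand" in regions:
            summary = run_attachment(traj, bundle.topology, regions["ligand"], regions["protein"],
                                     cutoff=config.contact_cutoff_a)
            attach_bound += int(round(summary.fraction_attached * traj.n_frames))
    n_total = sum(t.n_frames for t in bundle.runs)
    ab = summarize(np.concatenate(ab_vals), threshold=config.open_state_threshold_deg,
                   units="deg", metric_name="AB_helix")
    hinge = summarize(np.concatenate(hinge_vals), units="deg", metric_name="hinge")
    dom = summarize(np.concatenate(dist_vals), units="A", metric_name="interdomain_distance")
    sb = float(np.concatenate(sb_bound).mean())
    attach = attach_bound / n_total if "ligand" in regions else None
    return ab, hinge, dom, sb, attach


def _summary_cols(prefix: str, s: DistributionSummary) -> dict:
    out = {f"{prefix}_mean": s.mean, f"{prefix}_std": s.std, f"{prefix}_fwhm": s.fwhm}
    if s.pct_above is not None:
        out[f"{prefix}_pct_above"] = s.pct_above
    return out


def _trajectory_stage(config: RunConfig) -> dict[str, pd.DataFrame]:
    ab_ref = load_table("ab_angle_metrics")
    hinge_ref = load_table("hinge_angle_metrics")
    dom_ref = load_table("interdomain_metrics")
    attach_ref = load_table("attachment_mmpbsa").set_index(["troponin", "ligand"])

    results = {}
    for _, row_ab in ab_ref.iterrows():
        key = (row_ab["troponin"], row_ab["ligand"])
        row_hinge = hinge_ref[(hinge_ref.troponin == key[0]) & (hinge_ref.ligand == key[1])].iloc[0]
        row_dom = dom_ref[(dom_ref.troponin == key[0]) & (dom_ref.ligand == key[1])].iloc[0]
        per_state = {}
        for state in ("uP", "P"):
            att = None
            if key in attach_ref.index:
                col = "fraction_attached_up" if state == "uP" else "fraction_attached_p"
                v = attach_ref.loc[key, col]
                att = None if pd.isna(v) else float(v)
            spec = _traj_spec_for(row_ab, row_hinge, row_dom, att, state, config,
                                  tag=f"{key[0]}/{key[1]}/{state}")
            per_state[state] = _analyze_condition(spec, config)
        results[key] = per_state

    wt = results[("WT", "apo")]
    wt_deltas = {
        "ab": delta(wt["uP"][0], wt["P"][0]),
        "hinge": delta(wt["uP"][1], wt["P"][1]),
        "dom": delta(wt["uP"][2], wt["P"][2]),
    }

    ab_rows, hinge_rows, dom_rows, attach_rows = [], [], [], []
    for key, per_state in results.items():
        troponin, ligand = key
        base = {"troponin": troponin, "ligand": ligand}
        is_wt = key == ("WT", "apo")
        for idx, (name, rows, dead_band) in enumerate(
            (
                ("ab", ab_rows, config.dead_band_angle_deg),
                ("hinge", hinge_rows, config.dead_band_angle_deg),
                ("dom", dom_rows, config.dead_band_distance_a),
            )
        ):
            d = delta(per_state["uP"][idx], per_state["P"][idx])
            row = dict(base)
            row.update(_summary_cols("up", d.uP))
            row["delta_mean"] = d.delta_mean
            row.update(_summary_cols("p", d.P))
            row["delta_fwhm"] = d.delta_fwhm
            if d.delta_pct_above is not None:
                row["delta_pct_above"] = d.delta_pct_above
            if not is_wt:
                row["restored_mean"] = classify_recoupling(
                    wt_deltas[name], d, dead_band=dead_band
                ).restored
            rows.append(row)
        sb_u, sb_p = per_state["uP"][3], per_state["P"][3]
        dom_rows[-1].update({"saltbridge_occupancy_up": sb_u, "saltbridge_occupancy_p": sb_p})
        if per_state["uP"][4] is not None or per_state["P"][4] is not None:
            arow = dict(base)
            arow["fraction_attached_up"] = per_state["uP"][4]
            arow["fraction_attached_p"] = per_state["P"][4]
            if key in attach_ref.index:
                for col in ("mmpbsa_ligand_up", "mmpbsa_ligand_delta", "mmpbsa_ligand_p"):
                    arow[col] = attach_ref.loc[key, col]   # echoed external input
            attach_rows.append(arow)

    return {
        "ab_angle": pd.DataFrame(ab_rows),
        "hinge_angle": pd.DataFrame(hinge_rows),
        "interdomain": pd.DataFrame(dom_rows),
        "attachment": pd.DataFrame(attach_rows),
    }


def _motility_stage(config: RunConfig) -> pd.DataFrame:
    ref = load_table("motility_ec50")
    rows = []
    for _, r in ref.iterrows():
        tag = f"motility/{r['condition']}/{r['ligand']}"
        spec = CurveSpec(
            ec50_unp_um=float(r["ec50_unp_um"]),
            ratio=float(r["ratio"]),
            noise_sd=config.curve_noise_sd,
            n_replicates=config.curve_replicates,
            seed=_cond_seed(config.seed, tag),
        )
        pairs, _ = gen_activation_curves(spec)
        fits = [(fit_hill(p), fit_hill(u)) for p, u in pairs]
        call = coupling_call(fits, threshold=config.coupling_ratio_threshold)
        rows.append(
            {
                "condition": r["condition"],
                "ligand": r["ligand"],
                "ec50_p_um": float(np.mean([f.ec50 for f, _ in fits])),
                "ec50_unp_um": float(np.mean([f.ec50 for _, f in fits])),
                "mean_ratio": call.mean_ratio,
                "sem_ratio": call.sem_ratio,
                "p_value": call.p_value,
                "coupled": call.coupled,
                "n_pairs": len(fits),
            }
        )
    return pd.DataFrame(rows)


def _myocyte_stage(config: RunConfig) -> pd.DataFrame:
    ref = load_table("myocyte_lusitropy")
    rows = []
    for _, r in ref.iterrows():
        tag = f"myocyte/{r['model']}/{r['mutation']}/{r['ligand']}"
        # guinea-pig kinetics are about twice as slow as mouse
        slow = 2.0 if r["model"] == "guinea_pig" else 1.0
        spec = TransientSpec(
            ttp90_s=0.08 * slow,
            ttb90_s=0.18 * slow,
            n_cells=config.n_cells,
            seed=_cond_seed(config.seed, tag),
        )
        pre, post, _ = gen_paired_transients(spec, lusitropy=float(r["lusitropy"]))
        pre_f = {t.cell_id: trace_features(t) for t in pre}
        post_f = {t.cell_id: trace_features(t) for t in post}
        resp = paired_response(pre_f, post_f)
        lus = resp.deltas["lusitropy"]
        rows.append(
            {
                "model": r["model"],
                "mutation": r["mutation"],
                "ligand": r["ligand"],
                "lusitropy_mean": float(np.mean(lus)),
                "lusitropy_sem": resp.sems["lusitropy"],
                "ttb90_p_value": resp.p_values["ttb90_s"],
                "stars": resp.stars["ttb90_s"],
                "n_cells": resp.n_cells,
                "lusitropic": bool(
                    np.mean(lus) > 0
                    and resp.p_values["ttb90_s"] is not None
                    and resp.p_values["ttb90_s"] < 0.05
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the configured stages and assemble the study report."""
    tables: dict[str, pd.DataFrame] = {}
    for stage in config.stages:
        if stage == "trajectory":
            tables.update(_trajectory_stage(config))
        elif stage == "motility":
            tables["motility"] = _motility_stage(config)
        elif stage == "myocyte":
            tables["myocyte"] = _myocyte_stage(config)
        else:
            raise ValueError(f"unknown stage {stage!r}")
    report = StudyReport(
        tables=tables,
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


_LEVEL_TABLES = {
    "ab_angle": ("restored_mean", ("troponin", "ligand")),
    "hinge_angle": ("restored_mean", ("troponin", "ligand")),
}


def cross_level_summary(report: StudyReport) -> pd.DataFrame:
    """Per-ligand restored/not-restored flags across tiers, with agreement.

    The agreement score is the fraction of available tiers matching the
    majority call for that ligand.  Requires at least two tiers in the
    report.
    """
    ligands = ("EGCG", "RVL", "SilybinA", "SilybinB", "ECG")
    rows = []
    for lig in ligands:
        flags: dict[str, Optional[bool]] = {}
        for tname, (col, _) in _LEVEL_TABLES.items():
            if tname in report.tables:
                df = report.tables[tname]
                sel = df[(df.get("troponin") == "G159D") & (df["ligand"] == lig)]
                if len(sel) and col in sel.columns:
                    flags[tname] = bool(sel.iloc[0][col])
        if "motility" in report.tables:
            df = report.tables["motility"]
            sel = df[(df["ligand"] == lig) & (df["condition"] != "Native TF")]
            if len(sel):
                flags["motility"] = bool(sel["coupled"].any())
        if "myocyte" in report.tables:
            df = report.tables["myocyte"]
            sel = df[(df["ligand"] == lig) & (df["mutation"] != "WT")]
            if len(sel):
                flags["myocyte"] = bool(sel["lusitropic"].any())
        avail = {k: v for k, v in flags.items() if v is not None}
        if not avail:
            continue
        votes = list(avail.values())
        majority = votes.count(True) >= votes.count(False)
        agreement = votes.count(majority) / len(votes)
        row = {"ligand": lig, **avail, "majority_restored": majority, "agreement": agreement}
        rows.append(row)
    n_levels = max((len(r) - 3 for r in rows), default=0)
    if n_levels < 2:
        raise ValueError("cross-level summary needs at least two analysis tiers in the report")
    return pd.DataFrame(rows)
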