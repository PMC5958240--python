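"""End-to-end pipeline driver: build → simulate → analyze, per scenario.

For each requested scenario the driver builds the coiled-coil model, draws
a synthetic conformational ensemble plus CD/melt, filament, solubility,
integration and line-scan data from the scenario preset, and runs every
analysis stage, writing tidy CSVs, a JSON report and generator-truth
sidecars under ``<out_dir>/<scenario>/``.  A stage failure aborts that
scenario (logged) and the remaining scenarios continue.  Every output
carries the configuration hash and root seed; re-running with the same
configuration reproduces all numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from myotail import cd as cdq
from myotail import ensemble_stats as es
from myotail import morphometry as mor
from myotail import sarcomere as sc
from myotail import sasa as sasa_mod
from myotail import synthetic as syn
from myotail import trajectory as tm
from myotail.builder import build_coiled_coil
from myotail.ensemble import write_ensemble, write_model_pdb
from myotail.motifs import make_motif_schedule
from myotail.params import CrickParams
from myotail.register import assign_heptad_register, mutate_sequence
from myotail.saltbridges import bridges_to_frame, salt_bridge_occupancy
from myotail.sequences import (
    REGISTER_ANCHORS,
    SKIP_RESIDUE,
    wild_type_sequence,
)

log = logging.getLogger("myotail")

ALL_STAGES = (
    "build", "ensemble", "trajectory", "stats", "cd", "filaments",
    "solubility", "integration", "sarcomere",
)


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the study conditions."""

    scenarios: "list[str]" = field(default_factory=lambda: ["WT"])
    stages: "list[str]" = field(default_factory=lambda: list(ALL_STAGES))
    out_dir: str = "results"
    seed: int = 0
    # ensemble generation / reduction
    n_frames: int = 60
    time_per_frame_ns: float = 0.5
    equilibration_ns: float = 10.0
    # trajectory metrics
    dcom_window: int = 7
    cluster_cutoff_a: float = 8.0
    probe_radius_a: float = 1.4
    n_sphere_points: int = 240
    rsa_max_frames: int = 3
    salt_bridge_cutoff_a: float = 4.0
    salt_bridge_min_occupancy: float = 0.7
    # CD
    melt_noise_pct: float = 1.0
    cd_noise: float = 300.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def build_scenario_model(scenario: str, params: CrickParams = CrickParams()):
    """Model + (sequence, assignment, schedule) for a named scenario preset."""
    preset = syn.PRESETS[scenario]
    wt = wild_type_sequence()
    seq = mutate_sequence(wt, preset.mutation)
    assignment = assign_heptad_register(wt.numbering, REGISTER_ANCHORS, (SKIP_RESIDUE,))
    deletions = tuple(seq.gaps)
    if preset.mode == "canonical-throughout":
        schedule = make_motif_schedule(assignment, deletions=deletions, mode=preset.mode)
    else:
        schedule = make_motif_schedule(assignment, deletions=deletions)
    model = build_coiled_coil(seq, seq, schedule, params, assignment)
    return model, seq, assignment, schedule


def _scenario_seed(root_seed: int, scenario: str, stage: str) -> int:
    """Stable per-(scenario, stage) seed below 2^31 derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{scenario}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _write_json(path: Path, data) -> None:
    path.write_text(json.dumps(data, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_scenario(scenario: str, config: RunConfig, out: Path) -> dict:
    """Run all configured stages for one scenario; returns the report dict."""
    preset = syn.PRESETS[scenario]
    report: dict = {"scenario": scenario, "config_hash": config.config_hash,
                    "seed": config.seed}
    out.mkdir(parents=True, exist_ok=True)
    stages = config.stages

    model = None
    if "build" in stages:
        model, seq, assignment, schedule = build_scenario_model(scenario)
        write_model_pdb(model, out / "model.pdb")
        report["build"] = {
            "n_residues": len(seq),
            "numbering_gaps": list(seq.gaps),
            "noncanonical_motifs": [
                {"start": m.start_residue, "length": m.length, "turns": m.helical_turns}
                for m in schedule.noncanonical
            ],
            "axis_length_nm": model.axis_length() / 10.0,
        }

    ens = None
    if "ensemble" in stages and model is not None and preset.ee_mean_nm is not None:
        ens = syn.gen_ensemble(
            model, preset.hinge_residue, "end-to-end-target",
            ee_mean_nm=preset.ee_mean_nm, ee_sd_nm=preset.ee_sd_nm,
            n_frames=config.n_frames, time_per_frame_ns=config.time_per_frame_ns,
            seed=_scenario_seed(config.seed, scenario, "ensemble"),
        )
        write_ensemble(ens, out / "ensemble.pdb")
        _write_json(out / "ensemble.truth.json", ens.metadata["truth"])
        ens = es.discard_equilibration(ens, config.equilibration_ns)
        report["ensemble"] = {"n_frames_analyzed": ens.n_frames}

    if "trajectory" in stages and ens is not None:
        dcom = tm.dcom_profile(ens, config.dcom_window)
        dcom.to_frame().to_csv(out / "dcom.csv", index=False)
        pd.concat(
            [p.to_frame() for p in tm.heptad_length_profile(ens).values()]
        ).to_csv(out / "heptad_length.csv", index=False)
        pd.concat(
            [p.to_frame() for p in tm.inter_heptad_angle_profile(ens).values()]
        ).to_csv(out / "inter_heptad_angle.csv", index=False)
        hel = tm.helicity(ens)
        ee_mean, ee_sd = tm.end_to_end(ens)
        rsa_sub = ens.frame_subset(slice(0, None, max(1, ens.n_frames // config.rsa_max_frames)))
        rsa = sasa_mod.rsa_profile(
            rsa_sub, probe=config.probe_radius_a, n_sphere_points=config.n_sphere_points,
        )
        pd.concat([p.to_frame() for p in rsa.values()]).to_csv(out / "rsa.csv", index=False)
        has_sidechains = bool(
            np.isin(ens.atom_name, ["NZ", "NH1", "OD1", "OE1"]).any()
        )
        if has_sidechains:
            bridges, (sb_mean, sb_sd) = salt_bridge_occupancy(ens, config.salt_bridge_cutoff_a)
            bridges_to_frame(bridges).to_csv(out / "salt_bridges.csv", index=False)
            report["salt_bridges"] = {"mean_count": sb_mean, "sd": sb_sd}
        else:
            log.info("%s: backbone-only ensemble — salt-bridge stage skipped", scenario)
        report["trajectory"] = {
            "helicity": hel, "end_to_end_nm": [ee_mean, ee_sd],
        }

    if "stats" in stages and ens is not None:
        rmsd = es.rmsd_vs_initial(ens)
        clusters = es.cluster_structures(ens, config.cluster_cutoff_a)
        pd.DataFrame(
            {"frame": np.arange(ens.n_frames), "time_ns": ens.times_ns,
             "rmsd_A": rmsd, "cluster": clusters.labels}
        ).to_csv(out / "rmsd_clusters.csv", index=False)
        es.rmsf(ens).to_csv(out / "rmsf.csv", index=False)
        report["stats"] = {
            "n_clusters": clusters.n_clusters,
            "cluster_populations_pct": clusters.populations.tolist(),
        }

    if "cd" in stages and preset.helix_fraction is not None:
        spec = syn.gen_cd(
            preset.helix_fraction, config.cd_noise,
            seed=_scenario_seed(config.seed, scenario, "cd"),
        )
        pd.DataFrame(
            {"wavelength_nm": spec.wavelengths_nm, "mre": spec.mre}
        ).to_csv(out / "cd_spectrum.csv", index=False)
        melt = syn.gen_melt(
            preset.melt_tm_c, noise_sd=config.melt_noise_pct,
            seed=_scenario_seed(config.seed, scenario, "melt"),
        )
        cdq.melt_to_frame(melt).to_csv(out / "melt.csv", index=False)
        tm_c, width = cdq.fit_melt(melt)
        report["cd"] = {**cdq.spectrum_summary(spec), "tm_c": tm_c, "melt_width_c": width}
        _write_json(out / "cd.truth.json",
                    {**spec.metadata["truth"], **melt.metadata["truth"]})

    if "filaments" in stages and preset.length is not None:
        fil = syn.gen_filaments(
            {scenario: preset, "WT": syn.PRESETS["WT"]},
            seed=_scenario_seed(config.seed, "shared", "filaments"),
        )
        fil.to_csv(out / "filaments.csv", index=False)
        _write_json(out / "filaments.truth.json", fil.attrs["truth"])
        stats_len = mor.filament_stats(fil, "length_nm")
        stats_wid = mor.filament_stats(fil, "width_nm")
        bundles = mor.bundle_fraction(fil)
        stats_len.to_csv(out / "filament_lengths.csv", index=False)
        stats_wid.to_csv(out / "filament_widths.csv", index=False)
        bundles.to_csv(out / "bundles.csv", index=False)
        row = stats_len[stats_len["group"] == scenario].iloc[0]
        brow = bundles[bundles["group"] == scenario].iloc[0]
        report["filaments"] = {
            "mean_length_nm": row["mean"], "sem_length_nm": row["sem"],
            "bundled_pct": brow["bundled_pct"],
        }

    if "solubility" in stages and preset.solubility_midpoint_mm is not None:
        sol = syn.gen_solubility(
            {scenario: preset, "WT": syn.PRESETS["WT"]},
            seed=_scenario_seed(config.seed, "shared", "solubility"),
        )
        curve, fit = mor.solubility_curve(sol[sol["group"] == scenario])
        curve.to_csv(out / "solubility.csv", index=False)
        report["solubility"] = {"fit": fit}
        _write_json(out / "solubility.truth.json", sol.attrs["truth"])

    if "integration" in stages and preset.integration is not None:
        scores = syn.gen_integration(
            {scenario: preset, "WT": syn.PRESETS["WT"]},
            seed=_scenario_seed(config.seed, "shared", "integration"),
        )
        per_exp, summary = mor.integration_summary(scores)
        per_exp.to_csv(out / "integration_per_experiment.csv", index=False)
        summary.to_csv(out / "integration_summary.csv", index=False)
        report["integration"] = summary[summary["group"] == scenario].to_dict("records")

    if "sarcomere" in stages and preset.sarcomere:
        scans, truth = syn.gen_linescans_for_scenario(
            scenario, seed=_scenario_seed(config.seed, scenario, "sarcomere")
        )
        _write_json(out / "linescans.truth.json", truth)
        per_mf_metrics = []
        all_windows = []
        for scan in scans:
            windows = sc.segment_sarcomeres(scan)
            all_windows.extend(windows)
            prof = sc.align_average(windows)
            per_mf_metrics.append(
                {"myofibril": scan.myofibril_id, **sc.profile_metrics(prof)}
            )
        profile = sc.align_average(all_windows)
        pd.DataFrame(
            {"offset_um": profile.offsets_um, "mean_intensity": profile.mean_intensity}
        ).to_csv(out / "sarcomere_profile.csv", index=False)
        dfm = pd.DataFrame(per_mf_metrics)
        dfm.to_csv(out / "sarcomere_metrics.csv", index=False)
        report["sarcomere"] = {
            "peak_to_min_ratio": dfm["peak_to_min_ratio"].mean(),
            "mean_peak_value": dfm["mean_peak_value"].mean(),
            "peak_peak_distance_um": dfm["peak_peak_distance_um"].mean(),
            "n_myofibrils": len(dfm),
        }

    _write_json(out / "report.json", report)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run all scenarios; failed scenarios are logged and skipped."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_root / "config.yaml")
    reports = {}
    for scenario in config.scenarios:
        try:
            reports[scenario] = run_scenario(scenario, config, out_root / scenario)
        except Exception:  # noqa: BLE001 — isolate scenario failures
            log.exception("scenario %s failed", scenario)
    _write_comparisons(reports, out_root)
    _write_json(out_root / "report.json", reports)
    return reports


def _write_comparisons(reports: dict, out_root: Path) -> None:
    """Per-residue ΔD_com tables for every mutant scenario vs WT."""
    wt_path = out_root / "WT" / "dcom.csv"
    if not wt_path.exists():
        return
    wt = pd.read_csv(wt_path).set_index("resid")
    for scenario in reports:
        if scenario == "WT":
            continue
        mut_path = out_root / scenario / "dcom.csv"
        if not mut_path.exists():
            continue
        mut = pd.read_csv(mut_path).set_index("resid")
        joined = wt.join(mut, lsuffix="_wt", rsuffix="_mut", how="inner")
        joined["delta_dcom"] = joined["mean_mut"] - joined["mean_wt"]
        joined.reset_index()[["resid", "mean_wt", "mean_mut", "delta_dcom"]].to_csv(
            out_root / f"delta_dcom_WT_vs_{scenario}.csv", index=False
        )
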