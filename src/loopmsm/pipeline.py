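"""Config-driven orchestration of the full two-system analysis.

Stages: featurize → prune (shared across systems) → iterative feature
selection → joint tICA → microstate MSM → HMM coarse-graining → system
comparison, with an independent relaxation branch.  Every stage writes
its artifacts under the output directory and a manifest records the
parameters, seed and completed stages, so a rerun with identical inputs
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import compare as cmp_mod
from . import featurize as feat
from . import metastable as meta
from . import msm as msm_mod
from . import relaxation as relax
from . import selection as sel
from . import tica as tica_mod

__all__ = ["PipelineConfig", "run", "run_from_yaml"]


@dataclass
class PipelineConfig:
    """Flat per-stage parameters with one global seed.

    System inputs may be given either as (topology PDB + trajectory files)
    per system, or as pre-built in-memory ensembles passed directly to
    :func:`run`.
    """

    # featurization
    terminal_clip: int = 2
    d_min: float = 3.0
    d_max: float = 10.0
    # selection / tICA
    lag: int = 5
    n_tics: int = 4
    target_n_features: int = 24
    n_tics_considered: int = 2
    # MSM / HMM
    k_micro: int = 50
    n_macro: int | str = "auto"
    n_boot: int = 30
    bins: int = 40
    kT: float = 1.0
    dt_ns: float = 1.0
    # reproducibility
    seed: int = 0
    out_dir: str = "pipeline_out"
    # file inputs (optional; in-memory ensembles may be passed to run())
    topology_a: str | None = None
    trajectories_a: list[str] = field(default_factory=list)
    topology_b: str | None = None
    trajectories_b: list[str] = field(default_factory=list)
    relaxation_csv: str | None = None
    field_MHz: float = 800.0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def validate_paths(self) -> None:
        for p in (
            [self.topology_a, self.topology_b, self.relaxation_csv]
            + self.trajectories_a
            + self.trajectories_b
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def run_from_yaml(path: str | Path) -> dict:
    cfg = PipelineConfig(**yaml.safe_load(Path(path).read_text()))
    return run(cfg)


def _load_system(cfg: PipelineConfig, top, trajs) -> feat.TrajectoryEnsemble:
    topo = feat.load_topology(top, terminal_clip=cfg.terminal_clip)
    return feat.load_trajectories(trajs, top, topology=topo, dt_ns=cfg.dt_ns)


def run(
    config: PipelineConfig,
    ensemble_a: feat.TrajectoryEnsemble | None = None,
    ensemble_b: feat.TrajectoryEnsemble | None = None,
    relaxation_data: relax.RelaxationDataset | None = None,
) -> dict:
    """Execute the pipeline; returns a report bundle (also written to disk).

    Two-system stages run when both ensembles are available; the
    relaxation branch runs when a dataset or CSV is configured.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(config).items()},
                      "stages": []}
    bundle: dict = {"manifest": manifest}

    if ensemble_a is None and config.topology_a:
        ensemble_a = _load_system(config, config.topology_a, config.trajectories_a)
    if ensemble_b is None and config.topology_b:
        ensemble_b = _load_system(config, config.topology_b, config.trajectories_b)

    if ensemble_a is not None:
        topo = ensemble_a.topology
        if topo.terminal_clip != config.terminal_clip:
            topo = feat.Topology(topo.residues, terminal_clip=config.terminal_clip)
            ensemble_a = feat.TrajectoryEnsemble(
                ensemble_a.trajectories, topo, ensemble_a.dt_ns
            )
            if ensemble_b is not None:
                ensemble_b = feat.TrajectoryEnsemble(
                    ensemble_b.trajectories, topo, ensemble_b.dt_ns
                )
        defs = feat.enumerate_ca_pairs(topo)
        fm_a = feat.compute_features(ensemble_a, defs)
        fms = [fm_a]
        if ensemble_b is not None:
            fm_b = feat.compute_features(ensemble_b, defs)
            fms.append(fm_b)
        # one pruning pass over the union of all systems' frames
        union = feat.FeatureMatrix(
            np.concatenate([f.values for f in fms]),
            list(defs),
            sum([list(f.segment_lengths) for f in fms], []),
        )
        _, prune_report = feat.prune_features(union, config.d_min, config.d_max)
        keep = [
            d.label
            for d in defs
            if d.label not in set(prune_report.removed_too_close)
            | set(prune_report.removed_too_far)
        ]
        fm_a = fm_a.subset(keep)
        prune_report.to_json(out / "prune_report.json")
        manifest["stages"].append("featurize")

        sel_cfg = sel.SelectionConfig(
            lag=config.lag,
            n_tics_considered=config.n_tics_considered,
            target_n_features=config.target_n_features,
        )
        if ensemble_b is not None:
            fm_b = fm_b.subset(keep)
            fm_sel_input = feat.FeatureMatrix(
                np.concatenate([fm_a.values, fm_b.values]),
                list(fm_a.definitions),
                list(fm_a.segment_lengths) + list(fm_b.segment_lengths),
            )
        else:
            fm_sel_input = fm_a
        selection = sel.iterative_tica_selection(fm_sel_input, sel_cfg)
        (out / "selection.json").write_text(
            json.dumps(
                {
                    "selected": selection.labels,
                    "anchors": {str(r): c for r, c in selection.anchor_table.items()},
                    "status": selection.status,
                },
                indent=1,
            )
        )
        bundle["selection"] = selection
        manifest["stages"].append("selection")

        fm_a_sel = fm_a.subset(selection.labels)
        if ensemble_b is not None:
            fm_b_sel = fm_b.subset(selection.labels)
            model = cmp_mod.joint_tica(fm_a_sel, fm_b_sel, lag=config.lag,
                                       n_components=config.n_tics)
        else:
            model = tica_mod.fit_tica(fm_a_sel, lag=config.lag,
                                      n_components=config.n_tics)
        bundle["tica"] = model
        manifest["stages"].append("tica")

        proj_a = tica_mod.project(model, fm_a_sel)
        systems = {"a": (fm_a_sel, proj_a)}
        if ensemble_b is not None:
            systems["b"] = (fm_b_sel, tica_mod.project(model, fm_b_sel))
        results = {}
        for name, (fm_s, proj) in systems.items():
            segs = np.cumsum(fm_s.segment_lengths)[:-1]
            parts = np.split(proj, segs)
            dtr = msm_mod.cluster_microstates(
                parts, k=min(config.k_micro, proj.shape[0] // 10),
                seed=config.stage_seed(f"cluster_{name}"),
            )
            its = msm_mod.implied_timescales(
                dtr, lags=[config.lag], n_its=min(6, dtr.n_states - 1)
            )
            if config.n_macro == "auto":
                n_macro = meta.select_macrostate_count(its)
            else:
                n_macro = int(config.n_macro)
            mmodel = meta.coarse_grain_hmm(
                dtr, n_macro, config.lag,
                seed=config.stage_seed(f"hmm_{name}"),
                n_boot=config.n_boot, dt_ns=config.dt_ns,
            )
            fes = msm_mod.free_energy_surface(proj, bins=config.bins, kT=config.kT)
            fes.to_csv(out / f"fes_{name}.csv")
            results[name] = {"dtrajs": dtr, "its": its, "metastable": mmodel,
                             "fes": fes, "projection": proj}
            manifest["stages"].append(f"msm_{name}")
        bundle["systems"] = results

        if ensemble_b is not None:
            ra, rb = results["a"], results["b"]
            cent_a = cmp_mod.macrostate_centroids(
                ra["metastable"], ra["projection"], ra["dtrajs"].dtrajs
            )
            cent_b = cmp_mod.macrostate_centroids(
                rb["metastable"], rb["projection"], rb["dtrajs"].dtrajs
            )
            report = cmp_mod.match_macrostates(
                cent_a, cent_b,
                ra["metastable"].populations, rb["metastable"].populations,
            )
            if report.matched:
                report = cmp_mod.compare_kinetics(
                    ra["metastable"], rb["metastable"], report, dt_ns=config.dt_ns
                )
            bundle["comparison"] = report
            (out / "comparison.json").write_text(
                json.dumps(
                    {
                        "matched": [
                            {"a": m.state_a, "b": m.state_b, "distance": m.distance}
                            for m in report.matched
                        ],
                        "exclusive_a": report.exclusive_a,
                        "exclusive_b": report.exclusive_b,
                        "population_shift": report.population_shift,
                        "mfpt_ratio": report.mfpt_ratio,
                    },
                    indent=1,
                    default=float,
                )
            )
            manifest["stages"].append("comparison")

    if relaxation_data is None and config.relaxation_csv:
        relaxation_data = relax.RelaxationDataset.from_csv(
            config.relaxation_csv, field_MHz=config.field_MHz
        )
    if relaxation_data is not None:
        tm = relax.estimate_tm(relaxation_data)
        mf = relax.modelfree_fit(relaxation_data, tau_m_ns=tm)
        cls = relax.classify_r2r1(relaxation_data)
        mf.to_frame().to_csv(out / "modelfree.csv", index=False)
        cls.to_frame().to_csv(out / "r2r1_classes.csv", index=False)
        bundle["relaxation"] = {"tau_m_ns": tm, "modelfree": mf,
                                "classification": cls}
        manifest["stages"].append("relaxation")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return bundle
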