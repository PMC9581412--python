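"""End-to-end pipeline: featurize → tICA → cluster → MSM → macrostates → profiles.

The configuration mirrors each stage's options.  Defaults follow the settings
that work well for a small ligand exploring discrete binding modes in a
protein pocket: inverse-distance contact features at a 6 Å cutoff, a 20 ns
tICA lag, 10 tICs, 200 k-means microstates, a 15 ns MSM lag, PCCA+ macrostates
with a 0.8 core-membership threshold and 5-fold cross-validation — with every
stochastic stage behind an explicit seed.  Lags are specified in ns and
converted to frames through the frame spacing, which must divide them evenly.

``run_pipeline`` executes the stages in order on either a generated toy
complex or user-supplied feature files, writing each stage's artifacts plus a
manifest (config echo and seeds) into the output directory; a re-run with the
same config reproduces the artifacts bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import ParameterError
from . import characterize, featurization, decomposition, importance, macrostates, msm, sampling, synthetic

logger = logging.getLogger("ligandmsm")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters of the analysis pipeline."""

    # input
    frame_spacing_ns: float = 1.0
    simulate: bool = True                # generate the toy complex
    toy_n_modes: int = 3
    toy_n_residues: int = 16
    toy_n_ligand_atoms: int = 3
    toy_n_trajs: int = 5
    toy_n_steps: int = 20_000
    toy_switch_rate: float = 0.02
    toy_jitter_sd: float = 0.3
    # featurization
    feature_transform: str = "inverse"
    feature_cutoff: float = 6.0
    pair_filter_cutoff: float = 6.5
    # kinetic decomposition
    tica_lag_ns: float = 20.0
    n_tics: int = 10
    vamp2_lags_ns: tuple = (2.0, 5.0, 10.0, 15.0, 20.0)
    n_eigenvalues: int = 10
    # MSM
    n_microstates: int = 200
    msm_lag_ns: float = 15.0
    its_lags_ns: tuple = ()
    n_bootstrap: int = 25
    # macrostates
    n_macrostates: int | None = None     # None = pick at the spectral gap
    core_threshold: float = 0.8
    # importance
    folds: int = 5
    # seeds
    seeds: dict = field(default_factory=lambda: {
        "simulate": 0, "cluster": 1, "cv": 2, "importance": 3, "bootstrap": 4,
        "sampling": 5,
    })
    log_level: str = "INFO"

    def lag_frames(self, lag_ns: float) -> int:
        ratio = lag_ns / self.frame_spacing_ns
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ParameterError(
                f"lag {lag_ns} ns is not a positive multiple of the "
                f"frame spacing {self.frame_spacing_ns} ns"
            )
        return int(round(ratio))


REQUIRED_SEEDS = ("simulate", "cluster", "cv", "importance", "bootstrap", "sampling")


def validate_config(config) -> PipelineConfig:
    """Normalize a mapping / YAML path / PipelineConfig, aggregating all errors."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if isinstance(config, PipelineConfig):
        cfg = config
    elif isinstance(config, dict):
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(config) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = PipelineConfig(**config)
    else:
        raise ParameterError(f"cannot interpret config of type {type(config)!r}")

    errors = []
    if cfg.frame_spacing_ns <= 0:
        errors.append("frame_spacing_ns must be positive")
    for name in REQUIRED_SEEDS:
        if name not in cfg.seeds:
            errors.append(f"missing seed for stage {name!r}")
    for label, lag in [("tica_lag_ns", cfg.tica_lag_ns), ("msm_lag_ns", cfg.msm_lag_ns),
                       *[(f"vamp2 lag {v}", v) for v in cfg.vamp2_lags_ns]]:
        try:
            cfg.lag_frames(lag)
        except ParameterError as exc:
            errors.append(f"{label}: {exc}")
    if not (0.5 <= cfg.core_threshold <= 1.0):
        errors.append("core_threshold must be in [0.5, 1]")
    if cfg.feature_transform not in featurization.VALID_TRANSFORMS:
        errors.append(f"feature_transform must be one of {featurization.VALID_TRANSFORMS}")
    if cfg.feature_cutoff <= 0:
        errors.append("feature_cutoff must be positive")
    if errors:
        raise ParameterError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def _save_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    path.write_text(json.dumps(obj, indent=1, default=default))


def run_pipeline(config, outdir: str | Path) -> dict:
    """Run the full analysis and write artifacts; returns the result bundle.

    Stages: simulate (toy complex) → featurize → tICA → cluster → MSM (+
    implied timescales) → macrostates (populations, cores, MFPTs) →
    importance profiles → state characterization (representatives, contact
    deltas).  A stage failure aborts with the stage named; artifacts written
    so far are retained.
    """
    cfg = validate_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        stage = "simulate"
        if not cfg.simulate:
            raise ParameterError("only the simulated-input path is wired into run_pipeline")
        logger.info("generating toy complex (%d modes)", cfg.toy_n_modes)
        spec = synthetic.default_toy_spec(
            n_modes=cfg.toy_n_modes, n_residues=cfg.toy_n_residues,
            n_ligand_atoms=cfg.toy_n_ligand_atoms, jitter_sd=cfg.toy_jitter_sd,
            switch_rate=cfg.toy_switch_rate, seed=cfg.seeds["simulate"],
        )
        traj, truth = synthetic.generate_toy_complex_trajectories(
            spec, cfg.toy_n_steps, seed=cfg.seeds["simulate"],
            n_trajs=cfg.toy_n_trajs, contact_cutoff=cfg.feature_cutoff,
            frame_spacing_ns=cfg.frame_spacing_ns,
        )
        results["ground_truth"] = truth
        _save_json(out / "ground_truth.json", truth.to_json())

        stage = "featurize"
        lig_names = [traj.topology.atom_names[i]
                     for i in np.flatnonzero(traj.topology.is_ligand)]
        fspec = featurization.FeatureSpec(
            mode="ligand_contacts", transform=cfg.feature_transform,
            cutoff=cfg.feature_cutoff, ligand_atoms=lig_names,
        )
        dists = featurization.min_distance_matrix(traj, ligand_atoms=lig_names)
        residues = traj.topology.protein_residues
        labels = [(int(r), a) for r in residues for a in lig_names]
        features = featurization.transform_quasibinary(
            dists, fspec, labels, cfg.frame_spacing_ns
        )
        features.save(str(out / "features"))
        results["features"] = features
        results["distances"] = dists

        stage = "tica"
        tica_lag = cfg.lag_frames(cfg.tica_lag_ns)
        n_comp = min(cfg.n_tics, features.n_features)
        model = decomposition.tica(features, lag=tica_lag, n_components=n_comp)
        coords = decomposition.project(model, features)
        results["tica"] = model
        results["tic_coords"] = coords
        np.savez(out / "tic_coords.npz", **{f"traj_{i}": c for i, c in enumerate(coords)})

        stage = "cluster"
        k = min(cfg.n_microstates, sum(c.shape[0] for c in coords) // 10)
        micro = msm.cluster_microstates(coords, k=k, seed=cfg.seeds["cluster"])
        results["microstates"] = micro

        stage = "msm"
        msm_lag = cfg.lag_frames(cfg.msm_lag_ns)
        model_msm = msm.estimate_msm_from_assignments(
            micro.assignments, msm_lag, cfg.frame_spacing_ns, n_states=k
        )
        results["msm"] = model_msm
        weights = msm.compute_frame_weights(model_msm, micro.assignments)
        results["weights"] = weights
        _save_json(out / "msm.json", {
            "lag_frames": model_msm.lag_frames,
            "active_set": model_msm.active_set,
            "pi": model_msm.pi,
            "eigenvalues": model_msm.eigenvalues[:20],
        })
        if cfg.its_lags_ns:
            its = msm.implied_timescales(
                micro.assignments, [cfg.lag_frames(l) for l in cfg.its_lags_ns],
                frame_spacing_ns=cfg.frame_spacing_ns,
                n_bootstrap=cfg.n_bootstrap, seed=cfg.seeds["bootstrap"],
            )
            its.to_csv(out / "implied_timescales.csv", index=False)
            results["implied_timescales"] = its

        stage = "macrostates"
        gap = macrostates.select_n_macrostates(model_msm)
        n_macro = cfg.n_macrostates or gap.recommended_n
        macro = macrostates.build_macrostate_model(
            model_msm, micro.assignments, n_macro,
            core_threshold=cfg.core_threshold,
            n_bootstrap=cfg.n_bootstrap, seed=cfg.seeds["bootstrap"],
        )
        results["spectral_gap"] = gap
        results["macrostates"] = macro
        _save_json(out / "macrostates.json", {
            "recommended_n": gap.recommended_n,
            "confident": gap.confident,
            "n_macro": n_macro,
            "macro_pi": macro.macro_pi,
            "macro_pi_std": macro.macro_pi_std,
            "mfpt_ns": macro.mfpt,
            "mfpt_std_ns": macro.mfpt_std,
        })

        stage = "importance"
        pair_features = featurization.build_residue_pair_features(
            traj, cutoff_filter=cfg.pair_filter_cutoff
        )
        prof = importance.rf_importance(
            pair_features, macro.core_assignment,
            folds=cfg.folds, seed=cfg.seeds["importance"],
        )
        results["importance"] = prof
        prof.residue_table().to_csv(out / "residue_importance.csv", index=False)

        stage = "characterize"
        states = sorted(int(s) for s in np.unique(np.concatenate(macro.core_assignment))
                        if s >= 0)
        deltas = {}
        for i, a in enumerate(states):
            for b in states[i + 1:]:
                deltas[(a, b)] = characterize.contact_frequency_delta(
                    dists, macro.core_assignment, weights, a, b,
                    cutoff=cfg.feature_cutoff,
                )
        results["contact_deltas"] = deltas
        _save_json(out / "contact_deltas.json",
                   {f"{a}-{b}": v["delta"] for (a, b), v in deltas.items()})

        stage = "manifest"
        _save_json(out / "manifest.json", {
            "config": dataclasses.asdict(cfg),
            "stages": ["simulate", "featurize", "tica", "cluster", "msm",
                       "macrostates", "importance", "characterize"],
        })
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
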