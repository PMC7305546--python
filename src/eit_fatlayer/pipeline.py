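"""Stage runner binding the pipeline into reproducible, resumable runs.

Each stage writes its artifacts into a run directory together with the
producing config hash; downstream stages verify the hash so that artifacts
from different configurations can never be silently mixed.  Completed stages
are skipped on re-runs (idempotent).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .baseline import assemble_sensitivity, solve_regularized
from .config import ExperimentConfig
from .dataset import (
    LayeredConductivity,
    TrainingDataset,
    enumerate_specs,
    generate_dataset,
    spec_to_field,
)
from .errors import ValidationError
from .estimation import (
    geometry_transfer_experiment,
    reconstruct,
    robustness_screen,
    thickness_sweep,
)
from .forward import FEMOperator, make_protocol
from .geometry import build_mesh, compute_layers, make_domain, place_electrodes
from .io import write_msh
from .mlp import MLPConfig, MLPWeights, train_with_restarts
from .normalization import reference_set

logger = logging.getLogger(__name__)

STAGES = ("mesh", "dataset", "train", "reconstruct", "evaluate", "ablation",
          "robustness")


class Pipeline:
    """Materialized experiment context: mesh, operator, partition, reference."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.domain = make_domain(config.domain_kind, **config.domain_params)
        # a rigid electrode plate covers the same frontal arc in cm on any
        # body outline; plate_span_cm therefore beats the arc fraction
        span = (config.plate_span_cm / self.domain.perimeter
                if config.plate_span_cm else config.arc_span)
        self.electrodes = place_electrodes(
            self.domain, config.n_electrodes, span, config.electrode_width,
        )
        self.mesh = build_mesh(
            self.domain, self.electrodes, config.mesh_h,
            d0=config.d0, n_layers=config.L,
        )
        self.protocol = make_protocol(config.n_electrodes, config.current_mA)
        self.operator = FEMOperator(self.mesh, self.protocol)
        self.partition = compute_layers(
            self.mesh, config.d0, config.L, roi=config.roi
        )
        self.reference = reference_set(self.operator)

    # -- building blocks --------------------------------------------------
    def specs(self) -> list[LayeredConductivity]:
        c = self.config
        return enumerate_specs(
            c.L, c.gamma_f, c.gamma_m_array, c.gamma_r_array, c.enforce_order
        )

    def build_dataset(self) -> TrainingDataset:
        c = self.config
        ds = generate_dataset(
            self.operator, self.partition, self.specs(),
            ref=self.reference, noise=c.noise, seed=c.seed,
        )
        ds.provenance["config_hash"] = c.content_hash()
        return ds

    def mlp_config(self) -> MLPConfig:
        c = self.config
        return MLPConfig(
            layer_sizes=(self.protocol.n_measurements, *c.hidden, c.L),
            bias=c.bias, output_activation=c.output_activation, seed=c.seed,
        )

    def train_kwargs(self) -> dict:
        c = self.config
        return dict(
            lr=c.lr, lr_decay=c.lr_decay, lr_decay_every=c.lr_decay_every,
            batch_size=c.batch_size, epochs=c.epochs, patience=c.patience,
            val_frac=c.val_frac, input_transform=c.input_transform,
            input_clip=tuple(c.input_clip) if c.input_clip else None,
            select=c.select, seed=c.seed,
        )

    def fit(self, ds: TrainingDataset):
        return train_with_restarts(
            ds.inputs, ds.targets, self.mlp_config(),
            provenance=ds.provenance, **self.train_kwargs(),
        )


def _check_hash(meta_path: Path, config: ExperimentConfig, producer: str) -> None:
    if not meta_path.exists():
        raise ValidationError(
            f"missing upstream artifact {meta_path.name}; run the "
            f"'{producer}' stage first"
        )
    meta = json.loads(meta_path.read_text())
    if meta["config_hash"] != config.content_hash():
        raise ValidationError(
            f"artifact {meta_path.name} was produced by config "
            f"{meta['config_hash']}, current config is "
            f"{config.content_hash()}; re-run the '{producer}' stage"
        )


def run_pipeline(config: ExperimentConfig, stage: str, outdir) -> dict:
    """Execute one stage, writing artifacts plus provenance into ``outdir``."""
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    chash = config.content_hash()

    def _stamp(name: str, extra: dict | None = None) -> dict:
        meta = {"config_hash": chash, "stage": stage,
                "elapsed_s": round(time.time() - t0, 2), **(extra or {})}
        (out / f"{name}.meta.json").write_text(json.dumps(meta, indent=1))
        return meta

    if stage == "mesh":
        if (out / "mesh.meta.json").exists():
            _check_hash(out / "mesh.meta.json", config, "mesh")
            logger.info("mesh stage already complete; skipping")
            return json.loads((out / "mesh.meta.json").read_text())
        pipe = Pipeline(config)
        write_msh(pipe.mesh, out / "mesh.msh")
        return _stamp("mesh", {
            "mesh_hash": pipe.mesh.content_hash(),
            "n_nodes": pipe.mesh.n_nodes,
            "n_elements": pipe.mesh.n_elements,
        })

    if stage == "dataset":
        _check_hash(out / "mesh.meta.json", config, "mesh")
        if (out / "dataset.meta.json").exists():
            _check_hash(out / "dataset.meta.json", config, "dataset")
            logger.info("dataset stage already complete; skipping")
            return json.loads((out / "dataset.meta.json").read_text())
        pipe = Pipeline(config)
        ds = pipe.build_dataset()
        ds.save(out / "dataset.h5")
        return _stamp("dataset", {"n_rows": ds.n_rows,
                                  "dataset_hash": ds.content_hash()})

    if stage == "train":
        _check_hash(out / "dataset.meta.json", config, "dataset")
        if (out / "weights.meta.json").exists():
            _check_hash(out / "weights.meta.json", config, "train")
            logger.info("train stage already complete; skipping")
            return json.loads((out / "weights.meta.json").read_text())
        pipe = Pipeline(config)
        ds = TrainingDataset.load(out / "dataset.h5")
        weights, history = pipe.fit(ds)
        weights.save(out / "weights.h5")
        history.to_frame().to_csv(out / "training_log.csv", index=False)
        return _stamp("weights", weights.meta)

    # stages below need the trained model
    _check_hash(out / "weights.meta.json", config, "train")
    pipe = Pipeline(config)
    weights = MLPWeights.load(out / "weights.h5")

    if stage == "evaluate":
        tab = thickness_sweep(
            pipe.operator, pipe.partition, pipe.reference, weights,
            min_jump=config.min_jump,
        )
        tab.to_csv(out / "evaluation.csv", index=False)
        return _stamp("evaluation", {
            "max_thickness_pct_error": float(tab.thickness_pct_error.max()),
            "max_conductivity_pct_error": float(tab.conductivity_pct_error.max()),
        })

    if stage == "reconstruct":
        spec = LayeredConductivity(7, 14, config.gamma_f, 6.0, 4.5)
        field_r, _ = spec_to_field(spec, pipe.partition)
        V = pipe.operator.simulate(field_r)
        res = reconstruct(V, pipe.reference, weights, d0=config.d0,
                          min_jump=config.min_jump)
        res.profile().to_csv(out / "profile_mlp.csv", index=False)
        S = assemble_sensitivity(pipe.operator, pipe.partition)
        gb = solve_regularized(S, V)
        np.savetxt(out / "profile_baseline.csv", gb, header="conductivity")
        _, truth = spec_to_field(spec, pipe.partition)
        try:  # depth profile figure (optional plotting dependency)
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            depth = config.d0 * (np.arange(config.L) + 0.5)
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.step(depth, truth, where="mid", color="0.6", label="true")
            ax.step(depth, res.layer_values, where="mid", color="tab:blue",
                    label="learned map")
            ax.step(depth, gb, where="mid", color="tab:red",
                    label="regularized LS")
            ax.set_xlabel("depth from boundary (cm)")
            ax.set_ylabel("conductivity (relative)")
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            fig.savefig(out / "profile.png", dpi=120)
            plt.close(fig)
        except ImportError:
            pass
        return _stamp("reconstruction", {
            "fat_thickness_cm": res.fat_thickness_cm,
            "fat_conductivity": res.fat_conductivity_hat,
        })

    if stage == "ablation":
        ds = TrainingDataset.load(out / "dataset.h5")
        test_cfg = ExperimentConfig.from_dict(
            {**config.to_dict(), "domain_kind": "ellipse", "domain_params": {}}
        )
        test_pipe = Pipeline(test_cfg)
        rep = geometry_transfer_experiment(
            ds, test_pipe.operator, test_pipe.partition, test_pipe.reference,
            weights_norm=weights, config=pipe.mlp_config(),
            train_kwargs=pipe.train_kwargs(), min_jump=config.min_jump,
        )
        return _stamp("ablation", {
            "fat_thickness_true_cm": rep["fat_thickness_true_cm"],
            "fat_thickness_norm_cm": rep["normalized"].fat_thickness_cm,
            "fat_thickness_raw_cm": rep["raw"].fat_thickness_cm,
            "thickness_pct_error_normalized": rep["thickness_pct_error_normalized"],
            "thickness_pct_error_raw": rep["thickness_pct_error_raw"],
        })

    if stage == "robustness":
        tab = robustness_screen(
            pipe.operator, pipe.partition, pipe.reference, weights,
            seed=config.seed, min_jump=config.min_jump,
        )
        tab.to_csv(out / "robustness.csv", index=False)
        neg = tab[~tab.kind.str.startswith("control")]
        pos = tab[tab.kind.str.startswith("control")]
        return _stamp("robustness", {
            "fraction_without_structure": float(1 - neg.structure_detected.mean()),
            "controls_triggered": bool(pos.structure_detected.all()),
        })

    raise AssertionError("unreachable")
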