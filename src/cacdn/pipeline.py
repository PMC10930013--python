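"""End-to-end denoising workflow: simulate -> noise maps -> train -> subtract
-> evaluate.

Denoising itself is a single subtraction: ``I_denoise = I_thin - sigma_CNN``
where sigma_CNN is the network's whole-image noise estimate.  The
workflow runner orchestrates the stages, derives every random seed from
one base seed, and writes a manifest so that identical configurations
reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from cacdn import io as cio
from cacdn.metrics import EvalReport, evaluate
from cacdn.model import (DenseNoiseNet, ModelConfig, TrainConfig,
                         build_model, load_checkpoint, predict_noise,
                         save_checkpoint, train, _Adam)
from cacdn.noisemaps import NoiseMap, build_training_patches, real_noise_map
from cacdn.phantoms import (CIRS_NAMES, CTImage, GridSpec, ScanPair,
                            acquisition_protocol, make_phantom_spec,
                            simulate_scan)


@dataclass(frozen=True)
class WorkflowConfig:
    """Configuration of one reproducible denoising run."""

    mode: str = "full"                  # train | denoise | evaluate | full
    thicknesses: tuple[float, ...] = (1.5,)
    train_phantoms: tuple[str, ...] = ("CIRS_S",)
    eval_phantom: str = "QRM_S"
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str = "cacdn_run"
    checkpoint: str | None = None       # required for mode="denoise"

    def __post_init__(self) -> None:
        if self.mode not in ("train", "denoise", "evaluate", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.thicknesses:
            raise ValueError("at least one slice thickness required")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def denoise(thin: CTImage, model: DenseNoiseNet,
            model_thickness: float | None = None,
            noise_map: NoiseMap | None = None) -> CTImage:
    """Subtract the predicted quantum-noise map from a thin-slice image.

    ``model_thickness`` declares which z the model was trained for; a
    mismatch with the image is refused rather than silently denoised.
    ``noise_map`` substitutes a precomputed map (e.g. the real noise map
    as an oracle) for the network prediction.
    """
    if model_thickness is not None and \
            model_thickness != thin.slice_thickness:
        raise ValueError(
            f"model trained for z={model_thickness} mm applied to a "
            f"z={thin.slice_thickness} mm image")
    sigma = noise_map if noise_map is not None \
        else predict_noise(model, thin)
    if sigma.values.shape != thin.pixels.shape:
        raise ValueError("noise map grid does not match the image")
    out = thin.pixels.astype(np.float64) - sigma.values
    return thin.copy_with(out.astype(np.float32),
                          provenance=f"denoise({thin.provenance})")


class _StageLog:
    """JSON-lines stage log."""

    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "w")

    def emit(self, stage: str, **payload) -> None:
        rec = {"stage": stage, **payload}
        self._fh.write(json.dumps(rec) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def run_workflow(cfg: WorkflowConfig) -> dict:
    """Execute the configured stages and return the artifact manifest.

    Reruns with an identical configuration reproduce identical artifacts:
    all randomness is derived from ``cfg.seed``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "stages.jsonl")
    manifest: dict = {"config": asdict(cfg),
                      "config_hash": cfg.config_hash(),
                      "artifacts": {}}
    try:
        for z in cfg.thicknesses:
            ztag = f"z{z:g}mm"
            ckpt_path = out / f"model_{ztag}.npz"
            model: DenseNoiseNet | None = None

            if cfg.mode in ("train", "full"):
                log.emit("simulate", phantoms=list(cfg.train_phantoms), z=z)
                pairs = acquisition_protocol(cfg.train_phantoms, z,
                                             base_seed=cfg.seed)
                log.emit("patches", n_datasets=len(pairs))
                ps = build_training_patches(pairs, shuffle_seed=cfg.seed)
                log.emit("train", n_patches=len(ps),
                         iterations=cfg.training.max_iterations)
                model = build_model(cfg.model, seed=cfg.seed)
                opt = _Adam(model, cfg.training)
                state = train(model, ps, cfg.training, optimizer=opt)
                save_checkpoint(ckpt_path, model, cfg.training, opt,
                                state.iteration, state.loss_history)
                manifest["artifacts"][f"checkpoint_{ztag}"] = str(ckpt_path)
                manifest["artifacts"][f"loss_history_{ztag}"] = \
                    state.loss_history
            elif cfg.mode in ("denoise", "evaluate"):
                src = cfg.checkpoint
                if src is None:
                    raise FileNotFoundError(
                        f"mode={cfg.mode!r} requires a model checkpoint; "
                        "none was configured")
                model, *_ = load_checkpoint(src)

            if cfg.mode == "train":
                continue

            # held-out validation series
            spec = make_phantom_spec(cfg.eval_phantom)
            pair = simulate_scan(spec, z=z, seed=cfg.seed + 1000)
            den = denoise(pair.thin, model, model_thickness=z)
            series_dir = out / f"denoised_{cfg.eval_phantom}_{ztag}"
            cio.write_series(den, series_dir, backend="array")
            manifest["artifacts"][f"denoised_{ztag}"] = str(series_dir)
            log.emit("denoise", phantom=cfg.eval_phantom, z=z)

            if cfg.mode in ("evaluate", "full"):
                report = evaluate(den, pair.thick, spec,
                                  image_name=f"I_denoise_{ztag}",
                                  reference_name="I_3mm")
                rpath = out / f"eval_{cfg.eval_phantom}_{ztag}.json"
                report.to_json(rpath)
                manifest["artifacts"][f"eval_{ztag}"] = str(rpath)
                log.emit("evaluate", rmse=report.rmse, psnr=report.psnr)
    except Exception as exc:  # name the failing stage, then re-raise
        log.emit("error", error=str(exc))
        log.close()
        raise
    log.close()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def oracle_denoise(pair: ScanPair) -> CTImage:
    """Denoise with the *real* noise map instead of the network.

    By construction this recovers the 3-mm image exactly (the subtraction
    identity), which is the closure check for the whole pipeline.
    """
    sigma = real_noise_map(pair.thick, pair.thin)
    return denoise(pair.thin, model=None, noise_map=sigma)
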