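"""End-to-end pipeline: simulate -> split -> train -> evaluate -> report.

Each stage writes its artifact under the run directory and is skipped on
re-run when the artifact already exists for the same config hash, so a
pipeline can resume from any completed stage. A manifest ties every
artifact to the global seed and the config hash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as bio
from .config import RunConfig, stage_seed
from .core import SplitIndices
from .metrics import baseline_filters, evaluate_set
from .model import build_discriminator, build_generator
from .preprocess import split_dataset
from .simulate import generate_paired_dataset
from .training import infer, load_checkpoint, save_checkpoint, train

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a dict of artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    manifest = {"seed": config.seed, "config_hash": chash, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            manifest = old
    config.save(out / "config.yaml")

    def done(stage, path):
        manifest["stages"][stage] = str(path)
        manifest_path.write_text(json.dumps(manifest, indent=1))

    # --- simulate ---
    data_path = out / "pairs.h5"
    if manifest["stages"].get("simulate") and data_path.exists():
        log.info("simulate: reusing %s", data_path)
        pairs, _ = bio.load_pairs_hdf5(data_path)
    else:
        pairs, pair_manifest = generate_paired_dataset(
            config.n_pairs,
            config.geometry,
            config.jitter,
            seed=stage_seed(config.seed, "simulate"),
            crop_size=config.crop_size,
            crops_per_scene=config.crops_per_scene,
            noise_sigma=config.noise_sigma,
            ref_pixel_um=config.ref_pixel_um,
        )
        bio.save_pairs_hdf5(data_path, pairs, pair_manifest)
        done("simulate", data_path)

    # --- split ---
    split_path = out / "split.json"
    if manifest["stages"].get("split") and split_path.exists():
        d = json.loads(split_path.read_text())
        split = SplitIndices(tuple(d["train"]), tuple(d["validation"]), tuple(d["test"]))
    else:
        split = split_dataset(
            len(pairs),
            config.test_frac,
            config.val_frac,
            seed=stage_seed(config.seed, "split"),
        )
        split_path.write_text(
            json.dumps(
                {"train": split.train, "validation": split.validation, "test": split.test}
            )
        )
        done("split", split_path)

    # --- train ---
    ckpt_path = out / "generator.npz"
    if manifest["stages"].get("train") and ckpt_path.exists():
        log.info("train: reusing %s", ckpt_path)
        generator = load_checkpoint(ckpt_path)
    else:
        import dataclasses

        generator = build_generator(config.generator)
        discriminator = build_discriminator(config.discriminator)
        tcfg = dataclasses.replace(config.training, seed=stage_seed(config.seed, "train"))
        result = train(generator, discriminator, pairs, split, tcfg)
        save_checkpoint(
            ckpt_path,
            result.generator,
            meta={"best_epoch": result.best_epoch, "best_val_ssim": result.best_val_ssim},
        )
        result.log_frame().to_csv(out / "training_log.csv", index=False)
        generator = result.generator
        done("train", ckpt_path)

    # --- evaluate ---
    report_path = out / "report.csv"
    if not (manifest["stages"].get("evaluate") and report_path.exists()):
        test_pairs = [pairs[i] for i in split.test]
        methods = {
            "bicubic": lambda im: baseline_filters(im, "bicubic"),
            "bilateral": lambda im: baseline_filters(im, "bilateral"),
            "median": lambda im: baseline_filters(im, "median"),
            "model": lambda im: infer(generator, im),
        }
        report = evaluate_set(test_pairs, methods)
        report.to_csv(report_path)
        report.per_image.to_json(out / "per_image_metrics.json", orient="records")
        done("evaluate", report_path)

    return dict(manifest["stages"])
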