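"""End-to-end orchestration: synth -> split -> patch prep -> train -> eval.

Every stage communicates through files under the run's output
directory, so a later stage can resume from a previous run's artifacts:

    out/
      config.yaml           # the resolved configuration, echoed back
      data/                 # synthetic samples (when generated)
      patches/{train,validation,test}/   # paired *_img.png / *_mask.png
      patches/balance.csv   # per-image grid and filter report
      run/history.csv       # per-epoch training log
      run/best_weights.npz  # best checkpoint (by validation F1)
      report.json           # test-set metrics
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from nucseg.ada import ADAParams, Patch, prepare_patch_dataset
from nucseg.io_dataset import load_dataset, split_dataset, write_mask
from nucseg.model import build_network, default_spec
from nucseg.synth import SynthConfig, generate_dataset, write_dsb_layout
from nucseg.training import TrainConfig, evaluate, patches_to_arrays, train

logger = logging.getLogger(__name__)

STAGES = ("synth", "prepare", "train", "eval")


@dataclass
class RunConfig:
    out_dir: Path
    data_dir: Path | None = None          # existing dataset; None -> synthesize
    ada: ADAParams = field(default_factory=ADAParams)
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    width_divisor: int = 1
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_synth_images: int = 64
    size_jitter: tuple[int, int] = (128, 192)
    split_seed: int = 42
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.data_dir is not None:
            self.data_dir = Path(self.data_dir)

    def echo(self) -> None:
        doc = {
            "out_dir": str(self.out_dir),
            "data_dir": str(self.data_dir) if self.data_dir else None,
            "ada": dataclasses.asdict(self.ada),
            "train": dataclasses.asdict(self.train_cfg),
            "width_divisor": self.width_divisor,
            "synth": dataclasses.asdict(self.synth),
            "n_synth_images": self.n_synth_images,
            "size_jitter": list(self.size_jitter),
            "split_seed": self.split_seed,
            "log_level": self.log_level,
        }
        self.out_dir.mkdir(parents=True, exist_ok=True)
        with open(self.out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        synth_doc = doc.get("synth", {})
        if "radius_range" in synth_doc:
            synth_doc["radius_range"] = tuple(synth_doc["radius_range"])
        return cls(
            out_dir=Path(doc["out_dir"]),
            data_dir=Path(doc["data_dir"]) if doc.get("data_dir") else None,
            ada=ADAParams(**doc.get("ada", {})),
            train_cfg=TrainConfig(**doc.get("train", {})),
            width_divisor=doc.get("width_divisor", 1),
            synth=SynthConfig(**synth_doc),
            n_synth_images=doc.get("n_synth_images", 64),
            size_jitter=tuple(doc.get("size_jitter", (128, 192))),
            split_seed=doc.get("split_seed", 42),
            log_level=doc.get("log_level", "INFO"),
        )


# -- patch persistence ---------------------------------------------------

def save_patches(patch_dir: Path, patches: list[Patch]) -> None:
    patch_dir.mkdir(parents=True, exist_ok=True)
    seen: dict[str, int] = {}
    for p in patches:
        stem = f"{p.source_id}_{p.row0}_{p.col0}"
        n = seen.get(stem, 0)
        seen[stem] = n + 1
        if n:
            stem = f"{stem}_aug{n}"
        iio.imwrite(patch_dir / f"{stem}_img.png", p.image)
        write_mask(patch_dir / f"{stem}_mask.png", p.mask)


def load_patches(patch_dir: Path) -> list[Patch]:
    patches = []
    for img_path in sorted(patch_dir.glob("*_img.png")):
        stem = img_path.name[:-len("_img.png")]
        mask = (np.asarray(iio.imread(patch_dir / f"{stem}_mask.png")) > 0
                ).astype(np.uint8)
        image = np.asarray(iio.imread(img_path))
        parts = stem.split("_")
        aug = parts[-1].startswith("aug")
        row0, col0 = (parts[-3], parts[-2]) if aug else (parts[-2], parts[-1])
        patches.append(Patch(image=image, mask=mask,
                             source_id="_".join(parts[:-3 if aug else -2]),
                             row0=int(row0), col0=int(col0),
                             foreground_count=int(mask.sum())))
    return patches


# -- pipeline ------------------------------------------------------------

def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] = STAGES) -> dict[str, float]:
    """Execute the requested stages; returns the final metrics report
    (empty dict when ``eval`` is not among the stages).

    Stages not requested are resumed from artifacts already present in
    the output directory.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    logging.basicConfig(level=config.log_level)
    config.echo()
    out = config.out_dir
    patches_dir = out / "patches"
    run_dir = out / "run"

    data_dir = config.data_dir
    if "synth" in stages and data_dir is None:
        data_dir = out / "data"
        logger.info("stage synth: %d images -> %s", config.n_synth_images, data_dir)
        samples = generate_dataset(config.n_synth_images, config.synth,
                                   size_jitter=config.size_jitter)
        write_dsb_layout(data_dir, samples)
    elif data_dir is None:
        data_dir = out / "data"

    if "prepare" in stages:
        logger.info("stage prepare: %s -> %s", data_dir, patches_dir)
        records = load_dataset(data_dir)
        split = split_dataset(records, seed=config.split_seed)
        ensembles, report = prepare_patch_dataset(split, config.ada)
        for subset, patches in ensembles.items():
            save_patches(patches_dir / subset, patches)
        report.to_csv(patches_dir / "balance.csv", index=False)

    if "train" in stages:
        logger.info("stage train: %s", run_dir)
        train_patches = load_patches(patches_dir / "train")
        val_patches = load_patches(patches_dir / "validation")
        spec = default_spec(width_divisor=config.width_divisor,
                            dropout_rate=config.train_cfg.dropout)
        model = build_network(spec, seed=config.train_cfg.seed)
        train(model, train_patches, val_patches, config.train_cfg,
              out_dir=run_dir)

    report_dict: dict[str, float] = {}
    if "eval" in stages:
        logger.info("stage eval")
        spec = default_spec(width_divisor=config.width_divisor,
                            dropout_rate=config.train_cfg.dropout)
        model = build_network(spec, seed=config.train_cfg.seed)
        model.load_weights(run_dir / "best_weights.npz")
        test_patches = load_patches(patches_dir / "test")
        X, Y = patches_to_arrays(test_patches)
        metrics, loss = evaluate(model, X, Y,
                                 batch_size=config.train_cfg.batch_size)
        report_dict = metrics.to_dict()
        report_dict["test_loss"] = loss
        report_dict["n_test_patches"] = len(test_patches)
        with open(out / "report.json", "w") as fh:
            json.dump(report_dict, fh, indent=2)
    return report_dict
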