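"""High-level pipeline: generate -> train -> predict -> evaluate -> visualize.

These functions wire the library modules together exactly as the
command-line interface exposes them; the CLI in :mod:`aswnet.cli` is a
thin wrapper.  A run is described by a YAML config with nested blocks
(``synth``, ``preprocess``, ``model``, ``train``, ``postprocess``) and a
frozen ``schema_version``.

Images whose dimensions are not divisible by 8 (e.g. the common
520 x 696 field of view) are reflect-padded up to the next multiple
before the forward pass and the logits cropped back, so predictions
exist at native resolution.
"""

from __future__ import annotations

import csv
import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ManifestError, NotFound
from .io import (GrayImage, InstanceMask, ProbMap, read_image, read_label_map,
                 write_label_map, write_prob_map)
from .metrics import MetricReport, area_correlation, evaluate, mean_report
from .network import (ModelHandle, NetworkConfig, build_model, load_checkpoint,
                      save_checkpoint)
from .postprocess import PostprocessConfig, run_postprocess
from .preprocess import (PreprocessConfig, apply_transform, compute_class_weights,
                         instance_to_three_class, list_transforms,
                         normalize_grayscale)
from .synthetic import SynthConfig, generate_dataset, preset
from .training import TrainConfig, train

__all__ = [
    "PipelineConfig", "load_config", "save_config",
    "run_generate", "run_train", "run_predict", "run_evaluate",
    "run_visualize", "pad_to_multiple", "predict_image",
]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    variant: str = "asw"
    run_dir: str = "runs/default"
    splits: tuple[int, int, int] = (100, 50, 50)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in vars(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config: PipelineConfig, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **_to_plain(config)}
    doc["train"].pop("weights", None)  # derived from data, not configured
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema {doc.get('schema_version')}")
    def build(cls, key, **fix):
        block = dict(doc.get(key) or {})
        block.update(fix)
        for k, v in block.items():
            if isinstance(v, list):
                block[k] = tuple(v)
        return cls(**block)
    return PipelineConfig(
        synth=build(SynthConfig, "synth"),
        preprocess=build(PreprocessConfig, "preprocess"),
        model=build(NetworkConfig, "model"),
        train=build(TrainConfig, "train"),
        postprocess=build(PostprocessConfig, "postprocess"),
        variant=doc.get("variant", "asw"),
        run_dir=doc.get("run_dir", "runs/default"),
        splits=tuple(doc.get("splits", (100, 50, 50))),
    )


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------

def run_generate(config: PipelineConfig, out_dir=None, preset_name: str | None = None,
                 log=print) -> Path:
    """Write a synthetic dataset; returns the manifest path."""
    synth = config.synth
    splits = config.splits
    if preset_name:
        synth, splits = preset(preset_name)
        synth = dataclasses.replace(synth, rng_seed=config.synth.rng_seed)
    out_dir = Path(out_dir or Path(config.run_dir) / "data")
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = generate_dataset(synth, *splits, out_dir)
    log(f"[generate] seed={synth.rng_seed} splits={splits} "
        f"manifest={manifest} ({time.time() - t0:.1f}s)")
    return manifest


def read_manifest(manifest_path) -> dict[str, list[tuple[Path, Path]]]:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise NotFound(str(manifest_path))
    out: dict[str, list[tuple[Path, Path]]] = {"train": [], "val": [], "test": []}
    with open(manifest_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.setdefault(row["split"], []).append(
                (Path(row["image_path"]), Path(row["mask_path"])))
    return out


# ---------------------------------------------------------------------------
# train
# ---------------------------------------------------------------------------

def _load_split(pairs, pre: PreprocessConfig):
    samples = []
    for image_path, mask_path in pairs:
        image = normalize_grayscale(read_image(image_path), pre)
        label = instance_to_three_class(read_label_map(mask_path), pre.boundary_width)
        samples.append((image.pixels.astype(np.float32),
                        label.classes.astype(np.int64)))
    return samples


def run_train(config: PipelineConfig, manifest_path, log=print
              ) -> tuple[Path, Path]:
    """Train the configured variant; returns (checkpoint path, log CSV path)."""
    splits = read_manifest(manifest_path)
    pre = config.preprocess
    train_samples = _load_split(splits["train"], pre)
    val_samples = _load_split(splits["val"], pre)

    from .io import ThreeClassLabel
    weights = compute_class_weights(
        ThreeClassLabel(classes=t.astype(np.int8)) for _, t in train_samples)
    tcfg = dataclasses.replace(config.train, weights=weights)
    model = build_model(config.variant, config.model)
    log(f"[train] variant={config.variant} params={model.parameter_count} "
        f"weights=({weights.w_background:.3f}, {weights.w_interior:.3f}, "
        f"{weights.w_boundary:.3f}) seed={tcfg.rng_seed}")

    transforms = list_transforms(pre)

    def augmenter(im, tgt, rng):
        rot, flip = transforms[rng.integers(len(transforms))]
        return apply_transform(im, rot, flip), apply_transform(tgt, rot, flip)

    t0 = time.time()
    model, history = train(model, train_samples, val_samples, tcfg,
                           augmenter=augmenter, log=log)
    log(f"[train] best_epoch={history.best_epoch} "
        f"stopped_early={history.stopped_early} ({time.time() - t0:.1f}s)")

    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    ckpt = run_dir / "best.npz"
    save_checkpoint(model, ckpt)
    log_csv = run_dir / "training_log.csv"
    with open(log_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss", "lr"])
        for i, (tl, vl) in enumerate(zip(history.train_loss, history.val_loss)):
            writer.writerow([i, f"{tl:.6f}", f"{vl:.6f}",
                             tcfg.initial_learning_rate])
    return ckpt, log_csv


# ---------------------------------------------------------------------------
# predict
# ---------------------------------------------------------------------------

def pad_to_multiple(arr: np.ndarray, multiple: int = 8) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad a 2-D array so both dims divide ``multiple``."""
    H, W = arr.shape
    ph = (-H) % multiple
    pw = (-W) % multiple
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)), mode="reflect")
    return arr, (H, W)


def predict_image(model: ModelHandle, image: GrayImage,
                  pre: PreprocessConfig | None = None) -> ProbMap:
    """Normalize, reflect-pad to a multiple of 8, forward, crop."""
    pre = pre or PreprocessConfig()
    norm = normalize_grayscale(image, pre)
    padded, (H, W) = pad_to_multiple(norm.pixels, 8)
    probs = model.forward(padded[None])[0][:, :H, :W]
    # renormalize after cropping (softmax is per pixel, crop preserves it)
    return ProbMap(probs=probs)


def run_predict(config: PipelineConfig, checkpoint, image_paths, out_dir,
                log=print) -> list[tuple[Path, Path]]:
    """Predict instance masks; returns (prob map path, mask path) pairs."""
    model = load_checkpoint(checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for image_path in map(Path, image_paths):
        t0 = time.time()
        prob = predict_image(model, read_image(image_path), config.preprocess)
        mask = run_postprocess(prob, config.postprocess)
        prob_path = out_dir / f"{image_path.stem}_prob.tif"
        mask_path = out_dir / f"{image_path.stem}_instances.tif"
        write_prob_map(prob, prob_path)
        write_label_map(mask, mask_path)
        log(f"[predict] {image_path.name}: {mask.n_instances} instances "
            f"({time.time() - t0:.1f}s, method={config.postprocess.method})")
        results.append((prob_path, mask_path))
    return results


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def _pair_files(pred_dir: Path, truth_dir: Path) -> list[tuple[Path, Path]]:
    preds = sorted(p for p in pred_dir.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff") and "prob" not in p.stem)
    pairs = []
    for p in preds:
        stem = p.stem.replace("_instances", "")
        candidates = [truth_dir / f"{stem}{suf}" for suf in (".tif", ".tiff")]
        candidates += [truth_dir / f"{stem.replace('image', 'mask')}{suf}"
                       for suf in (".tif", ".tiff")]
        match = next((c for c in candidates if c.exists()), None)
        if match is None:
            raise ManifestError(f"no ground truth found for {p.name}")
        pairs.append((p, match))
    if not pairs:
        raise ManifestError(f"no predictions found in {pred_dir}")
    return pairs


def run_evaluate(pred_dir, truth_dir, out_csv=None, percent: bool = False,
                 log=print) -> tuple[list[MetricReport], MetricReport]:
    """Score every prediction against its ground truth; returns per-image
    reports and their unweighted mean."""
    pairs = _pair_files(Path(pred_dir), Path(truth_dir))
    reports = []
    names = []
    for pred_path, truth_path in pairs:
        rep = evaluate(read_label_map(pred_path), read_label_map(truth_path))
        reports.append(rep)
        names.append(pred_path.stem)
    mean = mean_report(reports)
    if out_csv is not None:
        keys = ["dice1", "dice2", "aji", "dq", "sq", "pq", "tp", "fp", "fn"]
        with open(out_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image"] + keys)
            for name, rep in zip(names, reports):
                d = rep.as_dict(percent=percent)
                writer.writerow([name] + [d[k] for k in keys])
            d = mean.as_dict(percent=percent)
            writer.writerow(["mean"] + [d[k] for k in keys])
    scale = 100.0 if percent else 1.0
    log(f"[evaluate] n={len(reports)} mean: dice1={mean.dice1 * scale:.4f} "
        f"dice2={mean.dice2 * scale:.4f} aji={mean.aji * scale:.4f} "
        f"dq={mean.dq * scale:.4f} sq={mean.sq * scale:.4f} pq={mean.pq * scale:.4f}")
    return reports, mean


def dataset_area_correlation(pred_masks: list[InstanceMask],
                             truth_masks: list[InstanceMask]) -> float:
    """Pearson r between matched nucleus areas pooled over a dataset."""
    ga, pa = [], []
    for pred, truth in zip(pred_masks, truth_masks):
        try:
            _, detail = area_correlation(pred, truth)
        except Exception:
            continue
        for _, _, g_area, p_area in detail["pairs"]:
            ga.append(g_area)
            pa.append(p_area)
    if len(ga) < 3:
        from .errors import InsufficientPairs
        raise InsufficientPairs("fewer than 3 matched nuclei across dataset")
    from scipy import stats
    return float(stats.pearsonr(np.array(ga, float), np.array(pa, float))[0])


# ---------------------------------------------------------------------------
# visualize
# ---------------------------------------------------------------------------

def run_visualize(checkpoint, image_path, what: str, out_dir, log=print) -> list[Path]:
    """Save channel grids of feature maps or attention coefficients.

    ``what`` is ``features`` (the five characteristic conv-block depths)
    or ``attention`` (the three gates' coefficient maps, min-max scaled
    for display with the true range annotated).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .errors import UnknownLayer
    model = load_checkpoint(checkpoint)
    image = read_image(Path(image_path))
    norm = normalize_grayscale(image)
    padded, _ = pad_to_multiple(norm.pixels, 8)
    model.forward_logits(padded[None, None].astype(np.float32),
                         training=False, capture=True)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if what == "features":
        for name in model.feature_blocks:
            fmap = model.activations[name][0]  # (C, h, w)
            C = fmap.shape[0]
            ncol = int(np.ceil(np.sqrt(C)))
            nrow = int(np.ceil(C / ncol))
            fig, axes = plt.subplots(nrow, ncol, figsize=(2 * ncol, 2 * nrow))
            for ch, ax in zip(range(C), np.atleast_1d(axes).ravel()):
                ax.imshow(fmap[ch], cmap="viridis")
                ax.set_title(f"ch {ch}", fontsize=6)
            for ax in np.atleast_1d(axes).ravel():
                ax.axis("off")
            path = out_dir / f"features_{name}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    elif what == "attention":
        maps = model.attention_maps()  # raises UnknownLayer on gate-less nets
        for name, coeff in maps.items():
            arr = coeff[0, 0]
            lo, hi = float(arr.min()), float(arr.max())
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow((arr - lo) / max(hi - lo, 1e-12), cmap="magma")
            ax.set_title(f"{name} coefficients (range {lo:.3f}..{hi:.3f})")
            ax.axis("off")
            path = out_dir / f"attention_{name}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    else:
        raise ValueError("what must be 'features' or 'attention'")
    for p in written:
        log(f"[visualize] wrote {p}")
    return written
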