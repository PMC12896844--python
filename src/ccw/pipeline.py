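"""End-to-end pipeline orchestration.

Runs synth -> split -> train -> eval -> segment -> refine -> measure ->
regress on a single YAML-style config dict, writing every stage's artifacts
plus a provenance manifest (config hash, seed, package version) under the
output directory.  Every stage is a pure function of (inputs, config, seed),
so a rerun with identical config and seed reproduces the report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .dataset_io import LabelMask, build_split
from .metrics import evaluate_masks
from .morphometry import StructuringElement, measure_areas, refine_mask
from .network import NetConfig, build_model, predict_mask
from .regression import MODS, assemble_features, evaluate_all
from .synthetic import generate_dataset
from .train import TrainConfig, save_checkpoint, train as train_loop


def _hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict, out_dir: Path, log=None) -> dict:
    """Execute the full pipeline; returns {'summary': ..., 'paths': ...}.

    Config keys (all optional): seed, synth {n_carcasses, canvas, replicates},
    network {...NetConfig fields...}, train {...TrainConfig fields...},
    se {shape, radius}, regression {models, mods, n_bootstrap}.
    """
    def say(msg):
        if log is not None:
            log(msg)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stage = "configure"
    try:
        synth_cfg = dict(cfg.get("synth", {}))
        n_carc = int(synth_cfg.get("n_carcasses", 12))
        canvas = int(synth_cfg.get("canvas", 64))
        replicates = int(synth_cfg.get("replicates", 3))

        net_d = dict(cfg.get("network", {}))
        net_d.setdefault("depth", 3)
        net_d.setdefault("base_width", 8)
        net_d.setdefault("input_size", canvas)
        net_d.setdefault("cbam_reduction", 4)
        net_d.setdefault("sk_reduction", 4)
        net_cfg = NetConfig.from_dict(net_d)

        tr_d = {k: v for k, v in dict(cfg.get("train", {})).items()
                if k in TrainConfig.__dataclass_fields__}
        tr_d.setdefault("input_size", canvas)
        tr_d.setdefault("batch_size", 4)
        tr_d.setdefault("epochs", 10)
        tr_d["seed"] = seed
        if "loss_weights" in tr_d:
            tr_d["loss_weights"] = tuple(tr_d["loss_weights"])
        train_cfg = TrainConfig(**tr_d)
        train_cfg.validate()

        se_d = dict(cfg.get("se", {}))
        se = StructuringElement(se_d.get("shape", "disk"),
                                int(se_d.get("radius",
                                             max(1, round(5 * canvas / 640)))))
        reg_cfg = dict(cfg.get("regression", {}))

        stage = "synth"
        manifest = generate_dataset(n_carc, replicates=replicates, seed=seed,
                                    canvas=canvas)
        manifest.to_csv(out_dir / "images.csv", out_dir / "weights.csv")
        say(f"[synth] {len(manifest.images)} image records")

        stage = "split"
        split = build_split(sorted(manifest.specs), seed=seed)
        pd.DataFrame(
            [{"carcass_id": k, "subset": v}
             for k, v in sorted(split.assignment.items())]
        ).to_csv(out_dir / "split.csv", index=False)

        stage = "render"
        samples = {cid: manifest.render_carcass(cid) for cid in manifest.specs}
        pairs: dict[str, list] = {"train": [], "val": [], "test": []}
        test_items = []
        for cid, sample in samples.items():
            subset = split.assignment[cid]
            for (view, rep), im in sample["images"].items():
                pairs[subset].append((im, sample["masks"][(view, rep)]))
                if subset == "test":
                    test_items.append((cid, view, rep, im,
                                       sample["masks"][(view, rep)]))

        stage = "train"
        model = build_model(net_cfg, seed=seed)
        hist = train_loop(model, pairs, train_cfg, log=log)
        if hist.best_state is not None:
            model.load_state_dict(hist.best_state)
        save_checkpoint(model, out_dir / "checkpoint.npz", seed=seed,
                        epoch=hist.best_epoch)
        pd.DataFrame(hist.records).to_csv(out_dir / "history.csv", index=False)

        stage = "segment+eval"
        model.eval()
        seg = [(predict_mask(model, im), gt)
               for _, _, _, im, gt in test_items]
        seg_m = evaluate_masks(seg, net_cfg.n_classes)
        say(f"[eval] test mIoU {seg_m['miou']:.4f}")

        stage = "measure"
        # areas from refined ground-truth masks (regression ground truth path)
        frames = []
        for cid, sample in samples.items():
            ppc = manifest.specs[cid].px_per_cm
            for (view, rep), labels in sample["masks"].items():
                refined = refine_mask(LabelMask(labels), se)
                frames.append(measure_areas(refined, ppc, carcass_id=cid,
                                            view=view, replicate=rep))
        areas = pd.concat(frames, ignore_index=True)
        areas.to_csv(out_dir / "areas.csv", index=False)

        stage = "regress"
        mods = reg_cfg.get("mods", sorted(MODS))
        models = reg_cfg.get("models", ["bayes", "lgbm"])
        tables = {m: assemble_features(areas, manifest.weights, m)
                  for m in mods}
        results = evaluate_all(tables, split, seed=seed, models=models,
                               n_bootstrap=int(reg_cfg.get("n_bootstrap", 200)))
        results.to_csv(out_dir / "regression.csv", index=False)

        stage = "report"
        summary = {
            "config_hash": _hash(cfg), "seed": seed, "version": __version__,
            "n_carcasses": n_carc, "n_images": int(len(manifest.images)),
            "best_val_miou": round(hist.best_miou, 6),
            "test_miou": round(seg_m["miou"], 6),
            "test_dice_foreground": round(float(seg_m["dice"][1:].mean()), 6),
            "regression": [
                {k: (round(v, 6) if isinstance(v, float) else v)
                 for k, v in row.items()}
                for row in results.to_dict("records")
            ],
        }
        (out_dir / "report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        return {"summary": summary,
                "paths": sorted(str(p.name) for p in out_dir.iterdir())}
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
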