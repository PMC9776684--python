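"""End-to-end orchestration of the two-stage subtyping algorithm.

Stage order: simulate -> train-seg (3-fold TMA cross-validation) ->
segment (heatmaps + masks) -> register (anchor-based affine fits) ->
preprocess (spectral chain) -> assemble (MALDI1/2/3 variants and the four
evaluation subsets) -> train-cls -> classify -> aggregate (verdicts,
tables, report).

Every stage writes its artifacts under the run directory together with a
stamp recording a content hash of the configuration slice and upstream
stamps it depends on; a stage re-runs only when its stamp no longer
matches, so deleting one stage's outputs recomputes that stage and
everything downstream while cached upstream artifacts are reused.  One
global seed deterministically derives all stage seeds.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .aggregate import EvaluationReport, evaluate_cohort
from .classifier import (
    SpecTrainConfig, StubSpecModel, assemble_training_variants, build_eval_datasets,
    IsotopeNet1d, predict_spectra, train_spectrum_classifier,
)
from .errors import StageError
from .preprocess import PreprocessConfig, baseline_correct, run_pipeline
from .register import AffineTransform2D, anchor_rmse, fit_affine, transfer_mask_to_spots
from .segmentation import (
    SegTrainConfig, StubSegModel, UNet, binarize, compute_iou, compute_iou_averaged,
    crossvalidate_segmentation, downsample_mask, predict_heatmap,
)
from .synthetic import CohortConfig, generate_cohort
from .types import BinaryMask, MsiDataset

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "train_seg", "segment", "register",
    "preprocess", "assemble", "train_cls", "classify", "aggregate",
)


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    outdir: str = "runs/default"
    seed: int = 0
    qc_threshold: float = 0.9
    dry_run: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seg: SegTrainConfig = field(default_factory=lambda: SegTrainConfig(
        downsample=2, base_width=8, epochs=8, repetitions=2, tiles_per_epoch=24))
    cls: SpecTrainConfig = field(default_factory=lambda: SpecTrainConfig(
        epochs=15, repetitions=2, channels=8))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["scene_shape"] = list(d["cohort"]["scene_shape"])
        d["cohort"]["mz_range"] = list(d["cohort"]["mz_range"])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("cohort", CohortConfig), ("preprocess", PreprocessConfig),
                         ("seg", SegTrainConfig), ("cls", SpecTrainConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                })
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class Pipeline:
    """Stateful runner holding configuration, caches and stage artifacts."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.stampdir = self.outdir / "stamps"
        self.stampdir.mkdir(exist_ok=True)
        self._mem: dict = {}
        logging.basicConfig(
            level=logging.INFO,
            format="%(asctime)s %(name)s %(levelname)s %(message)s",
        )

    # ------------------------------------------------------------------
    # seeds, stamps
    # ------------------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([int(self.cfg.seed), idx])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def _stamp_path(self, stage: str) -> Path:
        return self.stampdir / f"{stage}.json"

    def _check_stamp(self, stage: str, payload) -> bool:
        p = self._stamp_path(stage)
        if not p.exists():
            return False
        return json.loads(p.read_text()).get("hash") == _hash(payload)

    def _write_stamp(self, stage: str, payload) -> None:
        self._stamp_path(stage).write_text(json.dumps(
            {"hash": _hash(payload), "executed_at": time.time()}
        ))

    def _stamp_token(self, stage: str):
        p = self._stamp_path(stage)
        return json.loads(p.read_text()) if p.exists() else None

    # ------------------------------------------------------------------
    # stage: simulate
    # ------------------------------------------------------------------
    @property
    def cohort_dir(self) -> Path:
        return self.outdir / "cohort"

    def simulate(self) -> pd.DataFrame:
        payload = [dataclasses.asdict(self.cfg.cohort), self.cfg.seed]
        manifest_path = self.cohort_dir / "manifest.csv"
        if self._check_stamp("simulate", payload) and manifest_path.exists():
            log.info("stage simulate: cached")
        else:
            log.info("stage simulate: generating cohort")
            try:
                generate_cohort(self.cfg.cohort, self.stage_seed("simulate"), self.cohort_dir)
            except Exception as exc:
                raise StageError("simulate", str(exc)) from exc
            self._write_stamp("simulate", payload)
        manifest = pd.read_csv(manifest_path)
        self._mem["manifest"] = manifest
        return manifest

    def manifest(self) -> pd.DataFrame:
        if "manifest" not in self._mem:
            self.simulate()
        return self._mem["manifest"]

    def _sample_path(self, row, col) -> Path:
        return self.cohort_dir / row[col]

    # ------------------------------------------------------------------
    # stage: train_seg
    # ------------------------------------------------------------------
    def _load_seg_model(self, name: str):
        if self.cfg.dry_run:
            return StubSegModel(0.7)
        path = self.outdir / "models" / f"{name}.npz"
        model = UNet(depth=self.cfg.seg.depth, base_width=self.cfg.seg.base_width, seed=0)
        with np.load(path) as z:
            model.set_state([z[k] for k in sorted(z.files, key=lambda s: int(s[4:]))])
        return model

    def train_seg(self):
        manifest = self.manifest()
        payload = [dataclasses.asdict(self.cfg.seg), self.cfg.dry_run,
                   self._stamp_token("simulate")]
        mdir = self.outdir / "models"
        mdir.mkdir(exist_ok=True)
        gmap_path = mdir / "group_map.json"
        if self._check_stamp("train_seg", payload) and gmap_path.exists():
            log.info("stage train_seg: cached")
            group_map = json.loads(gmap_path.read_text())
            models = {name: self._load_seg_model(name) for name in group_map}
            self._mem["seg_models"] = (models, group_map)
            return models, group_map

        tmas = manifest[manifest["kind"] == "tma"]
        groups: dict = {}
        for _, row in tmas.iterrows():
            img = pio.read_image(self._sample_path(row, "image_path"))
            msk = pio.read_mask(self._sample_path(row, "gt_mask_path"),
                                reference_section=row["sample_id"])
            groups.setdefault(int(row["tma_group"]), []).append((img, msk))

        if self.cfg.dry_run:
            models = {f"Seg{i}": StubSegModel(0.7) for i in range(1, 4)}
            group_map = {f"Seg{i}": g for i, g in enumerate(sorted(groups), start=1)}
            histories = {}
        else:
            cfg = dataclasses.replace(self.cfg.seg, seed=self.stage_seed("train_seg"))
            try:
                models, group_map, histories = crossvalidate_segmentation(groups, cfg)
            except Exception as exc:
                raise StageError("train_seg", str(exc)) from exc
            for name, model in models.items():
                np.savez(mdir / f"{name}.npz",
                         **{f"arr_{i}": a for i, a in enumerate(model.get_state())})
        gmap_path.write_text(json.dumps(group_map))
        (mdir / "seg_histories.json").write_text(json.dumps(histories))
        self._write_stamp("train_seg", payload)
        self._mem["seg_models"] = (models, group_map)
        return models, group_map

    def seg_models(self):
        if "seg_models" not in self._mem:
            self.train_seg()
        return self._mem["seg_models"]

    # ------------------------------------------------------------------
    # stage: segment
    # ------------------------------------------------------------------
    def segment(self):
        manifest = self.manifest()
        models, group_map = self.seg_models()
        model_for_group = {g: m for m, g in group_map.items()}
        payload = [dataclasses.asdict(self.cfg.seg), self.cfg.dry_run,
                   self._stamp_token("simulate"), self._stamp_token("train_seg")]
        sdir = self.outdir / "segment"
        iou_path = sdir / "iou.json"
        if self._check_stamp("segment", payload) and iou_path.exists():
            log.info("stage segment: cached")
            self._mem["seg_iou"] = json.loads(iou_path.read_text())
            return self._mem["seg_iou"]
        sdir.mkdir(exist_ok=True)
        seg = self.cfg.seg
        ious = {}
        for _, row in manifest.iterrows():
            sid = row["sample_id"]
            # TMAs are segmented by the model validated on their group (which
            # never saw them in training); sections by Seg1
            if row["kind"] == "tma":
                model = models[model_for_group[int(row["tma_group"])]]
            else:
                model = models["Seg1"]
            img = pio.read_image(self._sample_path(row, "image_path"))
            img.section_id = sid
            hm = predict_heatmap(model, img, seg.tile_size, seg.stride, seg.downsample)
            mask = binarize(hm, 0.5)
            pio.write_heatmap(hm, sdir / f"{sid}_heatmap.png")
            pio.write_mask(mask, sdir / f"{sid}_mask.png")
            gt = pio.read_mask(self._sample_path(row, "gt_mask_path"))
            gt_ds = BinaryMask(downsample_mask(gt.values, seg.downsample), sid, seg.downsample)
            ious[sid] = {
                "tumor_iou": compute_iou(mask, gt_ds),
                "class_avg_iou": compute_iou_averaged(mask, gt_ds),
            }
        iou_path.write_text(json.dumps(ious))
        self._write_stamp("segment", payload)
        self._mem["seg_iou"] = ious
        return ious

    def seg_mask(self, sid: str) -> BinaryMask:
        return pio.read_mask(self.outdir / "segment" / f"{sid}_mask.png",
                             reference_section=sid, downsample=self.cfg.seg.downsample)

    # ------------------------------------------------------------------
    # stage: register
    # ------------------------------------------------------------------
    def register(self):
        manifest = self.manifest()
        payload = [self._stamp_token("simulate")]
        rdir = self.outdir / "register"
        done = rdir / "rmse.json"
        if self._check_stamp("register", payload) and done.exists():
            log.info("stage register: cached")
        else:
            rdir.mkdir(exist_ok=True)
            rmses = {}
            for _, row in manifest.iterrows():
                sid = row["sample_id"]
                try:
                    anchors = pio.read_anchors(self._sample_path(row, "anchors_path"))
                    T = fit_affine(anchors)
                except Exception as exc:
                    raise StageError("register", str(exc), sample_id=sid) from exc
                (rdir / f"{sid}.json").write_text(T.to_json())
                rmses[sid] = anchor_rmse(anchors, T)
            done.write_text(json.dumps(rmses))
            self._write_stamp("register", payload)
        self._mem["transforms"] = {
            row["sample_id"]: AffineTransform2D.from_json(
                (rdir / f"{row['sample_id']}.json").read_text())
            for _, row in manifest.iterrows()
        }
        return self._mem["transforms"]

    def transforms(self):
        if "transforms" not in self._mem:
            self.register()
        return self._mem["transforms"]

    # ------------------------------------------------------------------
    # stage: preprocess
    # ------------------------------------------------------------------
    def preprocess(self):
        manifest = self.manifest()
        payload = [dataclasses.asdict(self.cfg.preprocess), self._stamp_token("simulate")]
        pdir = self.outdir / "preprocess"
        done = pdir / "trace.json"
        if self._check_stamp("preprocess", payload) and done.exists():
            log.info("stage preprocess: cached")
            return
        pdir.mkdir(exist_ok=True)
        trace_out = None
        for _, row in manifest.iterrows():
            sid = row["sample_id"]
            try:
                ds = pio.read_imzml(self._sample_path(row, "imzml_path"))
                ds.section_id = sid
                ds = baseline_correct(ds, self.cfg.preprocess.baseline_window)
                ds, trace = run_pipeline(ds, self.cfg.preprocess)
            except Exception as exc:
                raise StageError("preprocess", str(exc), sample_id=sid) from exc
            np.savez(pdir / f"{sid}.npz", mz=ds.mz_axis,
                     intensities=ds.intensities.astype(np.float32), coords=ds.coords)
            trace_out = trace
        done.write_text(json.dumps(trace_out))
        self._write_stamp("preprocess", payload)

    def preprocessed(self, sid: str) -> MsiDataset:
        key = f"pp:{sid}"
        if key not in self._mem:
            with np.load(self.outdir / "preprocess" / f"{sid}.npz") as z:
                self._mem[key] = MsiDataset(
                    mz_axis=z["mz"], intensities=z["intensities"].astype(np.float64),
                    coords=z["coords"], section_id=sid,
                )
        return self._mem[key]

    # ------------------------------------------------------------------
    # stage: assemble
    # ------------------------------------------------------------------
    def assemble(self):
        manifest = self.manifest()
        self.segment()
        self.preprocess()
        transforms = self.transforms()
        models, group_map = self.seg_models()
        payload = [self._stamp_token(s) for s in
                   ("simulate", "train_seg", "segment", "register", "preprocess")]
        adir = self.outdir / "assemble"
        done = adir / "variants.json"
        members_path = adir / "memberships.npz"
        if self._check_stamp("assemble", payload) and members_path.exists():
            log.info("stage assemble: cached")
            return self._load_assemble(members_path, group_map)
        adir.mkdir(exist_ok=True)

        seg_cfg = self.cfg.seg
        tma_spots, section_spots, eval_sets = {}, {}, {}
        for _, row in manifest.iterrows():
            sid = row["sample_id"]
            ds = self.preprocessed(sid)
            T = transforms[sid]
            ann = pio.read_mask(self._sample_path(row, "ann_mask_path"),
                                reference_section=sid)
            try:
                if row["kind"] == "tma":
                    ann_member, _ = transfer_mask_to_spots(ann, T, ds)
                    # each TMA was segmented by the model validated on its
                    # group, which is exactly the mask MALDI3 needs
                    own = {g: m for m, g in group_map.items()}[int(row["tma_group"])]
                    mask = self.seg_mask(sid)
                    member, _ = transfer_mask_to_spots(mask, T, ds)
                    seg_member = {own: member}
                    tma_spots[sid] = {
                        "group": int(row["tma_group"]),
                        "annotation": ann_member,
                        "seg": seg_member,
                    }
                else:
                    mask = self.seg_mask(sid)
                    ann_member, _ = transfer_mask_to_spots(ann, T, ds)
                    seg_member, _ = transfer_mask_to_spots(mask, T, ds)
                    if row["split"] == "val":
                        section_spots[sid] = {
                            "annotation": ann_member, "seg1": seg_member,
                        }
                    sets = build_eval_datasets(ds, ann, mask, T)
                    eval_sets[sid] = sets
                    pd.DataFrame({
                        "section_id": sid,
                        "x": ds.coords[:, 0], "y": ds.coords[:, 1],
                        "in_D1": sets["D1"], "in_D2": sets["D2"],
                        "in_D3": sets["D3"], "in_D4": sets["D4"],
                    }).to_csv(adir / f"{sid}_datasets.csv", index=False)
            except Exception as exc:
                raise StageError("assemble", str(exc), sample_id=sid) from exc

        arrays = {}
        for sid, rec in tma_spots.items():
            arrays[f"tma.{sid}.group"] = np.array(rec["group"])
            arrays[f"tma.{sid}.ann"] = rec["annotation"]
            for mname, member in rec["seg"].items():
                arrays[f"tma.{sid}.seg.{mname}"] = member
        for sid, rec in section_spots.items():
            arrays[f"sec.{sid}.ann"] = rec["annotation"]
            arrays[f"sec.{sid}.seg1"] = rec["seg1"]
        for sid, sets in eval_sets.items():
            for dname in ("D1", "D2", "D3", "D4"):
                arrays[f"eval.{sid}.{dname}"] = sets[dname]
        np.savez(members_path, **arrays)

        variants = assemble_training_variants(tma_spots, section_spots, group_map)
        done.write_text(json.dumps({
            v: {split: {sid: int(m.sum()) for sid, m in spec[split].items()}
                for split in ("train", "val")}
            for v, spec in variants.items()
        }, indent=1))
        self._write_stamp("assemble", payload)
        self._mem["variants"] = variants
        self._mem["eval_sets"] = eval_sets
        return variants, eval_sets

    def _load_assemble(self, members_path, group_map):
        tma_spots: dict = {}
        section_spots: dict = {}
        eval_sets: dict = {}
        with np.load(members_path) as z:
            for key in z.files:
                parts = key.split(".")
                if parts[0] == "tma":
                    rec = tma_spots.setdefault(parts[1], {"seg": {}})
                    if parts[2] == "group":
                        rec["group"] = int(z[key])
                    elif parts[2] == "ann":
                        rec["annotation"] = z[key]
                    else:
                        rec["seg"][parts[3]] = z[key]
                elif parts[0] == "sec":
                    rec = section_spots.setdefault(parts[1], {})
                    rec["annotation" if parts[2] == "ann" else "seg1"] = z[key]
                else:
                    eval_sets.setdefault(parts[1], {})[parts[2]] = z[key]
        for sets in eval_sets.values():
            sets["counts"] = {k: int(v.sum()) for k, v in sets.items()}
        variants = assemble_training_variants(tma_spots, section_spots, group_map)
        self._mem["variants"] = variants
        self._mem["eval_sets"] = eval_sets
        return variants, eval_sets

    # ------------------------------------------------------------------
    # stage: train_cls
    # ------------------------------------------------------------------
    def _gather(self, spec: dict):
        manifest = self.manifest().set_index("sample_id")
        xs, ys = [], []
        for sid, member in spec.items():
            if not member.any():
                continue
            ds = self.preprocessed(sid)
            xs.append(ds.intensities[member])
            ys.extend([manifest.loc[sid, "diagnosis"]] * int(member.sum()))
        return np.concatenate(xs, axis=0), ys

    def _load_cls_model(self, variant: str):
        if self.cfg.dry_run:
            return StubSpecModel(0.9)
        path = self.outdir / "classifiers" / f"{variant}.npz"
        with np.load(path) as z:
            keys = sorted((k for k in z.files if k.startswith("arr_")),
                          key=lambda s: int(s[4:]))
            state = [z[k] for k in keys]
            n_channels = int(z["n_channels"])
            input_mean, input_sd = z["input_mean"], z["input_sd"]
        model = IsotopeNet1d(n_channels, channels=self.cfg.cls.channels,
                             pool=self.cfg.cls.pool, seed=0)
        model.set_state(state)
        model.input_mean = input_mean
        model.input_sd = input_sd
        return model

    def train_cls(self):
        variants, _ = self.assemble()
        payload = [dataclasses.asdict(self.cfg.cls), self.cfg.dry_run,
                   self._stamp_token("assemble")]
        cdir = self.outdir / "classifiers"
        done = cdir / "cls_histories.json"
        if self._check_stamp("train_cls", payload) and done.exists():
            log.info("stage train_cls: cached")
            self._mem["cls_models"] = {v: self._load_cls_model(v) for v in variants}
            return self._mem["cls_models"]
        cdir.mkdir(exist_ok=True)
        models, histories = {}, {}
        for i, (variant, spec) in enumerate(sorted(variants.items())):
            if self.cfg.dry_run:
                models[variant] = StubSpecModel(0.9)
                histories[variant] = {}
                continue
            xt, yt = self._gather(spec["train"])
            xv, yv = self._gather(spec["val"])
            cfg = dataclasses.replace(
                self.cfg.cls, seed=self.stage_seed("train_cls") + i)
            try:
                model, hist = train_spectrum_classifier(xt, yt, xv, yv, cfg)
            except Exception as exc:
                raise StageError("train_cls", str(exc), sample_id=variant) from exc
            models[variant] = model
            histories[variant] = hist | {"n_train": len(yt), "n_val": len(yv)}
            arrays = {f"arr_{j}": a for j, a in enumerate(model.get_state())}
            np.savez(cdir / f"{variant}.npz", n_channels=model.n_channels,
                     input_mean=model.input_mean, input_sd=model.input_sd, **arrays)
        done.write_text(json.dumps(
            {v: {k: h[k] for k in h if k != "best"} | {"best": h.get("best")}
             for v, h in histories.items()}, default=str))
        self._write_stamp("train_cls", payload)
        self._mem["cls_models"] = models
        return models

    # ------------------------------------------------------------------
    # stage: classify + aggregate
    # ------------------------------------------------------------------
    def classify(self):
        variants, eval_sets = self.assemble()
        models = self.train_cls()
        manifest = self.manifest()
        payload = [self._stamp_token("assemble"), self._stamp_token("train_cls")]
        kdir = self.outdir / "predictions"
        done = kdir / "spot_labels.json"
        if self._check_stamp("classify", payload) and done.exists():
            log.info("stage classify: cached")
            self._mem["spot_labels"] = json.loads(done.read_text())
            return self._mem["spot_labels"]
        kdir.mkdir(exist_ok=True)
        test_rows = manifest[manifest["split"] == "test"]
        spot_labels: dict = {}
        for variant, model in models.items():
            spot_labels[variant] = {f"D{i}": {} for i in range(1, 5)}
            all_preds = []
            for _, row in test_rows.iterrows():
                sid = row["sample_id"]
                ds = self.preprocessed(sid)
                try:
                    preds = predict_spectra(model, ds)
                except Exception as exc:
                    raise StageError("classify", str(exc), sample_id=sid) from exc
                all_preds.extend(preds)
                labels = np.array([p.label for p in preds])
                for dname in ("D1", "D2", "D3", "D4"):
                    member = eval_sets[sid][dname]
                    spot_labels[variant][dname][sid] = labels[member].tolist()
            pio.write_predictions(all_preds, kdir / f"{variant}.csv")
        done.write_text(json.dumps(spot_labels))
        self._write_stamp("classify", payload)
        self._mem["spot_labels"] = spot_labels
        return spot_labels

    def aggregate(self) -> EvaluationReport:
        spot_labels = self.classify()
        seg_iou = self.segment()
        manifest = self.manifest()
        truth = {row["sample_id"]: row["diagnosis"] for _, row in manifest.iterrows()}
        test_iou = {
            row["sample_id"]: seg_iou[row["sample_id"]]["tumor_iou"]
            for _, row in manifest.iterrows() if row["split"] == "test"
        }
        report = evaluate_cohort(spot_labels, truth,
                                 qc_threshold=self.cfg.qc_threshold, seg_iou=test_iou)
        rdir = self.outdir / "report"
        report.to_json(rdir / "report.json")
        report.write_csvs(rdir)
        for (net, dsname), vs in report.verdicts.items():
            pio.write_verdicts(vs, rdir / f"verdicts_{net}_{dsname}.csv")
        self._write_stamp("aggregate", [self._stamp_token("classify")])
        self._mem["report"] = report
        return report

    # ------------------------------------------------------------------
    def run_all(self) -> EvaluationReport:
        self.simulate()
        self.train_seg()
        self.segment()
        self.register()
        self.preprocess()
        self.assemble()
        self.train_cls()
        self.classify()
        return self.aggregate()
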