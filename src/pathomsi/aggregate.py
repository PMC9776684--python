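"""Section-level aggregation: majority vote, quality control, report tables.

Each section receives the subtype of the majority (> 50%) of its classified
spectra.  A verdict is flagged inconclusive by quality control when the
majority fraction p falls below a threshold (default 0.9); in a clinical
workflow such sections would be routed back to the pathologist.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import ADC, SQCC, SectionVerdict

INCONCLUSIVE = "inconclusive"
CONFUSION_COLUMNS = [SQCC, ADC, "p<qc"]


def majority_vote(labels, qc_threshold: float = 0.9, section_id: str = "") -> SectionVerdict:
    """Aggregate per-spectrum labels into a section verdict.

    The section label is the class holding strictly more than half of the
    spectra; an exact 50/50 tie is inconclusive with p = 0.5.  QC passes
    iff p >= qc_threshold.
    """
    labels = list(labels)
    if not labels:
        raise ValidationError("cannot vote on an empty prediction list")
    bad = set(labels) - {ADC, SQCC}
    if bad:
        raise ValidationError(f"unknown class labels in vote: {sorted(bad)}")
    counts = Counter(labels)
    n = len(labels)
    top = max(counts.values())
    p = top / n
    if top * 2 > n:
        label = max(counts, key=lambda c: counts[c])
    else:
        label = INCONCLUSIVE
    return SectionVerdict(
        section_id=section_id,
        n_spectra=n,
        counts={ADC: counts.get(ADC, 0), SQCC: counts.get(SQCC, 0)},
        p_majority=p,
        label=label,
        qc_threshold=qc_threshold,
        qc_pass=p >= qc_threshold,
    )


def balanced_accuracy(predicted, truth) -> float:
    """Mean of per-class recalls over the two subtype classes."""
    predicted = np.asarray(list(predicted))
    truth = np.asarray(list(truth))
    if predicted.shape != truth.shape:
        raise ValidationError("prediction and truth lengths differ")
    classes = set(truth.tolist())
    if classes != {ADC, SQCC}:
        raise ValidationError(f"truth must contain both classes, got {sorted(classes)}")
    recalls = []
    for c in (ADC, SQCC):
        sel = truth == c
        recalls.append(float((predicted[sel] == c).mean()))
    return float(np.mean(recalls))


def confusion_with_qc(verdicts, truths: dict) -> pd.DataFrame:
    """Per-true-class counts of QC-passing calls plus a p<qc column.

    Rows are the true classes (SqCC, ADC); a verdict failing QC lands in
    the ``p<qc`` column regardless of its label, so each row sums to the
    number of true sections of that class.
    """
    seen = set()
    table = pd.DataFrame(0, index=[SQCC, ADC], columns=CONFUSION_COLUMNS)
    for v in verdicts:
        if v.section_id in seen:
            raise ValidationError(f"duplicate section_id {v.section_id!r}")
        seen.add(v.section_id)
        true = truths[v.section_id]
        if v.qc_pass and v.label in (ADC, SQCC):
            table.loc[true, v.label] += 1
        else:
            table.loc[true, "p<qc"] += 1
    return table


@dataclass
class EvaluationReport:
    """All section- and spectrum-level result tables of one evaluation run."""

    balanced_accuracy: pd.DataFrame  # networks x datasets, spectrum level
    confusion: dict  # (network, dataset) -> DataFrame
    section_accuracy: pd.DataFrame  # rows (network, dataset): pre/post QC
    verdicts: dict  # (network, dataset) -> [SectionVerdict]
    seg_iou: dict = field(default_factory=dict)  # section_id -> IoU
    qc_threshold: float = 0.9

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "qc_threshold": self.qc_threshold,
            "balanced_accuracy": json.loads(self.balanced_accuracy.to_json()),
            "section_accuracy": json.loads(
                self.section_accuracy.to_json(orient="table")
            ),
            "confusion": {
                f"{net}|{dsname}": json.loads(tab.to_json())
                for (net, dsname), tab in self.confusion.items()
            },
            "seg_iou": self.seg_iou,
            "verdicts": {
                f"{net}|{dsname}": [
                    dict(section_id=v.section_id, n_spectra=v.n_spectra,
                         p_majority=v.p_majority, label=v.label, qc_pass=bool(v.qc_pass))
                    for v in vs
                ]
                for (net, dsname), vs in self.verdicts.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def write_csvs(self, outdir) -> list:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        p = outdir / "balanced_accuracy.csv"
        self.balanced_accuracy.to_csv(p)
        written.append(p)
        p = outdir / "section_accuracy.csv"
        self.section_accuracy.to_csv(p)
        written.append(p)
        for (net, dsname), tab in self.confusion.items():
            p = outdir / f"confusion_{net}_{dsname}.csv"
            tab.to_csv(p)
            written.append(p)
        if self.seg_iou:
            p = outdir / "section_iou.csv"
            pd.Series(self.seg_iou, name="iou").rename_axis("section_id").to_csv(p)
            written.append(p)
        return written


def evaluate_cohort(spot_labels: dict, section_truth: dict,
                    qc_threshold: float = 0.9, seg_iou: dict | None = None) -> EvaluationReport:
    """Assemble the full evaluation report from per-spot hard labels.

    Parameters
    ----------
    spot_labels : {network: {dataset_name: {section_id: [labels]}}}
        Hard per-spectrum labels of every evaluated subset.  Sections whose
        subset is empty are omitted from that dataset's tables.
    section_truth : {section_id: ADC | SqCC}
    seg_iou : optional {section_id: IoU} of the segmentation against truth.

    Spectrum-level balanced accuracy follows the convention that every
    spectrum of a section carries the section's diagnosis — datasets 2-4
    knowingly include non-tumor spectra.
    """
    networks = sorted(spot_labels)
    datasets = sorted({d for net in spot_labels.values() for d in net})
    bacc = pd.DataFrame(index=networks, columns=datasets, dtype=float)
    confusion = {}
    verdicts = {}
    sect_rows = []
    for net in networks:
        for dsname in datasets:
            sections = spot_labels[net].get(dsname, {})
            sections = {sid: labs for sid, labs in sections.items() if len(labs) > 0}
            if not sections:
                continue
            pred_flat, true_flat = [], []
            for sid, labs in sections.items():
                pred_flat.extend(labs)
                true_flat.extend([section_truth[sid]] * len(labs))
            if set(true_flat) == {ADC, SQCC}:
                bacc.loc[net, dsname] = balanced_accuracy(pred_flat, true_flat)
            vs = [majority_vote(labs, qc_threshold, section_id=sid)
                  for sid, labs in sections.items()]
            verdicts[(net, dsname)] = vs
            confusion[(net, dsname)] = confusion_with_qc(
                vs, {sid: section_truth[sid] for sid in sections}
            )
            correct = [v.label == section_truth[v.section_id] for v in vs]
            passing = [v for v in vs if v.qc_pass]
            correct_qc = [v.label == section_truth[v.section_id] for v in passing]
            sect_rows.append(dict(
                network=net, dataset=dsname, n_sections=len(vs),
                accuracy_pre_qc=float(np.mean(correct)),
                n_qc_pass=len(passing),
                accuracy_post_qc=float(np.mean(correct_qc)) if passing else np.nan,
            ))
    section_accuracy = pd.DataFrame(sect_rows).set_index(["network", "dataset"]) \
        if sect_rows else pd.DataFrame()
    return EvaluationReport(
        balanced_accuracy=bacc,
        confusion=confusion,
        section_accuracy=section_accuracy,
        verdicts=verdicts,
        seg_iou=seg_iou or {},
        qc_threshold=qc_threshold,
    )
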