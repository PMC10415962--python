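"""End-to-end orchestration: CT volume + biometrics -> sarcopenia report.

``run_end_to_end`` chains preprocessing, slice selection, segmentation and the
morphometric conversion into one JSON-serializable report. An *oracle mode*
(ground-truth slice/mask injected in place of the models) exercises the exact
same plumbing, which separates model error from pipeline error. Batch runs
isolate per-case failures: one unreadable volume yields one failure row, not an
aborted batch.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import morphometry
from .config import PipelineConfig
from .io_prep import conform_mask, load_mask, load_volume, preprocess
from .segment import SegModel, segment_muscle
from .slice_select import SliceModel, predict_mid_c3
from .types import Biometrics, CTVolume, MuscleMask

log = logging.getLogger(__name__)

REQUIRED_BIOMETRICS = ("age", "sex", "weight", "height")


class MissingBiometricsError(ValueError):
    def __init__(self, fields):
        super().__init__(f"missing biometrics field(s): {', '.join(fields)}")
        self.fields = tuple(fields)


def parse_biometrics(record: dict) -> Biometrics:
    """Build Biometrics from a mapping, naming every missing field."""
    missing = [f for f in REQUIRED_BIOMETRICS
               if record.get(f) in (None, "") or
               (isinstance(record.get(f), float) and pd.isna(record.get(f)))]
    if missing:
        raise MissingBiometricsError(missing)
    return Biometrics(age=float(record["age"]), sex=str(record["sex"]),
                      weight=float(record["weight"]), height=float(record["height"]))


def run_end_to_end(volume: CTVolume | str | Path,
                   biometrics: Biometrics | dict,
                   slice_model: SliceModel | None,
                   seg_model: SegModel | None,
                   config: PipelineConfig | None = None,
                   truth_mid_c3: int | None = None,
                   oracle_mask: MuscleMask | None = None) -> dict:
    """Produce one per-patient sarcopenia report.

    Passing ``truth_mid_c3``/``oracle_mask`` instead of models runs oracle mode.
    Sex 'unspecified' raises; such rows are excluded upstream with a logged count.
    """
    config = config if config is not None else PipelineConfig()
    if isinstance(biometrics, dict):
        biometrics = parse_biometrics(biometrics)
    if not isinstance(volume, CTVolume):
        volume = load_volume(volume)

    qa_flags: list[str] = []
    pre = preprocess(volume, config.preprocess)

    if slice_model is not None:
        selection = predict_mid_c3(slice_model, pre)
        predicted_slice = selection.predicted_index
    elif truth_mid_c3 is not None:
        predicted_slice = int(truth_mid_c3)
        qa_flags.append("oracle_slice")
    else:
        raise ValueError("provide a slice model or truth_mid_c3")

    if seg_model is not None:
        mask = segment_muscle(seg_model, pre.voxels[predicted_slice],
                              (pre.spacing[1], pre.spacing[2]), predicted_slice)
    elif oracle_mask is not None:
        mask = oracle_mask
        qa_flags.append("oracle_mask")
    else:
        raise ValueError("provide a segmentation model or oracle_mask")

    if mask.n_pixels == 0:
        qa_flags.append("empty_segmentation")
    meas = morphometry.measure(mask, biometrics, config.sarcopenia)
    bmi_info = morphometry.classify_bmi(biometrics, config.sarcopenia)
    if meas.smi is not None and not (10.0 <= meas.smi <= 120.0):
        qa_flags.append("smi_out_of_range")

    sarcopenia = (morphometry.classify_sarcopenia(meas.smi, biometrics.sex,
                                                  config.sarcopenia)
                  if meas.smi is not None and meas.smi >= 0 else "indeterminate")

    delta_h_mm = None
    if truth_mid_c3 is not None and slice_model is not None:
        delta_h_mm = (predicted_slice - truth_mid_c3) * pre.spacing[0]

    return {
        "source_id": volume.source_id,
        "predicted_slice": int(predicted_slice),
        "delta_h_mm": delta_h_mm,
        "csa_c3_cm2": round(meas.csa_c3, 6),
        "csa_l3_cm2": None if meas.csa_l3 is None else round(meas.csa_l3, 6),
        "smi_cm2_per_m2": None if meas.smi is None else round(meas.smi, 6),
        "sarcopenia": sarcopenia,
        "bmi_kg_per_m2": round(bmi_info["bmi"], 6),
        "bmi_class": bmi_info["underweight_class"],
        "qa_flags": qa_flags,
        "config_hash": config.hash,
        "model_versions": {
            "slice": None if slice_model is None else "densenet_regressor",
            "seg": None if seg_model is None else "unet2d",
        },
    }


def batch_run(manifest: str | Path | pd.DataFrame,
              slice_model: SliceModel | None,
              seg_model: SegModel | None,
              config: PipelineConfig | None = None,
              out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run every manifest row, isolating per-case failures.

    Manifest columns: volume_path, age, sex, weight, height; optional
    truth_mid_c3 and mask_path enable oracle mode and Δh reporting.
    """
    config = config if config is not None else PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if not path.exists():
            raise ValueError(f"unreadable manifest: {path}")
        manifest = pd.read_csv(path)
    rows = []
    n_excluded_sex = 0
    for i, rec in enumerate(manifest.to_dict("records")):
        case_id = str(rec.get("case_id", rec.get("volume_path", i)))
        try:
            if str(rec.get("sex", "")) not in Biometrics.VALID_SEX:
                n_excluded_sex += 1
                raise ValueError(f"sex {rec.get('sex')!r} excluded from classification")
            truth = rec.get("truth_mid_c3")
            truth = int(truth) if truth is not None and not pd.isna(truth) else None
            oracle_mask = None
            if seg_model is None and rec.get("mask_path"):
                oracle_mask = load_mask(rec["mask_path"])
                oracle_mask = conform_mask(
                    oracle_mask, preprocess(load_volume(rec["volume_path"]),
                                            config.preprocess))
            report = run_end_to_end(rec["volume_path"], rec, slice_model,
                                    seg_model, config, truth_mid_c3=truth,
                                    oracle_mask=oracle_mask)
            report.update({"case_id": case_id, "status": "ok", "error": ""})
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                (out / f"{case_id}.json").write_text(
                    json.dumps(report, indent=2, sort_keys=True))
            rows.append(report)
        except Exception as exc:  # per-case isolation is the contract
            log.warning("case %s failed: %s", case_id, exc)
            rows.append({"case_id": case_id, "status": "failed", "error": str(exc)})
    if n_excluded_sex:
        log.info("excluded %d case(s) with unspecified sex", n_excluded_sex)
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "summary.csv", index=False)
    return summary
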