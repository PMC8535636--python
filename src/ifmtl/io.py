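"""Dataset, report and checkpoint I/O.

Datasets are stored as one directory per case holding seven 16-bit
grayscale PNGs named after the stains (plus an optional ``mask.png`` with
the deposit ground truth), indexed by a manifest CSV with columns
``case_id, label, quality_gt, path``. 16-bit PNG preserves intensities to
1/65535, and the synthetic generator snaps to that grid, so synthetic
round-trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .case import LABELS, STAINS, IFCase, ValidationError
from .metrics import MetricsReport, rounded_row

MANIFEST_COLUMNS = ["case_id", "label", "quality_gt", "path"]
REPORT_HEADER = ["Diseases", "Numbers", "Accuracy", "Recall", "Precision", "F1 Score", "AUC"]


# ---------------------------------------------------------------------------
# Dataset I/O


def save_dataset(cases: list[IFCase], out_dir: str | Path) -> Path:
    """Write per-case PNG directories plus the manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        case.validate()
        case_dir = out_dir / case.case_id
        case_dir.mkdir(exist_ok=True)
        for i, stain in enumerate(STAINS):
            img = np.round(case.channels[i].astype(np.float64) * 65535).astype(np.uint16)
            iio.imwrite(case_dir / f"{stain}.png", img)
        if case.deposit_mask is not None:
            iio.imwrite(
                case_dir / "mask.png",
                (case.deposit_mask.astype(np.uint8) * 255),
            )
        rows.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                "quality_gt": case.quality_gt,
                "path": case.case_id,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[IFCase]:
    """Load cases listed in a manifest CSV; all problems reported together."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ValidationError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"manifest missing columns: {sorted(missing_cols)}")
    root = manifest_path.parent
    cases: list[IFCase] = []
    errors: list[str] = []
    for row in df.itertuples(index=False):
        case_dir = root / str(row.path)
        channels = []
        for stain in STAINS:
            f = case_dir / f"{stain}.png"
            if not f.exists():
                errors.append(f"{row.case_id}/{stain}: missing file {f}")
                continue
            img = iio.imread(f)
            if img.ndim != 2:
                errors.append(f"{row.case_id}/{stain}: not grayscale (shape {img.shape})")
                continue
            denom = 65535.0 if img.dtype == np.uint16 else 255.0
            channels.append((img.astype(np.float64) / denom).astype(np.float32))
        if len(channels) != len(STAINS):
            continue
        mask_file = case_dir / "mask.png"
        mask = iio.imread(mask_file) > 127 if mask_file.exists() else None
        try:
            cases.append(
                IFCase(
                    case_id=str(row.case_id),
                    channels=np.stack(channels),
                    label=str(row.label),
                    quality_gt=int(row.quality_gt),
                    deposit_mask=mask,
                ).validate()
            )
        except ValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError(
            f"{len(errors)} dataset problem(s):\n" + "\n".join(errors)
        )
    return cases


# ---------------------------------------------------------------------------
# Report I/O


def _report_rows(report: MetricsReport) -> list[dict]:
    rows = []
    for name in report.classes:
        r = rounded_row(report.per_class[name])
        rows.append(
            {
                "Diseases": name,
                "Numbers": int(r["n"]),
                "Accuracy": r["accuracy"],
                "Recall": r["recall"],
                "Precision": r["precision"],
                "F1 Score": r["f1"],
                "AUC": r.get("auc", float("nan")),
            }
        )
    t = rounded_row(
        {
            "n": report.totals["n"],
            "accuracy": report.totals["micro_accuracy"],
            "recall": report.totals["macro_recall"],
            "precision": report.totals["macro_precision"],
            "f1": report.totals["macro_f1"],
            **(
                {"auc": report.totals["macro_auc"]}
                if "macro_auc" in report.totals
                else {}
            ),
        }
    )
    rows.append(
        {
            "Diseases": "Total",
            "Numbers": int(t["n"]),
            "Accuracy": t["accuracy"],
            "Recall": t["recall"],
            "Precision": t["precision"],
            "F1 Score": t["f1"],
            "AUC": t.get("auc", float("nan")),
        }
    )
    return rows


def save_report(report: MetricsReport, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` and a fixed-width ``<path>.txt`` table."""
    if any(report.per_class[c]["n"] == 0 for c in report.classes):
        empty = [c for c in report.classes if report.per_class[c]["n"] == 0]
        raise ValidationError(f"classes with no cases: {empty}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = _report_rows(report)
    df = pd.DataFrame(rows, columns=REPORT_HEADER)
    csv_path = path.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.3f")
    txt_path = path.with_suffix(".txt")
    widths = [9, 8, 9, 7, 10, 9, 6]
    lines = ["".join(h.ljust(w + 1) for h, w in zip(REPORT_HEADER, widths)).rstrip()]
    for row in rows:
        cells = []
        for key, w in zip(REPORT_HEADER, widths):
            v = row[key]
            if key in ("Diseases", "Numbers"):
                cells.append(str(v).ljust(w + 1))
            elif key == "AUC":
                cells.append(f"{v:.3f}".ljust(w + 1))
            else:
                cells.append(f"{v:.2f}".ljust(w + 1))
        lines.append("".join(cells).rstrip())
    txt_path.write_text("\n".join(lines) + "\n")
    return csv_path, txt_path


def load_report_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model, path: str | Path) -> Path:
    """Persist an estimator: hyperparameters JSON + weight arrays (npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(model, "_all_params"):
        params = model._all_params()
    elif hasattr(model, "parameters"):
        params = model.parameters()
    elif hasattr(model, "_net"):
        params = model._net.parameters()
    else:  # pragma: no cover
        raise ValidationError(f"cannot checkpoint {type(model).__name__}")
    arrays = {f"arr_{i:04d}": p.value for i, p in enumerate(params)}
    meta = {
        "class": type(model).__name__,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.get_params().items()
        },
    }
    if hasattr(model, "classes_"):
        meta["classes"] = [str(c) for c in model.classes_]
    if hasattr(model, "_image_hw"):
        meta["image_hw"] = list(model._image_hw)
    np.savez(path, __meta__=json.dumps(meta), **arrays)
    return path


def load_checkpoint(path: str | Path):
    """Rebuild the estimator saved by :func:`save_checkpoint`."""
    from .models import DeblurNetwork, IQARegressor, StackClassifier

    registry = {
        "DeblurNetwork": DeblurNetwork,
        "IQARegressor": IQARegressor,
        "StackClassifier": StackClassifier,
    }
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = [data[k] for k in sorted(k for k in data.files if k != "__meta__")]
    cls = registry[meta["class"]]
    kwargs = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()
    }
    model = cls(**kwargs)
    if cls is StackClassifier:
        model.classes_ = np.array(meta["classes"])
        model._build(tuple(meta["image_hw"]), len(model.classes_))
        flat = model._all_params()
    elif cls is DeblurNetwork:
        model._build()
        flat = model.parameters()
    else:
        model._build()
        flat = model._net.parameters()
    for p, a in zip(flat, arrays):
        if p.value.shape != a.shape:
            raise ValidationError(
                f"checkpoint shape mismatch for {p.name}: {p.value.shape} vs {a.shape}"
            )
        p.value[...] = a
    return model


# ---------------------------------------------------------------------------
# Run manifests


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_run_manifest(
    out_dir: str | Path, config: dict, produced: list[str | Path]
) -> Path:
    """Record config, seeds and output checksums; never overwrites."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "files": {str(p): file_checksum(p) for p in produced if Path(p).exists()},
    }
    i = 0
    while (target := out_dir / f"run_manifest_{i:04d}.json").exists():
        i += 1
    target.write_text(json.dumps(record, indent=2, default=str))
    return target
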