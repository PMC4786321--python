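"""Annotation schema, report writers and pipeline orchestration.

Annotations travel as JSON, one document per eye (or a list of such
documents)::

    {
      "eye_id": "E001",
      "scans": [
        {
          "scan_id": "E001_h1",
          "meridian": "horizontal",
          "pixel_scale": 3.87,
          "bmo": [[x, y], [x, y]],
          "ali": [[x, y], [x, y]],
          "anterior_lc": [[x, y], ...]
        }
      ]
    }

Coordinates may be pixels; they are converted to micrometres via
``pixel_scale`` once, on read, so downstream geometry never sees pixel
units.  Validation errors carry a JSON-pointer-style location.

Reports are tidy CSV — one row per scan and one per eye — each preceded
by a comment header recording package version, seed and a hash of the run
configuration, so a rerun under the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .geometry import (
    BScanAnnotation,
    EyeMorphometry,
    Point2D,
    aggregate_eye,
    compute_scan_morphometry,
)

__all__ = [
    "AnnotationSchemaError",
    "RunConfig",
    "read_annotations",
    "write_annotations",
    "scan_table",
    "eye_table",
    "write_report",
    "run_pipeline",
]

log = logging.getLogger("lcindex")


class AnnotationSchemaError(ValueError):
    """Annotation JSON violates the schema; message carries the location."""


class _ScanModel(BaseModel):
    scan_id: str
    meridian: Literal["horizontal", "vertical"]
    pixel_scale: float = Field(gt=0, default=1.0)
    bmo: list[tuple[float, float]] = Field(min_length=2, max_length=2)
    ali: list[tuple[float, float]] = Field(min_length=2, max_length=2)
    anterior_lc: list[tuple[float, float]] = Field(min_length=2)


class _EyeModel(BaseModel):
    eye_id: str
    scans: list[_ScanModel]


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(p) for p in loc)


def _to_annotation(scan: _ScanModel) -> BScanAnnotation:
    s = scan.pixel_scale
    return BScanAnnotation(
        scan_id=scan.scan_id,
        meridian=scan.meridian,
        bmo=tuple(Point2D(x * s, y * s) for x, y in scan.bmo),
        ali=tuple(Point2D(x * s, y * s) for x, y in scan.ali),
        anterior_lc=tuple(Point2D(x * s, y * s) for x, y in scan.anterior_lc),
        pixel_scale=1.0,  # μm after conversion
    )


def read_annotations(path: str | Path) -> list[tuple[str, list[BScanAnnotation]]]:
    """Read and validate an annotation JSON file.

    Returns ``[(eye_id, [BScanAnnotation, ...]), ...]`` with all
    coordinates in micrometres.
    """
    raw = json.loads(Path(path).read_text())
    docs = raw if isinstance(raw, list) else [raw]
    eyes = []
    for i, doc in enumerate(docs):
        try:
            eye = _EyeModel.model_validate(doc)
        except ValidationError as err:
            first = err.errors()[0]
            prefix = f"/{i}" if isinstance(raw, list) else ""
            raise AnnotationSchemaError(
                f"{path}: invalid annotation at {prefix}{_pointer(first['loc'])}: "
                f"{first['msg']}"
            ) from err
        eyes.append((eye.eye_id, [_to_annotation(s) for s in eye.scans]))
    return eyes


def write_annotations(
    path: str | Path, eyes: Sequence[tuple[str, Sequence[BScanAnnotation]]]
) -> None:
    """Serialize annotations back to the JSON schema (μm, pixel_scale 1)."""
    docs = []
    for eye_id, scans in eyes:
        docs.append(
            {
                "eye_id": eye_id,
                "scans": [
                    {
                        "scan_id": a.scan_id,
                        "meridian": a.meridian,
                        "pixel_scale": a.pixel_scale,
                        "bmo": [[p.x, p.y] for p in a.bmo],
                        "ali": [[p.x, p.y] for p in a.ali],
                        "anterior_lc": [[p.x, p.y] for p in a.anterior_lc],
                    }
                    for a in scans
                ],
            }
        )
    payload = docs if len(docs) != 1 else docs[0]
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# report tables


def scan_table(rows: Sequence[tuple[str, object]]) -> pd.DataFrame:
    """Tidy per-scan table from (eye_id, ScanMorphometry) pairs."""
    recs = []
    for eye_id, m in rows:
        recs.append(
            {
                "eye_id": eye_id,
                "scan_id": m.scan_id,
                "meridian": m.meridian,
                "alid_side1": m.alid_side1,
                "alid_side2": m.alid_side2,
                "mean_alid": m.mean_alid,
                "D": m.D,
                "S": m.S,
                "mlcd": m.mlcd,
                "curvature_index": m.curvature_index,
            }
        )
    return pd.DataFrame(recs)


def eye_table(eyes: Sequence[EyeMorphometry]) -> pd.DataFrame:
    recs = []
    for e in eyes:
        recs.append(
            {
                "eye_id": e.eye_id,
                "horizontal_alid": e.horizontal_alid,
                "vertical_alid": e.vertical_alid,
                "horizontal_mlcd": e.horizontal_mlcd,
                "vertical_mlcd": e.vertical_mlcd,
                "horizontal_index": e.horizontal_index,
                "vertical_index": e.vertical_index,
                "overall_index": e.overall_index,
                "n_scans_horizontal": e.n_scans_horizontal,
                "n_scans_vertical": e.n_scans_vertical,
            }
        )
    return pd.DataFrame(recs)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one measurement run."""

    annotations: tuple[str, ...]
    out_dir: str
    seed: int = 0
    strict_vertical: bool = False
    welch: bool = False
    min_scans_per_meridian: int = 1
    tolerance_um: float = 1e-6
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "annotations": list(self.annotations),
                "seed": self.seed,
                "strict_vertical": self.strict_vertical,
                "welch": self.welch,
                "min_scans_per_meridian": self.min_scans_per_meridian,
                "tolerance_um": self.tolerance_um,
                "extra": self.extra,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_report(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """CSV with a provenance comment header (version, seed, config hash)."""
    header = (
        f"# lcindex v{__version__} seed={config.seed} "
        f"config={config.config_hash()}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Measure every annotated scan and write per-scan / per-eye reports.

    Scans whose geometry cannot be measured are excluded with a logged
    reason and the pipeline continues — mirroring per-scan quality
    exclusions in practice.  Returns a bundle with the tables, the
    exclusion log and the output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan_rows: list[tuple[str, object]] = []
    eye_rows = []
    exclusions: list[dict] = []
    for path in config.annotations:
        for eye_id, anns in read_annotations(path):
            measured = []
            for ann in anns:
                try:
                    m = compute_scan_morphometry(ann, strict_vertical=config.strict_vertical)
                except ValueError as err:
                    exclusions.append(
                        {"eye_id": eye_id, "scan_id": ann.scan_id, "reason": str(err)}
                    )
                    log.warning("excluded %s/%s: %s", eye_id, ann.scan_id, err)
                    continue
                measured.append(m)
                scan_rows.append((eye_id, m))
            by_meridian = {
                mer: [m for m in measured if m.meridian == mer]
                for mer in ("horizontal", "vertical")
            }
            kept = [
                m
                for mer, ms in by_meridian.items()
                if len(ms) >= config.min_scans_per_meridian
                for m in ms
            ]
            if kept:
                eye_rows.append(aggregate_eye(eye_id, kept))
            else:
                exclusions.append(
                    {"eye_id": eye_id, "scan_id": "", "reason": "no gradable scans"}
                )
                log.warning("excluded eye %s: no gradable scans", eye_id)
    scans_df = scan_table(scan_rows)
    eyes_df = eye_table(eye_rows)
    scan_path = out / "per_scan.csv"
    eye_path = out / "per_eye.csv"
    write_report(scans_df, scan_path, config)
    write_report(eyes_df, eye_path, config)
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_scans": len(scan_rows),
        "n_eyes": len(eye_rows),
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return {
        "scans": scans_df,
        "eyes": eyes_df,
        "exclusions": exclusions,
        "paths": {"per_scan": str(scan_path), "per_eye": str(eye_path)},
        "summary": summary,
    }
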