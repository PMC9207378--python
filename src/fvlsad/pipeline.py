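"""Batch orchestration: reports/curves in, indices and a run manifest out.

Each input is processed independently; any per-input failure is
recorded as a status row and never aborts the batch.  Inputs ending in
``.csv`` are read as pre-digitized curve tables, anything else as a
raster report page to digitize.  An optional sidecar metadata CSV
(columns ``source_id``, ``fev1_fvc``) applies the proximal-airway
inclusion filter FEV1/FVC > 0.7; inputs without metadata are processed
unfiltered.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .curve import ExpiratoryCurve
from .digitizer import DEFAULT_CONFIG, DigitizerConfig, ReportPage, digitize_page
from .errors import FvlsadError, InvalidInputError
from .sad_index import compute_indices
from .synthetic import PageLayout

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class PipelineConfig:
    digitizer: DigitizerConfig = DEFAULT_CONFIG
    aspect: float = 1.0
    #: FEV1/FVC threshold for the inclusion filter (applied only when a
    #: sidecar metadata table provides the ratio)
    fev1_fvc_min: float = 0.7

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        try:
            data = tomllib.loads(Path(path).read_text())
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise InvalidInputError(f"unreadable config {path}: {exc}") from exc
        dig = DigitizerConfig(**data.get("digitizer", {}))
        return cls(
            digitizer=dig,
            aspect=float(data.get("aspect", 1.0)),
            fev1_fvc_min=float(data.get("fev1_fvc_min", 0.7)),
        )

    def digest(self) -> str:
        payload = {"digitizer": asdict(self.digitizer), "aspect": self.aspect,
                   "fev1_fvc_min": self.fev1_fvc_min}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    statuses: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for status in self.statuses.values():
            out[status] = out.get(status, 0) + 1
        return out

    @property
    def n_inputs(self) -> int:
        return len(self.statuses)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "n_inputs": self.n_inputs,
            "counts": self.counts,
            "statuses": self.statuses,
            "outputs": self.outputs,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_metadata(path: str | Path | None) -> dict[str, float]:
    if path is None:
        return {}
    df = pd.read_csv(path)
    for col in ("source_id", "fev1_fvc"):
        if col not in df.columns:
            raise InvalidInputError(f"metadata table missing column {col!r}")
    return dict(zip(df["source_id"].astype(str), df["fev1_fvc"].astype(float)))


def run_batch(
    inputs: list[str | Path],
    config: PipelineConfig = PipelineConfig(),
    layout: PageLayout = PageLayout(),
    metadata_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Process every input into an index row; never abort on one failure.

    Returns the indices table (ok rows only, ordered by input path) and
    a manifest with one status per input (``ok`` or an error token).
    """
    if not inputs:
        raise InvalidInputError("no inputs given")
    manifest = RunManifest(version=__version__, config_hash=config.digest())
    metadata = _load_metadata(metadata_csv)
    label = layout.label_template()
    digit_x, digit_y = layout.digit_templates(2)
    rows = []
    for path in sorted(Path(p) for p in inputs):
        key = str(path)
        try:
            sid = path.stem
            ratio = metadata.get(sid)
            if ratio is not None and ratio <= config.fev1_fvc_min:
                manifest.statuses[key] = "excluded-fev1-fvc"
                continue
            if path.suffix.lower() == ".csv":
                curve = ExpiratoryCurve.from_csv(path)
            elif path.suffix.lower() in IMAGE_SUFFIXES:
                page = ReportPage.from_file(path, dpi=config.digitizer.dpi)
                curve, _, _ = digitize_page(
                    page, label, digit_x, digit_y, config.digitizer
                )
            else:
                raise InvalidInputError(f"unsupported input type {path.suffix!r}")
            rec = compute_indices(curve, aspect=config.aspect).to_record()
            rec["input"] = key
            rows.append(rec)
            manifest.statuses[key] = "ok"
        except FvlsadError as exc:
            manifest.statuses[key] = exc.status
    df = pd.DataFrame(rows)
    return df, manifest
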