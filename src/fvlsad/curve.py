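"""The expiratory flow-volume curve container.

An :class:`ExpiratoryCurve` holds the expiratory limb of a flow-volume
loop as ordered ``(volume, flow)`` samples: volume in litres measured
from the start of expiration (0 L) and strictly increasing, flow in
litres per second, non-negative up to a small tracing tolerance, ending
at (FVC, ~0).  All downstream geometry (landmarks, segment fits, the
flattening indices) operates on this object, whether it came from a
traced report image, a pre-digitized table, or the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: tolerance for "flow is zero" at the end of the limb and for slightly
#: negative flows introduced by tracing noise, in L/s
FLOW_EPSILON = 0.05

#: minimum number of samples for a usable curve
MIN_SAMPLES = 10

VALID_SOURCES = ("traced", "tabular", "synthetic")


@dataclass(frozen=True)
class ExpiratoryCurve:
    """Ordered samples of the expiratory flow-volume limb.

    Parameters
    ----------
    volume : ndarray
        Exhaled volume in L, strictly increasing, starting near 0.
    flow : ndarray
        Expiratory flow in L/s, all >= -FLOW_EPSILON; the final sample
        must lie within FLOW_EPSILON of zero.
    source : str
        One of ``traced``, ``tabular``, ``synthetic``.
    source_id : str
        Opaque identifier carried through to index records.
    """

    volume: np.ndarray
    flow: np.ndarray
    source: str = "tabular"
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        f = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "flow", f)
        if self.source not in VALID_SOURCES:
            raise InvalidInputError(f"unknown curve source {self.source!r}")
        if v.ndim != 1 or f.ndim != 1 or v.shape != f.shape:
            raise InvalidInputError("volume and flow must be 1-D arrays of equal length")
        if v.size < MIN_SAMPLES:
            raise InvalidInputError(
                f"curve needs at least {MIN_SAMPLES} samples, got {v.size}"
            )
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(f))):
            raise InvalidInputError("curve samples must be finite")
        if np.any(np.diff(v) <= 0):
            raise InvalidInputError("volume must be strictly increasing")
        if np.any(f < -FLOW_EPSILON):
            raise InvalidInputError(
                f"flow below -{FLOW_EPSILON} L/s: not an expiratory limb"
            )
        if abs(f[-1]) > FLOW_EPSILON:
            raise InvalidInputError(
                f"final flow {f[-1]:.3f} L/s not within {FLOW_EPSILON} of zero"
            )

    def __len__(self) -> int:
        return int(self.volume.size)

    @property
    def fvc(self) -> float:
        """Forced vital capacity: volume of the last sample, in L."""
        return float(self.volume[-1])

    @property
    def peak_flow(self) -> float:
        """Peak expiratory flow in L/s."""
        return float(self.flow.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"volume_L": self.volume, "flow_Lps": self.flow})

    def to_csv(self, path: str | Path) -> None:
        """Write the curve as `volume_L,flow_Lps` CSV, 4 decimal places."""
        self.to_frame().to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[tuple[float, float]],
        source: str = "tabular",
        source_id: str = "",
    ) -> "ExpiratoryCurve":
        arr = np.asarray(list(samples), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidInputError("samples must be (volume, flow) pairs")
        return cls(arr[:, 0], arr[:, 1], source=source, source_id=source_id)

    @classmethod
    def from_csv(cls, path: str | Path, source_id: str | None = None) -> "ExpiratoryCurve":
        """Read a two-column `volume_L,flow_Lps` table (header required)."""
        df = pd.read_csv(path)
        for col in ("volume_L", "flow_Lps"):
            if col not in df.columns:
                raise InvalidInputError(f"{path}: missing column {col!r}")
        sid = source_id if source_id is not None else Path(path).stem
        return cls(
            df["volume_L"].to_numpy(float),
            df["flow_Lps"].to_numpy(float),
            source="tabular",
            source_id=sid,
        )
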