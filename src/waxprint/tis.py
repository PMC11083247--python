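"""Total ion spectrum (TIS) construction and normalization.

A GC/MS run is a scan-by-channel intensity map. Collapsing it along the
retention-time axis gives the total ion spectrum: one intensity per integer
m/z channel, summed over the whole chromatographic range. The TIS is
time-independent, so it can be compared across instruments and runs without
retention-time alignment, and serves as an aroma fingerprint of the sample.

Every spectrum is base-peak normalized (divided by its own maximum) before
entering any distance computation or model, so the fingerprint encodes
relative ion abundances only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GcmsRun",
    "Tis",
    "TisMatrix",
    "collapse_to_tis",
    "base_peak_normalize",
    "assemble_matrix",
    "euclidean_distance",
    "write_matrix_csv",
    "read_matrix_csv",
]

#: Default nominal-mass window of the fingerprint, inclusive (501 channels).
MZ_LO_DEFAULT = 50
MZ_HI_DEFAULT = 550


@dataclass
class GcmsRun:
    """One GC/MS acquisition: scan times, m/z axis and the intensity map.

    ``intensities`` has shape ``(n_scans, n_channels)``; the m/z axis may be
    float (profile mode) and is binned to nominal integer mass on collapse.
    """

    scan_times: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.scan_times.ndim != 1 or self.mz_axis.ndim != 1:
            raise ValueError("scan_times and mz_axis must be 1-D")
        if self.intensities.shape != (self.scan_times.size, self.mz_axis.size):
            raise ValueError(
                f"intensity map shape {self.intensities.shape} does not match "
                f"{self.scan_times.size} scans x {self.mz_axis.size} channels"
            )
        if self.scan_times.size and np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan_times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be sorted and unique")


@dataclass
class Tis:
    """A collapsed (and optionally base-peak-normalized) total ion spectrum."""

    mz_axis: np.ndarray
    values: np.ndarray
    normalized: bool = False
    sample_id: str = ""
    lot: str = ""
    blend_pct: float | None = None
    replicate: str = ""

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.mz_axis.shape != self.values.shape:
            raise ValueError("mz_axis and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("TIS values must be non-negative")
        if self.normalized:
            if not np.isclose(self.values.max(initial=0.0), 1.0):
                raise ValueError("normalized TIS must have max exactly 1")


@dataclass
class TisMatrix:
    """Channel-by-sample matrix of normalized TIS plus sample metadata.

    ``values`` is a DataFrame indexed by integer m/z with one column per
    sample; ``metadata`` has one row per sample (sample_id, lot, blend_pct,
    replicate) in column order.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.metadata) and len(self.metadata) != self.values.shape[1]:
            raise ValueError("metadata rows must match sample columns")

    @property
    def mz_axis(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def X(self) -> np.ndarray:
        """Samples-by-channels array (observations in rows)."""
        return self.values.to_numpy().T


def collapse_to_tis(
    run: GcmsRun, mz_lo: int = MZ_LO_DEFAULT, mz_hi: int = MZ_HI_DEFAULT
) -> Tis:
    """Sum the intensity map over scans, binned to nominal integer mass.

    Channels are rounded to the nearest integer (ties to even); anything
    outside ``[mz_lo, mz_hi]`` is discarded. The result covers the full
    window, with zeros where the run recorded nothing, and is NOT yet
    normalized.
    """
    if run.scan_times.size == 0 or run.mz_axis.size == 0:
        raise ValueError("cannot collapse an empty run")
    if mz_hi < mz_lo:
        raise ValueError("mz_hi must be >= mz_lo")
    nominal = np.rint(np.asarray(run.mz_axis, dtype=float)).astype(int)
    keep = (nominal >= mz_lo) & (nominal <= mz_hi)
    if not keep.any():
        raise ValueError(
            f"run covers no channel in [{mz_lo}, {mz_hi}] "
            f"(run range {run.mz_axis.min()}-{run.mz_axis.max()})"
        )
    totals = run.intensities.sum(axis=0)
    axis = np.arange(mz_lo, mz_hi + 1)
    values = np.zeros(axis.size)
    np.add.at(values, nominal[keep] - mz_lo, totals[keep])
    return Tis(mz_axis=axis, values=values, sample_id=run.sample_id)


def base_peak_normalize(tis: Tis) -> Tis:
    """Divide every channel by the base peak so the maximum is exactly 1."""
    peak = tis.values.max(initial=0.0)
    if peak <= 0:
        raise ValueError(f"all-zero spectrum cannot be normalized: {tis.sample_id!r}")
    out = replace(tis, values=tis.values / peak, normalized=True)
    out.values[np.argmax(out.values)] = 1.0  # guard against rounding
    return out


def assemble_matrix(tis_list: list[Tis]) -> TisMatrix:
    """Stack normalized spectra into the channel-by-sample data matrix."""
    if not tis_list:
        raise ValueError("need at least one TIS")
    axis = tis_list[0].mz_axis
    for t in tis_list:
        if not t.normalized:
            raise ValueError(f"TIS {t.sample_id!r} is not base-peak normalized")
        if not np.array_equal(t.mz_axis, axis):
            raise ValueError("all TIS must share one m/z axis")
    values = pd.DataFrame(
        np.column_stack([t.values for t in tis_list]),
        index=pd.Index(axis, name="mz"),
        columns=[t.sample_id for t in tis_list],
    )
    metadata = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in tis_list],
            "lot": [t.lot for t in tis_list],
            "blend_pct": [t.blend_pct for t in tis_list],
            "replicate": [t.replicate for t in tis_list],
        }
    )
    return TisMatrix(values=values, metadata=metadata)


def euclidean_distance(a: Tis, b: Tis) -> float:
    """Euclidean distance between two normalized spectra.

    This is the response statistic of the headspace optimization: the
    distance between the fingerprints of two odor grades measures how well
    a set of conditions separates them.
    """
    if not (a.normalized and b.normalized):
        raise ValueError("euclidean_distance is defined on normalized TIS only")
    if not np.array_equal(a.mz_axis, b.mz_axis):
        raise ValueError("spectra must share one m/z axis")
    return float(np.linalg.norm(a.values - b.values))


def write_matrix_csv(matrix: TisMatrix, path: str | Path, metadata_path: str | Path | None = None) -> None:
    """Write the matrix as wide CSV (rows = m/z, columns = sample ids)."""
    matrix.values.to_csv(path, float_format="%.17g")
    if metadata_path is not None:
        matrix.metadata.to_csv(metadata_path, index=False)


def read_matrix_csv(path: str | Path, metadata_path: str | Path | None = None) -> TisMatrix:
    values = pd.read_csv(path, index_col=0, float_precision="round_trip")
    values.index = values.index.astype(int)
    values.index.name = "mz"
    metadata = (
        pd.read_csv(metadata_path) if metadata_path is not None else pd.DataFrame()
    )
    return TisMatrix(values=values, metadata=metadata)
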