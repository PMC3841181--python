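"""Total chromatogram mass (TCM) spectra: the per-individual fingerprint.

A TCM spectrum aggregates all intensity observed at each nominal
(integer) m/z over a retention-time window. With the default window of
m/z 200-500 this yields a 300-element vector per individual, which is
the unit compared by the chemometric stage. Nominal mass is ``floor(m/z)``
and bins are half-open ``[m, m+1)``; this is the only convention that
gives exactly ``mz_high - mz_low`` bins for the stated range.

Baseline correction operates per nominal-mass channel: either the
channel's minimum over the retention window (``per_bin_min``) or a
running minimum over a sliding RT window (``rolling_min``) is
subtracted, and the residual is clipped at zero. Correction channelizes
the run onto the integer m/z grid, which is the representation the
fingerprint uses anyway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .msio import MassSpecRun, Scan


class TCMError(ValueError):
    pass


@dataclass(frozen=True)
class BinningConfig:
    """Nominal-mass binning and RT-window parameters for TCM extraction.

    Defaults follow the published acquisition: unit-mass bins over
    m/z 200-500 (300 bins) and a 2-17 min retention window. The
    alternative 2.5 min window start used in some published figures is
    available via ``rt_start``.
    """

    mz_low: int = 200
    mz_high: int = 500
    rt_start: float = 2.0
    rt_end: float = 17.0
    aggregate: str = "sum"           # "sum" | "mean"
    baseline_method: str = "per_bin_min"   # "per_bin_min" | "rolling_min"
    rolling_window: float = 1.0      # minutes, for rolling_min

    def __post_init__(self) -> None:
        if self.mz_low >= self.mz_high:
            raise TCMError(f"mz_low {self.mz_low} must be < mz_high {self.mz_high}")
        if self.rt_start >= self.rt_end:
            raise TCMError(f"rt_start {self.rt_start} must be < rt_end {self.rt_end}")
        if self.aggregate not in ("sum", "mean"):
            raise TCMError(f"unknown aggregate {self.aggregate!r}")
        if self.baseline_method not in ("per_bin_min", "rolling_min"):
            raise TCMError(f"unknown baseline_method {self.baseline_method!r}")
        if self.rolling_window <= 0:
            raise TCMError("rolling_window must be positive")

    @property
    def n_bins(self) -> int:
        return self.mz_high - self.mz_low

    def to_dict(self) -> dict:
        return {
            "mz_low": self.mz_low, "mz_high": self.mz_high,
            "rt_start": self.rt_start, "rt_end": self.rt_end,
            "aggregate": self.aggregate,
            "baseline_method": self.baseline_method,
            "rolling_window": self.rolling_window,
        }


@dataclass
class TCMSpectrum:
    individual_id: str
    values: np.ndarray
    config: BinningConfig = field(default_factory=BinningConfig)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        self.values = vals
        if vals.shape != (self.config.n_bins,):
            raise TCMError(
                f"{self.individual_id}: expected {self.config.n_bins} bins, "
                f"got shape {vals.shape}"
            )
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise TCMError(f"{self.individual_id}: bin values must be finite and >= 0")

    @property
    def bin_labels(self) -> np.ndarray:
        """Nominal masses, ``[mz_low, mz_high)``."""
        return np.arange(self.config.mz_low, self.config.mz_high)


def _window_scans(run: MassSpecRun, config: BinningConfig) -> list[Scan]:
    scans = [s for s in run.scans if config.rt_start <= s.rt <= config.rt_end]
    if not scans:
        raise TCMError(
            f"run {run.individual_id!r}: no scans in RT window "
            f"[{config.rt_start}, {config.rt_end}]"
        )
    return scans


def _channel_matrix(scans: list[Scan]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum each scan's peaks onto the integer nominal-mass grid.

    Returns (channels, rts, matrix) with matrix shape
    (n_channels, n_scans); channels covers every nominal mass observed.
    """
    rts = np.array([s.rt for s in scans])
    chan_set: set[int] = set()
    for s in scans:
        chan_set.update(np.floor(s.mz).astype(int).tolist())
    channels = np.array(sorted(chan_set), dtype=int)
    index = {c: i for i, c in enumerate(channels)}
    mat = np.zeros((channels.size, rts.size))
    for j, s in enumerate(scans):
        nominal = np.floor(s.mz).astype(int)
        for c, inten in zip(nominal, s.intensity):
            mat[index[int(c)], j] += inten
    return channels, rts, mat


def _rolling_min(series: np.ndarray, rts: np.ndarray, window: float) -> np.ndarray:
    """Running minimum over a centered RT window of the given width.

    A small tolerance keeps scans sitting exactly on a window edge
    inside the window despite floating-point grid arithmetic.
    """
    half = window / 2.0 + 1e-9
    lo = np.searchsorted(rts, rts - half, side="left")
    hi = np.searchsorted(rts, rts + half, side="right")
    return np.array([series[a:b].min() for a, b in zip(lo, hi)])


def baseline_correct(run: MassSpecRun, config: BinningConfig | None = None) -> MassSpecRun:
    """Subtract a per-channel baseline estimate; clip residuals at zero.

    ``per_bin_min`` subtracts each nominal-mass channel's minimum over
    the RT window (zero for channels absent from any scan, since absence
    reads as zero intensity). ``rolling_min`` subtracts a running minimum
    over ``config.rolling_window`` minutes, tracking drifting baselines.
    The returned run lives on the integer nominal-mass grid.
    """
    config = config or BinningConfig()
    scans = _window_scans(run, config)
    channels, rts, mat = _channel_matrix(scans)
    if config.baseline_method == "per_bin_min":
        baseline = mat.min(axis=1, keepdims=True)
        corrected = mat - baseline
    else:
        corrected = np.empty_like(mat)
        for i in range(channels.size):
            corrected[i] = mat[i] - _rolling_min(mat[i], rts, config.rolling_window)
    corrected = np.clip(corrected, 0.0, None)
    new_scans = [
        Scan(rt=float(rts[j]), mz=channels.astype(float),
             intensity=corrected[:, j])
        for j in range(rts.size)
    ]
    return MassSpecRun(individual_id=run.individual_id, scans=new_scans)


def extract_tcm(run: MassSpecRun, config: BinningConfig | None = None) -> TCMSpectrum:
    """Bin a run into its TCM fingerprint.

    Only scans with ``rt_start <= rt <= rt_end`` contribute; a peak at
    m/z x lands in bin ``floor(x)`` iff ``mz_low <= floor(x) < mz_high``.
    ``aggregate="sum"`` accumulates; ``"mean"`` divides every bin by the
    number of scans in the window (a per-individual scalar, so the two
    modes give proportional spectra and identical downstream
    correlations).
    """
    config = config or BinningConfig()
    scans = _window_scans(run, config)
    values = np.zeros(config.n_bins)
    for s in scans:
        nominal = np.floor(s.mz).astype(int)
        ok = (nominal >= config.mz_low) & (nominal < config.mz_high)
        np.add.at(values, nominal[ok] - config.mz_low, s.intensity[ok])
    if config.aggregate == "mean":
        values = values / len(scans)
    return TCMSpectrum(individual_id=run.individual_id, values=values, config=config)


def normalize_tcm(spec: TCMSpectrum, mode: str = "none") -> TCMSpectrum:
    """Rescale a fingerprint: ``none`` (identity), ``unit_sum``, ``unit_max``.

    Normalization never changes the downstream correlation matrix
    (Pearson correlation is invariant to per-vector positive scaling);
    it only aids display and cross-run comparison of magnitudes.
    """
    if mode == "none":
        return spec
    if mode not in ("unit_sum", "unit_max"):
        raise TCMError(f"unknown normalization mode {mode!r}")
    denom = spec.values.sum() if mode == "unit_sum" else spec.values.max()
    if denom <= 0:
        raise TCMError(
            f"{spec.individual_id}: cannot {mode}-normalize an all-zero spectrum"
        )
    return TCMSpectrum(individual_id=spec.individual_id,
                       values=spec.values / denom, config=spec.config)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def tcm_table(specs: list[TCMSpectrum]) -> pd.DataFrame:
    """Fingerprints as a DataFrame: rows = individuals, columns = nominal masses."""
    if not specs:
        raise TCMError("no spectra")
    cfg = specs[0].config
    for s in specs[1:]:
        if s.config.to_dict() != cfg.to_dict():
            raise TCMError("spectra have inconsistent binning configs")
    return pd.DataFrame(
        np.vstack([s.values for s in specs]),
        index=pd.Index([s.individual_id for s in specs], name="individual_id"),
        columns=specs[0].bin_labels,
    )


def write_tcm_tsv(specs: list[TCMSpectrum], path: str | Path) -> Path:
    path = Path(path)
    tcm_table(specs).to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_tcm_tsv(path: str | Path, config: BinningConfig | None = None) -> list[TCMSpectrum]:
    df = pd.read_csv(path, sep="\t", index_col="individual_id",
                     float_precision="round_trip")
    cols = [int(c) for c in df.columns]
    config = config or BinningConfig(mz_low=min(cols), mz_high=max(cols) + 1)
    if cols != list(range(config.mz_low, config.mz_high)):
        raise TCMError(f"{path}: columns do not form the nominal-mass grid "
                       f"[{config.mz_low}, {config.mz_high})")
    return [
        TCMSpectrum(individual_id=str(ind), values=row.to_numpy(float), config=config)
        for ind, row in df.iterrows()
    ]


def write_tcm_json(specs: list[TCMSpectrum], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "config": specs[0].config.to_dict() if specs else None,
        "spectra": {s.individual_id: s.values.tolist() for s in specs},
    }
    path.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return path
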