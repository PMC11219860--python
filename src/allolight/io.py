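"""Readers and writers for the delimited trace/trial/titration formats.

All files are comma-separated UTF-8 with ``.`` decimals; lines starting with
``#`` carry metadata (``#key=value``) or unit comments.  Time is always
seconds, zero-based at recording start.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import TitrationCurve, TitrationFamily
from .errors import SchemaError
from .photometry import PhotometryRecording, TrialTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording",
    "read_trials",
    "write_trials",
    "read_titration",
    "write_titration",
    "read_wide_session",
    "read_image_stack",
    "write_table",
]

_TIME_TOL = 1e-6  # relative tolerance on time-grid uniformity


def _read_meta(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_recording(path) -> PhotometryRecording:
    """Read a two-channel recording table ``time_s, ref405, sig465``.

    Sampling rate comes from a ``#fs=`` metadata line or is inferred from
    the time grid.  Shuffled rows are sorted with a warning; a non-uniform
    grid raises an error listing the offending rows.
    """
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["time_s", "ref405", "sig465"], path)
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: rows out of time order; sorting", stacklevel=2)
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
        t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    fs = float(meta["fs"]) if "fs" in meta else 1.0 / np.median(dt)
    bad = np.flatnonzero(np.abs(dt - 1.0 / fs) > _TIME_TOL * max(1.0, 1.0 / fs))
    if bad.size:
        rows = ", ".join(str(i + 1) for i in bad[:10])
        raise SchemaError(f"{path}: non-uniform time grid at row(s) {rows}"
                          + ("..." if bad.size > 10 else ""))
    return PhotometryRecording(time=t, reference=df["ref405"].to_numpy(dtype=float),
                               signal=df["sig465"].to_numpy(dtype=float), fs=fs)


def write_recording(path, rec: PhotometryRecording):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#fs={rec.fs!r}\n")
        fh.write("#units: time_s=s, ref405=a.u., sig465=a.u.\n")
        pd.DataFrame({"time_s": rec.time, "ref405": rec.reference,
                      "sig465": rec.signal}).to_csv(fh, index=False)


def read_trials(path) -> TrialTable:
    """Read a trial table ``onset_s, label``."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["onset_s"], path)
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    return TrialTable(onset_times=df["onset_s"].to_numpy(dtype=float), labels=labels)


def write_trials(path, trials: TrialTable):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#units: onset_s=s\n")
        pd.DataFrame({"onset_s": trials.onset_times,
                      "label": list(trials.labels)}).to_csv(fh, index=False)


def read_titration(path) -> TitrationFamily:
    """Read a titration table ``modulator_conc_M, ligand_conc_M, response_pct``."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["modulator_conc_M", "ligand_conc_M", "response_pct"], path)
    curves = []
    for b, grp in df.groupby("modulator_conc_M"):
        grp = grp.sort_values("ligand_conc_M")
        curves.append(TitrationCurve(
            concentrations=grp["ligand_conc_M"].to_numpy(dtype=float),
            responses=grp["response_pct"].to_numpy(dtype=float),
            modulator_conc=float(b)))
    curves.sort(key=lambda c: c.modulator_conc)
    return TitrationFamily(curves=tuple(curves))


def write_titration(path, family: TitrationFamily):
    rows = []
    for curve in family.curves:
        for c, r in zip(curve.concentrations, curve.responses):
            rows.append((curve.modulator_conc, c, r))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#units: modulator_conc_M=M, ligand_conc_M=M, response_pct=%\n")
        pd.DataFrame(rows, columns=["modulator_conc_M", "ligand_conc_M",
                                    "response_pct"]).to_csv(fh, index=False)


def read_wide_session(path):
    """Read a wide multi-channel table ``time_s, ch01, ch02, ...``.

    Returns ``(time, dff, channel_names)`` with ``dff`` shaped
    (n_channels, n_samples).
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["time_s"], path)
    channels = [c for c in df.columns if c != "time_s"]
    if not channels:
        raise SchemaError(f"{path}: no channel columns beside time_s")
    return (df["time_s"].to_numpy(dtype=float),
            df[channels].to_numpy(dtype=float).T, channels)


def read_image_stack(path, pixel_size_um: float | None = None):
    """Read a greyscale multi-frame TIFF stack.

    Returns ``(frames, pixel_size_um)`` with frames shaped (T, H, W).
    RGB stacks are rejected; a missing pixel size must be supplied via the
    ``pixel_size_um`` override.
    """
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel > 1 or page.photometric in (
                tifffile.PHOTOMETRIC.RGB, tifffile.PHOTOMETRIC.PALETTE):
            raise SchemaError(f"{path}: RGB/multichannel TIFF; expected a "
                              "greyscale (T, H, W) stack")
        arr = tif.asarray()
        if pixel_size_um is None:
            unit = page.tags.get("ResolutionUnit")
            res = page.tags.get("XResolution")
            if (res is not None and unit is not None
                    and unit.value != tifffile.RESUNIT.NONE and res.value[0]):
                num, den = res.value
                pixel_size_um = den / num  # resolution stored as px per unit
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise SchemaError(f"{path}: expected a greyscale (T, H, W) stack, "
                          f"got shape {arr.shape}")
    if pixel_size_um is None:
        raise SchemaError(f"{path}: no pixel size in metadata; pass pixel_size_um "
                          "explicitly (config override)")
    return arr.astype(float), float(pixel_size_um)


def write_table(path, df: pd.DataFrame, units: str = ""):
    """Write a result table with a units comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        if units:
            fh.write(f"#units: {units}\n")
        df.to_csv(fh, index=False)
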