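"""On-disk formats: long-format peak tables (CSV), tensor directories
(manifest + per-sample scan x m/z CSV matrices) and MSP spectral libraries.

Everything is plain text by design: diff-able fixtures, language-agnostic
round trips.  Times are hours, retention times minutes, m/z integer bins.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import PEAK_TABLE_COLUMNS
from .tensor import ThreeWayTensor

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_tensor_dir",
    "write_tensor_dir",
    "read_msp",
    "write_msp",
]


def read_peak_table(path) -> pd.DataFrame:
    """Read a long-format peak table CSV.

    Requires the columns sample_id, group, replicate, time_h, compound,
    intensity.  Empty intensity fields are missing values (zeros are
    legitimate intensities and stay zeros).  Duplicate (sample, compound)
    rows and non-numeric time or intensity entries are errors.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "compound": str})
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table lacks columns: {sorted(missing)}")
    for col in ("time_h", "intensity"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric values in column {col!r}") from exc
    if df["time_h"].isna().any():
        raise ValueError("missing values in column 'time_h'")
    dup = df.duplicated(subset=["sample_id", "compound"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "compound"]].iloc[0].tolist()
        raise ValueError(f"duplicate (sample, compound) rows, e.g. {pairs}")
    return df[PEAK_TABLE_COLUMNS + [c for c in df.columns if c not in PEAK_TABLE_COLUMNS]]


def write_peak_table(table: pd.DataFrame, path) -> None:
    """Write a peak table CSV; missing intensities become empty fields."""
    missing = set(PEAK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"peak table lacks columns: {sorted(missing)}")
    table.to_csv(path, index=False, na_rep="")


def write_tensor_dir(tensor: ThreeWayTensor, path) -> None:
    """Write a tensor directory: manifest.csv plus one CSV matrix per sample.

    Each sample file has retention_time_min as its first column and one
    column per m/z bin; all samples share the m/z header.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mz_cols = [str(m) for m in np.asarray(tensor.mz_axis).tolist()]
    records = []
    for sid, slab, rt in zip(tensor.sample_ids, tensor.slabs,
                             tensor.retention_time_axes):
        fname = f"{re.sub(r'[^A-Za-z0-9_.-]', '_', sid)}.csv"
        frame = pd.DataFrame(slab, columns=mz_cols)
        frame.insert(0, "retention_time_min", rt)
        frame.to_csv(path / fname, index=False)
        records.append({"sample_id": sid, "file": fname})
    pd.DataFrame(records).to_csv(path / "manifest.csv", index=False)


def read_tensor_dir(path) -> ThreeWayTensor:
    """Read a tensor directory written by :func:`write_tensor_dir`.

    Slab order follows the manifest; a divergent m/z header or a manifest
    entry without its file is an error naming the offending sample.
    """
    path = Path(path)
    manifest_path = path / "manifest.csv"
    if not manifest_path.exists():
        raise ValueError(f"no manifest.csv in {path}")
    manifest = pd.read_csv(manifest_path, dtype=str)
    if not {"sample_id", "file"} <= set(manifest.columns):
        raise ValueError("manifest must have sample_id and file columns")
    slabs, rts, sample_ids = [], [], []
    mz_header = None
    for _, row in manifest.iterrows():
        sid, fname = row["sample_id"], row["file"]
        fpath = path / fname
        if not fpath.exists():
            raise ValueError(f"manifest references missing file {fname!r} "
                             f"for sample {sid!r}")
        frame = pd.read_csv(fpath)
        if frame.columns[0] != "retention_time_min":
            raise ValueError(
                f"first column of {fname!r} must be retention_time_min"
            )
        header = list(frame.columns[1:])
        if mz_header is None:
            mz_header = header
        elif header != mz_header:
            raise ValueError(f"m/z header mismatch for sample {sid!r}")
        rts.append(frame["retention_time_min"].to_numpy(dtype=float))
        slabs.append(frame[header].to_numpy(dtype=float))
        sample_ids.append(sid)
    mz_axis = np.array([float(m) for m in mz_header])
    if np.allclose(mz_axis, np.round(mz_axis)):
        mz_axis = np.round(mz_axis).astype(int)
    return ThreeWayTensor(slabs=slabs, retention_time_axes=rts,
                          mz_axis=mz_axis, sample_ids=sample_ids)


def _validate_msp_text(path) -> None:
    """Light structural check matchms does not perform: every record's
    "Num Peaks" count must match its number of peak pairs."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"MSP file {path} is empty")
    blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
    pair_re = re.compile(r"^\s*\d+(?:\.\d+)?[\s;]+-?\d")
    for i, block in enumerate(blocks):
        declared = None
        n_pairs = 0
        for line in block.splitlines():
            m = re.match(r"(?i)^\s*num\s*peaks\s*:\s*(\d+)", line)
            if m:
                declared = int(m.group(1))
                continue
            if declared is not None and pair_re.match(line):
                n_pairs += len(re.findall(r"\d+(?:\.\d+)?[\s:]+\d+(?:\.\d+)?;?",
                                          line)) or 1
        if declared is not None and declared != n_pairs:
            raise ValueError(
                f"MSP record {i + 1}: Num Peaks declares {declared} but "
                f"{n_pairs} peak pairs found"
            )


def read_msp(path) -> list:
    """Read an MSP spectral library into matchms Spectrum objects.

    Records may appear in any order separated by blank lines; a record whose
    peak list disagrees with its Num Peaks declaration is an error.
    """
    from matchms.importing import load_from_msp

    from .utils import quiet_matchms

    quiet_matchms()
    _validate_msp_text(path)
    spectra = [s for s in load_from_msp(str(path)) if s is not None]
    if not spectra:
        raise ValueError(f"no spectra parsed from {path}")
    return spectra


def write_msp(library: Sequence, path) -> None:
    """Write matchms Spectrum objects to an MSP file."""
    from matchms.exporting import save_as_msp

    from .utils import quiet_matchms

    quiet_matchms()
    path = str(path)
    if os.path.exists(path):
        os.remove(path)  # save_as_msp appends
    save_as_msp(list(library), path)
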