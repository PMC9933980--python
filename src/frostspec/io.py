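"""Readers and writers for the package's tabular and cube artifacts.

Spectrum matrices travel as CSV with a ``sample_id`` first column and one
column per band named by wavelength (nm, 3 decimals), plus a companion
wavelength listing; biochemical panels as plain CSV; cubes as HDF5 with
wavelength metadata; band subsets as JSON.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .selection import BandSubset
from .simulate import SpectralCube, SpectrumMatrix


def write_spectra(spectra: SpectrumMatrix, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        spectra.values,
        columns=[f"{wl:.3f}" for wl in spectra.wavelengths],
    )
    frame.insert(0, "sample_id", spectra.sample_ids)
    frame.to_csv(path, index=False)
    companion = path.with_suffix(".wavelengths.txt")
    np.savetxt(companion, spectra.wavelengths, fmt="%.6f")


def read_spectra(path: str | Path) -> SpectrumMatrix:
    frame = pd.read_csv(path)
    ids = frame["sample_id"].astype(str).tolist()
    bands = [c for c in frame.columns if c != "sample_id"]
    return SpectrumMatrix(
        values=frame[bands].to_numpy(dtype=float),
        wavelengths=np.array([float(c) for c in bands]),
        sample_ids=ids,
        provenance=[f"read({Path(path).name})"],
    )


def write_panel(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("reflectance", data=cube.values)
        fh.create_dataset("wavelengths_nm", data=cube.wavelengths)
        fh.create_dataset("leaf_mask", data=cube.leaf_mask)


def read_cube(path: str | Path) -> SpectralCube:
    with h5py.File(path, "r") as fh:
        return SpectralCube(
            values=fh["reflectance"][...],
            wavelengths=fh["wavelengths_nm"][...],
            leaf_mask=fh["leaf_mask"][...].astype(bool),
        )


def write_subset(subset: BandSubset, path: str | Path) -> None:
    Path(path).write_text(subset.to_json())


def read_subset(path: str | Path) -> BandSubset:
    return BandSubset.from_json(Path(path).read_text())
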