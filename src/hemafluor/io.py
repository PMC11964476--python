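"""Readers and writers for the spectrum, EEM, and CBC formats.

Spectra are two-column ASCII (tab or comma separated) with ``#``-prefixed
metadata header lines; EEMs are CSV matrices with excitation wavelengths down
the first column and emission wavelengths across the first row; CBC records
travel as CSV or JSON. All numerics are written with 9 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import EEMatrix, Spectrum1D
from .synthetic import CBCRecord

logger = logging.getLogger("hemafluor")

_FMT = "%.9g"


def _format(value: float) -> str:
    return _FMT % value


def write_spectrum(s: Spectrum1D, path: str | Path, dialect: str = "tsv") -> None:
    """Write a spectrum as two-column ASCII with '#' metadata headers."""
    sep = "\t" if dialect == "tsv" else ","
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# role: {s.role}\n")
        if s.source is not None:
            fh.write(f"# source: {s.source}\n")
        for key, value in s.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(f"# columns: wavelength_nm{sep}intensity_au\n")
        for wl, ii in zip(s.wavelengths, s.intensities):
            fh.write(f"{_format(wl)}{sep}{_format(ii)}\n")


def read_spectrum(path: str | Path, dialect: str = "auto") -> Spectrum1D:
    """Read a two-column ASCII spectrum.

    Accepts tab, comma, or whitespace delimiters (``auto``), skips
    ``#``-prefixed header lines (parsed into metadata where they look like
    ``key: value``), validates strictly increasing wavelengths — a reversed
    grid is sorted with a warning, duplicates are an error.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    wavelengths: list[float] = []
    intensities: list[float] = []
    role = "emission"
    source = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key, value = key.strip(), value.strip()
                    if key == "role":
                        role = value
                    elif key == "source":
                        source = value
                    else:
                        meta[key] = value
                continue
            if dialect == "tsv":
                parts = line.split("\t")
            elif dialect == "csv":
                parts = line.split(",")
            else:
                parts = line.replace(",", " ").replace("\t", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                wl, ii = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric body line {line!r}") from exc
            wavelengths.append(wl)
            intensities.append(ii)

    wl_arr = np.asarray(wavelengths)
    ii_arr = np.asarray(intensities)
    uniq, counts = np.unique(wl_arr, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise ValueError(f"{path}: duplicate wavelength {dup} nm")
    if not np.all(np.diff(wl_arr) > 0):
        warnings.warn(f"{path}: wavelengths not increasing; sorting", stacklevel=2)
        logger.warning("%s: wavelengths not increasing; sorting", path)
        order = np.argsort(wl_arr)
        wl_arr, ii_arr = wl_arr[order], ii_arr[order]

    return Spectrum1D(
        wavelengths=wl_arr, intensities=ii_arr, role=role, source=source, meta=meta
    )


def write_eem(eem: EEMatrix, path: str | Path) -> None:
    """CSV matrix: first row emission wavelengths, first column excitation."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ex_nm\\em_nm," + ",".join(_format(w) for w in eem.em_wavelengths) + "\n")
        for i, ex in enumerate(eem.ex_wavelengths):
            row = ",".join(_format(v) for v in eem.intensities[i])
            fh.write(f"{_format(ex)},{row}\n")


def read_eem(path: str | Path) -> EEMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        em = np.asarray([float(v) for v in header[1:]])
        ex_list, rows = [], []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            ex_list.append(float(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    return EEMatrix(
        ex_wavelengths=np.asarray(ex_list), em_wavelengths=em, intensities=np.asarray(rows)
    )


_CBC_FIELDS = [f.name for f in dataclasses.fields(CBCRecord)]


def write_cbc(records: list[CBCRecord], path: str | Path) -> None:
    """Write CBC records as CSV (``.csv``) or JSON (``.json``)."""
    path = Path(path)
    dicts = [dataclasses.asdict(r) for r in records]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(dicts, fh, indent=2)
    else:
        pd.DataFrame(dicts, columns=_CBC_FIELDS).to_csv(path, index=False)


def read_cbc(path: str | Path) -> list[CBCRecord]:
    """Read CBC records from CSV or JSON produced by :func:`write_cbc`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            dicts = json.load(fh)
    else:
        frame = pd.read_csv(path)
        dicts = frame.to_dict(orient="records")
    records = []
    for d in dicts:
        kwargs = {}
        for key, value in d.items():
            if key not in _CBC_FIELDS:
                raise ValueError(f"{path}: unknown CBC field {key!r}")
            if isinstance(value, float) and np.isnan(value):
                value = None
            kwargs[key] = value
        records.append(CBCRecord(**kwargs))
    return records
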