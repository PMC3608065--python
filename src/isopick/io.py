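"""Readers, writers and flat configuration files.

Spectra are read from mzML (first or indexed profile spectrum) or from
two-column text; peaklists are written as CSV with a JSON config sidecar;
configurations round-trip through flat key=value files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .peakshape import ParameterError, Spectrum
from .postprocess import Peaklist

__all__ = [
    "read_spectrum",
    "write_spectrum_text",
    "write_peaklist",
    "write_truth_csv",
    "PipelineConfig",
]

logger = logging.getLogger("isopick")


class SpectrumReadError(ValueError):
    pass


def _read_text(path: Path) -> Spectrum:
    mzs, intens = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if lineno == 1 and not _is_number(parts[0]):
                continue  # header line
            if len(parts) < 2 or not (_is_number(parts[0]) and _is_number(parts[1])):
                raise SpectrumReadError(f"{path}: malformed row at line {lineno}: {line.rstrip()!r}")
            mzs.append(float(parts[0]))
            intens.append(float(parts[1]))
    if not mzs:
        raise SpectrumReadError(f"{path}: no data rows")
    return _validated(np.array(mzs), np.array(intens), str(path))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


_MZML_DTYPE = {"MS:1000523": "d", "MS:1000521": "f"}  # 64- / 32-bit float
_MZML_ARRAY = {"MS:1000514": "mz", "MS:1000515": "intensity"}


def _decode_binary_array(elem) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (array kind, values)."""
    import base64
    import struct
    import zlib

    dtype, kind, compressed = "d", None, False
    payload = ""
    for child in elem.iter():
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc in _MZML_DTYPE:
                dtype = _MZML_DTYPE[acc]
            elif acc in _MZML_ARRAY:
                kind = _MZML_ARRAY[acc]
            elif acc == "MS:1000574":
                compressed = True
        elif tag == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    values = np.array(struct.unpack(f"<{len(raw) // width}{dtype}", raw), dtype=float)
    return kind, values


def _read_mzml(path: Path, index: int = 0) -> Spectrum:
    """Minimal mzML reader for profile spectra: base64-encoded 32/64-bit
    float m/z and intensity arrays, plain or zlib-compressed."""
    from lxml import etree

    seen = 0
    for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
        if seen == index:
            arrays = {}
            for bda in elem.iter("{*}binaryDataArray"):
                kind, values = _decode_binary_array(bda)
                if kind:
                    arrays[kind] = values
            if "mz" not in arrays or "intensity" not in arrays:
                raise SpectrumReadError(f"{path}: spectrum {index} lacks m/z or intensity arrays")
            return _validated(arrays["mz"], arrays["intensity"], str(path))
        seen += 1
        elem.clear()
    raise SpectrumReadError(f"{path}: no spectrum at index {index}")


def _validated(mz: np.ndarray, inten: np.ndarray, origin: str) -> Spectrum:
    if np.any(inten < 0):
        raise SpectrumReadError(f"{origin}: negative intensities present")
    if np.any(np.diff(mz) < 0):
        warnings.warn(f"{origin}: m/z values unsorted; sorting", stacklevel=3)
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
    if np.any(np.diff(mz) == 0):
        warnings.warn(f"{origin}: duplicate m/z values; averaging", stacklevel=3)
        uniq, inverse = np.unique(mz, return_inverse=True)
        sums = np.zeros_like(uniq)
        counts = np.zeros_like(uniq)
        np.add.at(sums, inverse, inten)
        np.add.at(counts, inverse, 1.0)
        mz, inten = uniq, sums / counts
    return Spectrum(mz=mz, intensity=inten)


def read_spectrum(path, format: str | None = None, index: int = 0) -> Spectrum:
    """Read a profile spectrum from mzML or a two-column text file.

    The format is inferred from the extension unless given; text files may
    carry an optional header line and comma or whitespace separators.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "text"
    if format == "mzml":
        return _read_mzml(path, index)
    if format == "text":
        return _read_text(path)
    raise ParameterError(f"unknown spectrum format {format!r}")


def write_spectrum_text(spectrum: Spectrum, path) -> None:
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]), fmt="%.6f %.8g")


PEAKLIST_COLUMNS = [
    "monoisotopic_mz",
    "charge",
    "neutral_mass",
    "intensity",
    "ratio",
    "lnl_plus",
    "gof_plus",
    "anchor_mz",
]


def write_peaklist(peaklist: Peaklist, path) -> None:
    """Write a peaklist as CSV (masses at 6 decimals) plus a JSON config
    sidecar ``<path>.config.json``."""
    path = Path(path)
    rows = [
        {
            "monoisotopic_mz": f.monoisotopic_mz,
            "charge": f.charge,
            "neutral_mass": f.neutral_mass,
            "intensity": f.coefficient,
            "ratio": f.ratio,
            "lnl_plus": f.lnl_plus,
            "gof_plus": f.gof_plus,
            "anchor_mz": f.location,
        }
        for f in peaklist.features
    ]
    frame = pd.DataFrame(rows, columns=PEAKLIST_COLUMNS)
    for col in ("monoisotopic_mz", "neutral_mass", "anchor_mz"):
        frame[col] = frame[col].map(lambda v: f"{v:.6f}")
    frame.to_csv(path, index=False)
    sidecar = path.with_name(path.name + ".config.json")
    meta = dict(peaklist.metadata)
    meta["threshold"] = peaklist.threshold
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_peaklist(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_csv(truth, path) -> None:
    frame = pd.DataFrame(
        [
            {
                "charge": t.charge,
                "monoisotopic_mz": t.monoisotopic_mz,
                "anchor_mz": t.anchor_mz,
                "mass": t.mass,
                "height": t.height,
            }
            for t in truth
        ]
    )
    frame.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Flat, serializable pipeline configuration with the method defaults."""

    charges: tuple = (1, 2, 3, 4)
    peak_shape: str = "gaussian"
    q: int = 2
    window_h: float = 2.5
    factor_place: float = 1.5
    merge_ppm: float = 100.0
    threshold: float = 5.0
    kappa: float = 1.00235
    mass_filter: bool = False
    mass_filter_ppm: float = 200.0
    sigma: float | None = None
    alpha: float | None = None
    mu: float = 0.0
    gamma0: float = 10.0
    gamma_mult: float = 10.0
    gamma_max: float = 1e8
    seed: int | None = None
    log_level: str = "WARNING"

    def __post_init__(self):
        for name in ("window_h", "factor_place", "merge_ppm", "kappa", "gamma0", "gamma_max"):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be positive")
        if self.threshold < 0:
            raise ParameterError("threshold must be >= 0")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        values = {}
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if not s or s.startswith("#") or "=" not in s:
                    continue
                key, raw = (part.strip() for part in s.split("=", 1))
                values[key] = raw
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if f.name == "charges":
                kwargs[f.name] = tuple(int(x) for x in raw.split(",") if x)
            elif raw == "None":
                kwargs[f.name] = None
            elif f.name in ("q",):
                kwargs[f.name] = int(raw)
            elif f.name in ("seed",):
                kwargs[f.name] = int(raw)
            elif f.name in ("mass_filter",):
                kwargs[f.name] = raw in ("True", "true", "1")
            elif f.name in ("peak_shape", "log_level"):
                kwargs[f.name] = raw
            else:
                kwargs[f.name] = float(raw)
        return cls(**kwargs)

    def shape_params(self):
        from .peakshape import PeakShapeParams

        if self.sigma is None:
            return None
        return PeakShapeParams(sigma=self.sigma, alpha=self.alpha, mu=self.mu)

    def solver_config(self):
        from .solvers import SolverConfig

        return SolverConfig(gamma0=self.gamma0, mult=self.gamma_mult, gamma_max=self.gamma_max)
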