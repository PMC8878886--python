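"""File I/O: spectra as two-column CSV or JCAMP-DX (1D real, AFFN and
(X++(Y..Y)) forms), peak tables and region matrices as CSV, reports as JSON.

The JCAMP-DX support is a deliberately small dialect: single-block 1D real
spectra with ##XYDATA=(X++(Y..Y)) in AFFN encoding, which round-trips the
package's own output and covers plainly exported instrument data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Spectrum
from .regions import RegionDefinition, RegionMatrix
from .simulate import AcquisitionParams

__all__ = [
    "FormatError",
    "read_fid",
    "write_fid",
    "read_spectrum",
    "write_spectrum",
    "read_region_matrix",
    "write_region_matrix",
    "write_peak_table",
    "write_report",
]


class FormatError(ValueError):
    """Malformed spectrum / table file; message cites the offending line."""


def _spectrum_from_arrays(ppm: np.ndarray, intensity: np.ndarray,
                          freq_mhz: float = 600.0) -> Spectrum:
    order = np.argsort(ppm)[::-1]
    acq = AcquisitionParams(spectrometer_freq_mhz=freq_mhz)
    return Spectrum(ppm=ppm[order], intensity=intensity[order],
                    complex_data=None, f_norm=None, acquisition=acq,
                    calibrated=True, processing_log=["loaded from file"])


# --------------------------------------------------------------------------
# FIDs (internal serialization: CSV of real,imag plus a JSON header line)
# --------------------------------------------------------------------------

def write_fid(fid, path: str | Path) -> None:
    """Serialize an FID as CSV: a commented JSON header with the acquisition
    parameters, then one (real, imag) row per complex point."""
    from .simulate import FID  # local import to avoid a cycle at module load
    assert isinstance(fid, FID)
    acq = fid.acquisition
    header = {
        "dwell_s": fid.dwell_s,
        "spectrometer_freq_mhz": acq.spectrometer_freq_mhz,
        "spectral_width_ppm": acq.spectral_width_ppm,
        "n_points_td": acq.n_points_td,
        "n_cpmg_pulses": acq.n_cpmg_pulses,
        "spin_rate_hz": acq.spin_rate_hz,
        "recycle_time_s": acq.recycle_time_s,
        "carrier_ppm": acq.carrier_ppm,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("real,imag\n")
        for z in fid.points:
            fh.write(f"{z.real:.12g},{z.imag:.12g}\n")


def read_fid(path: str | Path):
    """Read an FID written by :func:`write_fid`."""
    from .simulate import FID, AcquisitionParams as AP
    p = Path(path)
    with open(p) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{p}:1: missing FID header line")
        try:
            header = json.loads(first.lstrip("# "))
        except json.JSONDecodeError:
            raise FormatError(f"{p}:1: malformed FID header") from None
        re_im = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("real"):
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise FormatError(f"{p}:{lineno}: expected 2 columns")
            try:
                re_im.append((float(cells[0]), float(cells[1])))
            except ValueError:
                raise FormatError(f"{p}:{lineno}: non-numeric value") from None
    arr = np.asarray(re_im)
    dwell = float(header.pop("dwell_s"))
    acq = AP(**header)
    return FID(points=arr[:, 0] + 1j * arr[:, 1], dwell_s=dwell, acquisition=acq)


# --------------------------------------------------------------------------
# CSV spectra
# --------------------------------------------------------------------------

def _read_spectrum_csv(path: Path) -> Spectrum:
    ppm, intensity = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and any(c.isalpha() for c in line):
                continue  # header row
            cells = line.split(",")
            if len(cells) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            try:
                ppm.append(float(cells[0]))
                intensity.append(float(cells[1]))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value in {line!r}") from None
    if not ppm:
        raise FormatError(f"{path}: no data rows")
    return _spectrum_from_arrays(np.array(ppm), np.array(intensity))


def _write_spectrum_csv(spectrum: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ppm,intensity\n")
        for p, v in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{p:.10g},{v:.10g}\n")


# --------------------------------------------------------------------------
# JCAMP-DX
# --------------------------------------------------------------------------

def _write_spectrum_jcamp(spectrum: Spectrum, path: Path, title: str) -> None:
    # evenly spaced, increasing X internally; stored down-field first is fine
    ppm = spectrum.ppm
    y = spectrum.intensity
    n = ppm.size
    yfactor = max(np.abs(y).max(), 1e-300) / 2**30
    with open(path, "w") as fh:
        fh.write(f"##TITLE={title}\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=PPM\n")
        fh.write("##YUNITS=ARBITRARY\n")
        fh.write(f"##NPOINTS={n}\n")
        fh.write(f"##FIRSTX={ppm[0]:.10g}\n")
        fh.write(f"##LASTX={ppm[-1]:.10g}\n")
        fh.write("##XFACTOR=1.0\n")
        fh.write(f"##YFACTOR={yfactor:.10g}\n")
        fh.write(f"##FIRSTY={y[0]:.10g}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        step = (ppm[-1] - ppm[0]) / (n - 1) if n > 1 else 0.0
        per_line = 6
        for i in range(0, n, per_line):
            x = ppm[0] + i * step
            ints = " ".join(str(int(round(v / yfactor))) for v in y[i:i + per_line])
            fh.write(f"{x:.8f} {ints}\n")
        fh.write("##END=\n")


def _read_spectrum_jcamp(path: Path) -> Spectrum:
    header: dict[str, str] = {}
    ys: list[float] = []
    xs_first: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                if in_data and not line.upper().startswith("##END"):
                    in_data = False
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                header[key] = value.strip()
                if key == "XYDATA":
                    if value.strip().upper().replace(" ", "") != "(X++(Y..Y))":
                        raise FormatError(
                            f"{path}:{lineno}: unsupported XYDATA form {value.strip()!r}")
                    in_data = True
                continue
            if in_data:
                cells = line.replace(",", " ").split()
                if len(cells) < 2:
                    raise FormatError(f"{path}:{lineno}: malformed data line {line!r}")
                try:
                    xs_first.append(float(cells[0]))
                    ys.extend(float(c) for c in cells[1:])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value in {line!r}") from None
    for needed in ("NPOINTS", "FIRSTX", "LASTX"):
        if needed not in header:
            raise FormatError(f"{path}: missing ##{needed}")
    n = int(header["NPOINTS"])
    if len(ys) != n:
        raise FormatError(
            f"{path}: NPOINTS={n} but {len(ys)} ordinates parsed")
    firstx, lastx = float(header["FIRSTX"]), float(header["LASTX"])
    xfactor = float(header.get("XFACTOR", "1.0"))
    yfactor = float(header.get("YFACTOR", "1.0"))
    ppm = np.linspace(firstx, lastx, n) * xfactor
    y = np.asarray(ys) * yfactor
    return _spectrum_from_arrays(ppm, y)


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a processed spectrum from two-column CSV or JCAMP-DX (inferred
    from the extension unless ``format`` is given)."""
    p = Path(path)
    fmt = format or ("jcamp_dx" if p.suffix.lower() in (".jdx", ".dx", ".jcamp")
                     else "csv")
    if fmt == "jcamp_dx":
        return _read_spectrum_jcamp(p)
    if fmt == "csv":
        return _read_spectrum_csv(p)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   format: str | None = None, title: str = "plasmanmr") -> None:
    p = Path(path)
    fmt = format or ("jcamp_dx" if p.suffix.lower() in (".jdx", ".dx", ".jcamp")
                     else "csv")
    if fmt == "jcamp_dx":
        _write_spectrum_jcamp(spectrum, p, title)
    elif fmt == "csv":
        _write_spectrum_csv(spectrum, p)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


# --------------------------------------------------------------------------
# tables and reports
# --------------------------------------------------------------------------

def write_peak_table(tables: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Concatenate per-sample peak tables into one CSV with a sample_id
    column first."""
    rows = []
    for sid, pk in tables.items():
        t = pk.copy()
        t.insert(0, "sample_id", sid)
        rows.append(t)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "segment_id", "center_ppm", "height", "fwhm_hz",
                 "gauss_fraction", "integral"])
    cols = ["sample_id", "segment_id", "center_ppm", "height", "fwhm_hz",
            "gauss_fraction", "integral"]
    out[cols].to_csv(path, index=False)


def write_region_matrix(matrix: RegionMatrix, path: str | Path,
                        sidecar: str | Path | None = None) -> None:
    frame = matrix.values.copy()
    frame.insert(0, "sample_id", frame.index)
    frame.to_csv(path, index=False)
    if sidecar is not None:
        mapping = {str(r.region_id): {"lo_ppm": r.lo_ppm, "hi_ppm": r.hi_ppm,
                                      "label": r.label,
                                      "candidate_metabolites": list(r.candidate_metabolites)}
                   for r in matrix.regions}
        with open(sidecar, "w") as fh:
            json.dump(mapping, fh, indent=1)


def read_region_matrix(path: str | Path,
                       sidecar: str | Path | None = None) -> RegionMatrix:
    frame = pd.read_csv(path)
    if "sample_id" not in frame.columns:
        raise FormatError(f"{path}: missing sample_id column")
    frame = frame.set_index("sample_id")
    frame.index.name = None
    regions = []
    if sidecar is not None:
        with open(sidecar) as fh:
            mapping = json.load(fh)
        for rid, rec in sorted(mapping.items(), key=lambda kv: int(kv[0])):
            regions.append(RegionDefinition(
                region_id=int(rid), lo_ppm=rec["lo_ppm"], hi_ppm=rec["hi_ppm"],
                candidate_metabolites=tuple(rec.get("candidate_metabolites", ()))))
    else:
        for i, col in enumerate(frame.columns):
            lo, hi = col.lstrip("r").split("-")
            regions.append(RegionDefinition(region_id=i, lo_ppm=float(lo),
                                            hi_ppm=float(hi)))
    return RegionMatrix(sample_ids=list(frame.index), regions=regions,
                        values=frame)


def write_report(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=default)
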