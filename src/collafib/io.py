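"""Plain-text and TIFF readers/writers for every pipeline artifact.

Images are 32-bit float grayscale TIFF with the physical pixel size in a
sidecar JSON; labels and reports are TSV; curves and decays are headered
two-column TSV with ``# key=value`` metadata lines; spectra are two-column
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flim import DecayHistogram
from .ftir import Spectrum
from .mechanics import ForceCurve
from .synthetic import LABEL_COLUMNS
from .texture import AFMImage, ChangeRow, ConsistencyReport


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_afm_tiff(path: str | Path, image: AFMImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.heights.astype(np.float32))
    _sidecar(path).write_text(json.dumps(
        {"px_size_nm": image.px_size_nm, "id": image.id}, indent=1))


def read_afm_tiff(path: str | Path, px_size_nm: float | None = None) -> AFMImage:
    path = Path(path)
    heights = np.asarray(tifffile.imread(path), dtype=float)
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    px = px_size_nm if px_size_nm is not None else meta.get("px_size_nm")
    if px is None:
        raise ValueError(f"no pixel size for {path}: sidecar missing and none given")
    return AFMImage(heights=heights, px_size_nm=float(px), id=meta.get("id", path.stem))


def write_labels_tsv(path: str | Path, labels: pd.DataFrame) -> None:
    labels.loc[:, list(LABEL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label file {path} missing columns {sorted(missing)}")
    return df


# --- headered two-column text files ---

def _write_two_column(
    path: Path, meta: dict, header: tuple[str, str],
    col_a: np.ndarray, col_b: np.ndarray, sep: str, fmt_b: str = "%.8g",
) -> None:
    lines = [f"# {k}={v}" for k, v in meta.items()]
    lines.append(sep.join(header))
    for a, b in zip(col_a, col_b):
        lines.append(f"{a:.8g}{sep}{fmt_b % b}")
    path.write_text("\n".join(lines) + "\n")


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def write_force_curve_tsv(path: str | Path, curve: ForceCurve) -> None:
    _write_two_column(
        Path(path),
        {
            "direction": curve.direction,
            "spring_constant_N_per_m": curve.spring_constant_N_per_m,
            "id": curve.id,
        },
        ("distance_nm", "force_nN"),
        curve.distance_nm, curve.force_nN, sep="\t",
    )


def read_force_curve_tsv(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return ForceCurve(
        distance_nm=df["distance_nm"].to_numpy(),
        force_nN=df["force_nN"].to_numpy(),
        direction=meta.get("direction", "extend"),
        spring_constant_N_per_m=float(meta.get("spring_constant_N_per_m", 2.8)),
        id=meta.get("id", path.stem),
    )


def write_decay_tsv(path: str | Path, hist: DecayHistogram) -> None:
    _write_two_column(
        Path(path),
        {"bin_width_ps": hist.bin_width_ps, "id": hist.id},
        ("time_ns", "counts"),
        hist.bin_centers_ns, hist.counts, sep="\t", fmt_b="%d",
    )


def read_decay_tsv(path: str | Path) -> DecayHistogram:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return DecayHistogram(
        bin_centers_ns=df["time_ns"].to_numpy(),
        counts=df["counts"].to_numpy(),
        bin_width_ps=float(meta.get("bin_width_ps", 50.0)),
        id=meta.get("id", path.stem),
    )


def write_spectrum_csv(path: str | Path, spectrum: Spectrum) -> None:
    pd.DataFrame({
        "wavenumber_cm1": spectrum.wavenumbers_cm1,
        "absorbance": spectrum.absorbance,
    }).to_csv(path, index=False, float_format="%.8g")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    return Spectrum(
        wavenumbers_cm1=df["wavenumber_cm1"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        id=path.stem,
    )


# --- report tables ---

def consistency_frame(reports: list[ConsistencyReport]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "metric": r.metric,
            "consistency_pct": r.consistency_pct,
            "threshold_pct": r.threshold_pct,
            "n": r.n_rois,
        }
        for r in reports
    ])


def change_frame(rows: list[ChangeRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "metric": r.metric,
            "control_prevalence_pct": r.control_prevalence_pct,
            "irradiated_prevalence_pct": r.irradiated_prevalence_pct,
            "change_pct": r.change_pct,
            "threshold_pct": r.threshold_pct,
            "exceeds": int(r.exceeds),
        }
        for r in rows
    ])


def write_table(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
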