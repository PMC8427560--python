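"""Plain-text interchange: spectrum CSV, design/manifest tables, model JSON.

Spectra are two-column CSV (``wavenumber_cm-1,absorbance_AU``) with
acquisition metadata in leading ``#`` comment lines; values round-trip at
full double precision.  Malformed files are rejected with the offending
line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import PLSRModel
from .preprocess import OutlierReport
from .synthspec import (
    ANALYTES,
    ConcentrationSample,
    Design,
    Spectrum,
    WavenumberGrid,
)

SPECTRUM_HEADER = "wavenumber_cm-1,absorbance_AU"
DESIGN_COLUMNS = ["sample_id", "glucose_mM", "lactate_mM", "pyruvate_mM"]


def _fmt(value: float) -> str:
    return f"{value:.17g}"


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# path_length_um: {_fmt(spectrum.path_length_um)}",
        f"# n_sweeps_averaged: {spectrum.n_sweeps_averaged}",
        f"# label: {spectrum.label}",
        f"# is_artifact: {str(spectrum.is_artifact).lower()}",
        SPECTRUM_HEADER,
    ]
    lines += [
        f"{_fmt(nu)},{_fmt(ab)}"
        for nu, ab in zip(spectrum.grid.values, spectrum.absorbance)
    ]
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    meta: dict[str, str] = {}
    wavenumbers: list[float] = []
    absorbances: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            if line != SPECTRUM_HEADER:
                raise ValueError(
                    f"{path}:{lineno}: expected header {SPECTRUM_HEADER!r}, "
                    f"got {line!r}"
                )
            header_seen = True
            continue
        fields = line.split(",")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two comma-separated values")
        try:
            nu, ab = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
        if not (np.isfinite(nu) and np.isfinite(ab)):
            raise ValueError(f"{path}:{lineno}: non-finite value")
        if wavenumbers and nu <= wavenumbers[-1]:
            raise ValueError(
                f"{path}:{lineno}: wavenumbers must be strictly increasing"
            )
        wavenumbers.append(nu)
        absorbances.append(ab)
    if not header_seen:
        raise ValueError(f"{path}: missing header line {SPECTRUM_HEADER!r}")
    if len(wavenumbers) < 2:
        raise ValueError(f"{path}: need at least two data rows")
    values = np.array(wavenumbers)
    resolution = float(values[1] - values[0])
    return Spectrum(
        grid=WavenumberGrid(values, resolution=resolution),
        absorbance=np.array(absorbances),
        path_length_um=float(meta.get("path_length_um", 76.0)),
        n_sweeps_averaged=int(meta.get("n_sweeps_averaged", 1)),
        label=meta.get("label", path.stem),
        is_artifact=meta.get("is_artifact", "false") == "true",
    )


def write_design(
    samples: Design | Sequence[ConcentrationSample],
    path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    rows = samples.samples if isinstance(samples, Design) else list(samples)
    labels = labels or [f"S{i + 1:03d}" for i in range(len(rows))]
    with open(path, "w") as handle:
        handle.write(",".join(DESIGN_COLUMNS) + "\n")
        for label, sample in zip(labels, rows):
            handle.write(
                f"{label},{_fmt(sample.glucose)},{_fmt(sample.lactate)},"
                f"{_fmt(sample.pyruvate)}\n"
            )


def read_design(path: str | Path) -> tuple[list[str], list[ConcentrationSample]]:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if frame[DESIGN_COLUMNS[1:]].isna().any().any():
        bad = int(frame[DESIGN_COLUMNS[1:]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}:{bad}: missing concentration value")
    samples = [
        ConcentrationSample(
            glucose=float(r.glucose_mM),
            lactate=float(r.lactate_mM),
            pyruvate=float(r.pyruvate_mM),
        )
        for r in frame.itertuples()
    ]
    return [str(s) for s in frame["sample_id"]], samples


def write_manifest(
    path: str | Path,
    labels: Sequence[str],
    samples: Sequence[ConcentrationSample],
    spectra: Sequence[Spectrum],
) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": list(labels),
            **{
                f"{analyte}_mM": [getattr(s, analyte) for s in samples]
                for analyte in ANALYTES
            },
            "is_artifact": [s.is_artifact for s in spectra],
        }
    )
    frame.to_csv(path, index=False)


def write_outlier_report(report: OutlierReport, path: str | Path) -> None:
    pd.DataFrame(
        {
            "spectrum_id": list(report.labels),
            "score": report.scores,
            "flagged": report.flagged,
        }
    ).to_csv(path, index=False)


def write_series(series, directory: str | Path) -> None:
    """Persist a monitoring series: reference.csv plus one CSV per spectrum."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (t, ref, spectrum) in enumerate(
        zip(series.timestamps, series.reference, series.spectra)
    ):
        label = spectrum.label or f"P{i + 1:03d}"
        write_spectrum(spectrum, directory / f"{label}.csv")
        rows.append(
            {
                "sample_id": label,
                "time_h": t,
                "glucose_mM": ref.glucose,
                "lactate_mM": ref.lactate,
                "pyruvate_mM": ref.pyruvate,
                "pooled_from": series.pooled_from,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "reference.csv", index=False)


def read_series(directory: str | Path):
    """Load a monitoring series written by :func:`write_series`."""
    from .synthspec import TimeSeries

    directory = Path(directory)
    reference_path = directory / "reference.csv"
    if not reference_path.exists():
        raise ValueError(f"{directory}: missing reference.csv")
    frame = pd.read_csv(reference_path, float_precision="round_trip")
    required = ["sample_id", "time_h", *(f"{a}_mM" for a in ANALYTES), "pooled_from"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{reference_path}: missing columns {missing}")
    spectra = [read_spectrum(directory / f"{sid}.csv") for sid in frame["sample_id"]]
    references = [
        ConcentrationSample(
            glucose=float(r.glucose_mM),
            lactate=float(r.lactate_mM),
            pyruvate=float(r.pyruvate_mM),
        )
        for r in frame.itertuples()
    ]
    return TimeSeries(
        timestamps=frame["time_h"].to_numpy(float),
        reference=tuple(references),
        pooled_from=int(frame["pooled_from"].iloc[0]),
        spectra=tuple(spectra),
    )


def save_model(
    model: PLSRModel, path: str | Path, provenance: dict | None = None
) -> None:
    payload = model.to_dict()
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> PLSRModel:
    return PLSRModel.from_dict(json.loads(Path(path).read_text()))
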