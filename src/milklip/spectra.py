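"""Data model and IO for MS/MS^ALL experiments and GC peak tables.

An MS/MS^ALL acquisition records one centroided TOF MS/MS spectrum per 1-amu
precursor isolation step across m/z 400-1000 (fragments 150-1000), in each
polarity. The canonical on-disk form is JSON lines, one spectrum per line::

    {"sample": "human1", "step": 877, "polarity": "+", "peaks": [[mz, i], ...]}

with m/z fixed at 4 decimals and intensities at 1 decimal so identical
experiments serialize byte-identically. mzML ingest (via pyteomics) is an
optional convenience; the JSONL fixture format is canonical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .nomenclature import LipidAnnotation, parse_annotation

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentPeak",
    "MsMsSpectrum",
    "Experiment",
    "step_of",
    "isolation_window",
    "read_experiment",
    "write_experiment",
    "read_spike_sheet",
    "write_spike_sheet",
    "read_gc_peaks",
    "write_gc_peaks",
    "FRAGMENT_MZ_RANGE",
    "PRECURSOR_STEP_RANGE",
]

FRAGMENT_MZ_RANGE = (150.0, 1000.0)
PRECURSOR_STEP_RANGE = (400, 1000)


@dataclass(frozen=True)
class FragmentPeak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        lo, hi = FRAGMENT_MZ_RANGE
        if not lo <= self.mz <= hi:
            raise ValueError(f"fragment m/z {self.mz} outside stored range {lo}-{hi}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


@dataclass
class MsMsSpectrum:
    """One centroided fragment spectrum for a unit precursor step."""

    precursor_step: int
    polarity: str
    peaks: list[FragmentPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = PRECURSOR_STEP_RANGE
        if not lo <= self.precursor_step <= hi:
            raise ValueError(f"precursor step {self.precursor_step} outside {lo}-{hi}")
        if self.polarity not in "+-":
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            logger.warning(
                "unsorted peak list in spectrum (%d, %s); sorting on load",
                self.precursor_step,
                self.polarity,
            )
            self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]


@dataclass
class Experiment:
    """A full MS/MS^ALL acquisition of one sample plus its spike sheet."""

    sample: str
    spectra: dict[tuple[int, str], MsMsSpectrum] = field(default_factory=dict)
    spike_sheet: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, spec in self.spectra.items():
            if key != (spec.precursor_step, spec.polarity):
                raise ValueError(f"spectrum key {key} disagrees with spectrum header")
        for name in self.spike_sheet:
            ann = parse_annotation(name)
            if ann.level != "molecular":
                raise ValueError(f"spike sheet species {name!r} is not molecular-level")

    def spectrum(self, step: int, polarity: str) -> MsMsSpectrum | None:
        return self.spectra.get((step, polarity))

    def add(self, spectrum: MsMsSpectrum) -> None:
        key = (spectrum.precursor_step, spectrum.polarity)
        if key in self.spectra:
            raise ValueError(f"duplicate spectrum for (step, polarity) {key}")
        self.spectra[key] = spectrum

    def parsed_spikes(self) -> dict[str, tuple[LipidAnnotation, float]]:
        return {
            name: (parse_annotation(name), pmol)
            for name, pmol in self.spike_sheet.items()
        }


def step_of(mz: float) -> int:
    """Nominal 1-amu precursor step containing m/z; half-up at .5 exactly."""
    lo, hi = PRECURSOR_STEP_RANGE
    if not lo <= mz <= hi:
        raise ValueError(f"precursor m/z {mz} outside acquisition range {lo}-{hi}")
    return min(int(math.floor(mz + 0.5)), hi)


def isolation_window(step: int) -> tuple[float, float]:
    """The [step - 0.5, step + 0.5) isolation window of a unit step."""
    return (step - 0.5, step + 0.5)


# --- fixture (JSON lines) IO --------------------------------------------------


def write_experiment(experiment: Experiment, path: str | Path) -> None:
    """Write JSONL with fixed float formatting; byte-deterministic."""
    path = Path(path)
    lines = []
    for step, pol in sorted(experiment.spectra):
        spec = experiment.spectra[(step, pol)]
        peaks = ", ".join(
            f"[{p.mz:.4f}, {p.intensity:.1f}]" for p in spec.peaks
        )
        lines.append(
            f'{{"sample": {json.dumps(experiment.sample)}, "step": {step}, '
            f'"polarity": "{pol}", "peaks": [{peaks}]}}'
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_experiment(path: str | Path, format: str = "fixture") -> Experiment:
    """Read an experiment from the JSONL fixture format or from mzML."""
    if format == "mzML":
        return _read_mzml(path)
    if format != "fixture":
        raise ValueError(f"unknown experiment format {format!r}")
    path = Path(path)
    experiment: Experiment | None = None
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}:{i}: bad JSON line: {exc}") from exc
        if experiment is None:
            experiment = Experiment(sample=rec["sample"])
        spec = MsMsSpectrum(
            precursor_step=int(rec["step"]),
            polarity=rec["polarity"],
            peaks=[FragmentPeak(float(mz), float(i_)) for mz, i_ in rec["peaks"]],
        )
        experiment.add(spec)
    if experiment is None:
        raise ValueError(f"{path}: empty experiment file (no sample record)")
    return experiment


def _read_mzml(path: str | Path) -> Experiment:
    """Minimal mzML reader for centroided MS2 scans.

    Covers the subset this package needs: ms level, scan polarity, the
    isolation window target m/z, and zlib-or-plain base64 64/32-bit float
    peak arrays. Vendor extensions and chromatograms are ignored.
    """
    import base64
    import struct
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"

    def decode(binary_array: ET.Element) -> list[float]:
        accessions = {
            p.get("accession") for p in binary_array.iter(f"{ns}cvParam")
        }
        text = binary_array.find(f"{ns}binary").text or ""
        raw = base64.b64decode(text)
        if "MS:1000574" in accessions:  # zlib compression
            raw = zlib.decompress(raw)
        fmt = "f" if "MS:1000521" in accessions else "d"  # 32- vs 64-bit
        return list(struct.unpack(f"<{len(raw) // struct.calcsize(fmt)}{fmt}", raw))

    experiment = Experiment(sample=Path(path).stem)
    lo, hi = FRAGMENT_MZ_RANGE
    for spectrum in ET.parse(path).getroot().iter(f"{ns}spectrum"):
        params = {
            p.get("accession"): p.get("value")
            for p in spectrum.iter(f"{ns}cvParam")
        }
        if params.get("MS:1000511") != "2":  # ms level
            continue
        polarity = "+" if "MS:1000130" in params else "-"
        target = float(params["MS:1000827"])  # isolation window target m/z
        arrays = {}
        for ba in spectrum.iter(f"{ns}binaryDataArray"):
            accs = {p.get("accession") for p in ba.iter(f"{ns}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = decode(ba)
            elif "MS:1000515" in accs:
                arrays["intensity"] = decode(ba)
        peaks = [
            FragmentPeak(mz, inten)
            for mz, inten in zip(arrays.get("mz", []), arrays.get("intensity", []))
            if lo <= mz <= hi
        ]
        experiment.add(MsMsSpectrum(step_of(target), polarity, peaks))
    return experiment


# --- spike sheet and GC peak tables (TSV) ------------------------------------


def read_spike_sheet(path: str | Path) -> dict[str, float]:
    """TSV (annotation, pmol); species must parse at molecular level."""
    sheet: dict[str, float] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, pmol = line.split("\t")
            ann = parse_annotation(name)
        except ValueError as exc:
            raise ValueError(f"spike sheet row {i} ({line!r}): {exc}") from exc
        if ann.level != "molecular":
            raise ValueError(f"spike sheet row {i}: {name!r} is not molecular-level")
        sheet[name] = float(pmol)
    return sheet


def write_spike_sheet(sheet: dict[str, float], path: str | Path) -> None:
    lines = ["# annotation\tpmol"]
    lines += [f"{name}\t{pmol:g}" for name, pmol in sheet.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gc_peaks(path: str | Path) -> list[tuple[float, float]]:
    """GC peak table TSV (rt_min, area)."""
    peaks = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rt, area = line.split("\t")
        peaks.append((float(rt), float(area)))
    return peaks


def write_gc_peaks(peaks: list[tuple[float, float]], path: str | Path) -> None:
    lines = ["# rt_min\tarea"]
    lines += [f"{rt:.3f}\t{area:.4f}" for rt, area in peaks]
    Path(path).write_text("\n".join(lines) + "\n")
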