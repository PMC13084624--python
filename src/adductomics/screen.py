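"""Diagnostic-fragment-ion screening of MS2 spectra.

Sulfur-mustard adducts shed small reporter cations from the alkyl side
chain (HETE 105.04, the HETET chain fragment 137.01, HETETE 165.04 m/z).
Scanning the low-mass region of every MS2 spectrum for these reporters
within a ppm tolerance flags adduct-bearing precursors without any
sequence database -- this module automates that evaluation, plus the
precursor-level match against candidate modified peptides and a synthetic
spectrum generator used as the screening test bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import PROTON_MASS, Modification, diagnostic_ion_mz
from .digest import ModifiedPeptide

__all__ = [
    "Spectrum",
    "ScreenConfig",
    "DiagnosticHit",
    "ppm_error",
    "screen_spectrum",
    "screen_spectra",
    "match_precursor",
    "generate_spectrum",
    "read_mgf",
    "write_mgf",
    "write_hits_tsv",
]


@dataclass
class Spectrum:
    """One MS2 spectrum: precursor plus a sorted (m/z, intensity) peak list.

    Ion mobility is carried as metadata only; it plays no role in scoring.
    """

    id: str
    precursor_mz: float
    precursor_charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    ion_mobility: float | None = None
    annotations: tuple = ()  # optional ground-truth labels, parallel to peaks

    def __post_init__(self):
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        if self.peaks_mz.shape != self.peaks_intensity.shape:
            raise ValueError("peak m/z and intensity arrays differ in length")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if np.any(self.peaks_intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]
        if self.annotations:
            ann = list(self.annotations)
            self.annotations = tuple(ann[i] for i in order)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.peaks_intensity.max()) if self.peaks_mz.size else 0.0


@dataclass(frozen=True)
class ScreenConfig:
    """Tolerances of the manual diagnostic-ion evaluation, automated.

    20 ppm on both MS levels mirrors the manual screen; the search-engine
    style settings (15 ppm precursor / 0.05 Da fragment) are available by
    overriding ``tol_ms1_ppm`` and using ``fragment_tol_da``.
    """

    tol_ms1_ppm: float = 20.0
    tol_ms2_ppm: float = 20.0
    min_diagnostic_intensity_fraction: float = 0.01
    fragment_tol_da: float | None = None  # absolute-Da alternative for b/y work

    def __post_init__(self):
        if self.tol_ms1_ppm <= 0 or self.tol_ms2_ppm <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class DiagnosticHit:
    spectrum_id: str
    modification: str
    matched_mz: float
    theoretical_mz: float
    ppm: float
    intensity: float
    candidate: ModifiedPeptide | None = None


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return (observed - theoretical) / theoretical * 1e6


def screen_spectrum(
    spectrum: Spectrum,
    mods: Sequence[Modification],
    cfg: ScreenConfig | None = None,
) -> list[DiagnosticHit]:
    """Flag reporter ions of ``mods`` present in one spectrum.

    For each modification with a diagnostic ion, the peak with smallest
    absolute ppm error within ``tol_ms2_ppm`` and above the relative
    intensity floor yields one hit.  Order of input peaks is irrelevant
    (peaks are kept sorted).
    """
    cfg = cfg or ScreenConfig()
    hits: list[DiagnosticHit] = []
    if spectrum.peaks_mz.size == 0:
        return hits
    floor = cfg.min_diagnostic_intensity_fraction * spectrum.base_peak_intensity
    for mod in mods:
        if mod.diagnostic_ion is None:
            continue
        theo = diagnostic_ion_mz(mod)
        ppm = (spectrum.peaks_mz - theo) / theo * 1e6
        ok = (np.abs(ppm) <= cfg.tol_ms2_ppm) & (spectrum.peaks_intensity >= floor)
        if not np.any(ok):
            continue
        idx = np.flatnonzero(ok)
        best = idx[np.argmin(np.abs(ppm[idx]))]
        hits.append(
            DiagnosticHit(
                spectrum_id=spectrum.id,
                modification=mod.name,
                matched_mz=float(spectrum.peaks_mz[best]),
                theoretical_mz=theo,
                ppm=float(ppm[best]),
                intensity=float(spectrum.peaks_intensity[best]),
            )
        )
    return hits


def screen_spectra(
    spectra: Iterable[Spectrum],
    mods: Sequence[Modification],
    cfg: ScreenConfig | None = None,
) -> list[DiagnosticHit]:
    out: list[DiagnosticHit] = []
    for s in spectra:
        out.extend(screen_spectrum(s, mods, cfg))
    return out


def match_precursor(
    spectrum: Spectrum,
    candidates: Sequence[ModifiedPeptide],
    tol_ms1_ppm: float = 20.0,
) -> list[tuple[ModifiedPeptide, float]]:
    """Candidates whose protonated mass matches the precursor within tolerance.

    Returns (candidate, ppm error) pairs sorted by absolute ppm.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    z = spectrum.precursor_charge
    matched = []
    for cand in candidates:
        theo = (cand.mass() + z * PROTON_MASS) / z
        ppm = ppm_error(spectrum.precursor_mz, theo)
        if abs(ppm) <= tol_ms1_ppm:
            matched.append((cand, ppm))
    matched.sort(key=lambda t: abs(t[1]))
    return matched


def generate_spectrum(
    pep: ModifiedPeptide,
    seed: int,
    spectrum_id: str | None = None,
    charge: int = 2,
    jitter_ppm: float = 5.0,
    mz_offset_ppm: float = 0.0,
    n_noise_peaks: int = 30,
    noise_intensity_fraction: float = 0.05,
    ion_mobility: float | None = None,
) -> Spectrum:
    """Simulate an MS2 spectrum of a modified peptide.

    Singly charged b/y ions at every index, one reporter cation per
    attached modification, Gaussian m/z jitter of ``jitter_ppm`` sigma (plus
    an optional systematic ``mz_offset_ppm``), and uniform decoy peaks below
    the precursor.  Deterministic for a fixed seed; ground-truth labels for
    every peak are kept in ``annotations``.
    """
    rng = np.random.default_rng(seed)
    n = len(pep.sequence)
    mzs: list[float] = []
    intens: list[float] = []
    labels: list[str] = []
    for i in range(1, n):
        mzs.append(pep.fragment_mz("b", i, 1))
        labels.append(f"b{i}")
        mzs.append(pep.fragment_mz("y", i, 1))
        labels.append(f"y{i}")
    intens.extend(rng.uniform(0.2, 1.0, size=len(mzs)))
    seen_mods = []
    for _, mod in pep.assignments:
        if mod.diagnostic_ion is not None and mod.name not in seen_mods:
            mzs.append(diagnostic_ion_mz(mod))
            intens.append(float(rng.uniform(0.3, 0.8)))
            labels.append(f"diag:{mod.name}")
            seen_mods.append(mod.name)
    mzs_arr = np.array(mzs, dtype=float)
    shift = 1.0 + mz_offset_ppm * 1e-6
    if jitter_ppm > 0:
        shift = shift * (1.0 + rng.normal(0.0, jitter_ppm * 1e-6, size=mzs_arr.size))
    mzs_arr = mzs_arr * shift
    prec = pep.precursor_mz(charge)
    noise_mz = rng.uniform(50.0, max(prec, 200.0), size=n_noise_peaks)
    noise_int = rng.uniform(0.0, noise_intensity_fraction, size=n_noise_peaks)
    return Spectrum(
        id=spectrum_id or f"sim:{pep.sequence}:{pep.modification_string() or 'bare'}",
        precursor_mz=prec,
        precursor_charge=charge,
        peaks_mz=np.concatenate([mzs_arr, noise_mz]),
        peaks_intensity=np.concatenate([np.array(intens), noise_int]),
        ion_mobility=ion_mobility,
        annotations=tuple(labels) + ("noise",) * n_noise_peaks,
    )


def read_mgf(path) -> list[Spectrum]:
    """Read spectra from an MGF peak list."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            charge = int(params.get("charge", [1])[0])
            spectra.append(
                Spectrum(
                    id=str(params.get("title", f"spectrum_{i}")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks_mz=entry["m/z array"],
                    peaks_intensity=entry["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks_mz,
                "intensity array": s.peaks_intensity,
                "params": {
                    "title": s.id,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.precursor_charge}+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_hits_tsv(hits: Iterable[DiagnosticHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "spectrum_id\tmodification\tmatched_mz\ttheoretical_mz\tppm\tintensity\n"
        )
        for h in hits:
            fh.write(
                f"{h.spectrum_id}\t{h.modification}\t{h.matched_mz:.5f}\t"
                f"{h.theoretical_mz:.5f}\t{h.ppm:.3f}\t{h.intensity:.4g}\n"
            )
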