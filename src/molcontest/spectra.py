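"""MS/MS peak-list I/O, ppm-tolerant cosine similarity, library search and
the spectral-similarity training/challenge split.

Peak lists travel as two-column plain text or Mascot Generic Format (MGF).
Similarity is the normalized dot product over peak pairs matched within a
relative (ppm) m/z tolerance, the standard for high-resolution MS/MS. The
library-search baseline filters a reference library to spectra whose
precursor lies within a ppm window of the query's and ranks the survivors by
cosine similarity. The dataset split sends a spectrum to the training set
iff its best library similarity is strictly above a threshold (default
0.85), with an explicit exception list forcing named spectra into the
challenge set regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from pyteomics import mgf as pyteomics_mgf

logger = logging.getLogger("molcontest")

__all__ = [
    "Spectrum",
    "read_peaklist",
    "write_peaklist",
    "read_mgf",
    "write_mgf",
    "cosine_similarity",
    "LibraryHit",
    "library_search",
    "split_train_challenge",
    "dedupe_spectra",
    "quality_filter",
]


@dataclass
class Spectrum:
    """One MS/MS spectrum: peaks plus precursor annotation.

    Peaks are stored sorted ascending by m/z; unsorted input is sorted with a
    log notice. At least one peak with a positive intensity is required.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    ion_mode: Optional[str] = None
    spectrum_id: str = ""
    structure_key: Optional[str] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.spectrum_id!r} has no peaks")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(self.intensity < 0) or not np.any(self.intensity > 0):
            raise ValueError("intensities must be >= 0 and not all zero")
        if np.any(np.diff(self.mz) < 0):
            logger.info("spectrum %s: peaks unsorted, sorting by m/z", self.spectrum_id)
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def peak_signature(self) -> tuple:
        """Hashable exact identity of the peak list (for duplicate removal)."""
        return (tuple(self.mz.tolist()), tuple(self.intensity.tolist()))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peaklist(path, fmt: str = "plain", **meta) -> Spectrum:
    """Read one spectrum from a two-column plain-text file or a one-block MGF.

    Plain format: one ``m/z intensity`` pair per line (whitespace separated,
    ``#`` comments and blank lines ignored). Extra keyword arguments populate
    the Spectrum's metadata fields.
    """
    path = Path(path)
    if fmt == "plain":
        mzs: list[float] = []
        intensities: list[float] = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path.name}: malformed peak line {line!r}")
            mzs.append(float(fields[0]))
            intensities.append(float(fields[1]))
        if not mzs:
            raise ValueError(f"{path.name}: no peaks")
        return Spectrum(np.array(mzs), np.array(intensities),
                        spectrum_id=meta.pop("spectrum_id", path.stem), **meta)
    if fmt == "mgf":
        spectra = read_mgf(path)
        if not spectra:
            raise ValueError(f"{path.name}: no MGF spectra")
        return spectra[0]
    raise ValueError(f"unknown peak-list format: {fmt!r}")


def write_peaklist(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column plain text."""
    lines = [f"{mz!r} {inten!r}" for mz, inten in spectrum.peaks]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_MODE_CHARGE = {"positive": "1+", "negative": "1-"}


def read_mgf(path) -> list[Spectrum]:
    """Read all BEGIN IONS/END IONS blocks of an MGF file."""
    spectra: list[Spectrum] = []
    with pyteomics_mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block["params"]
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            charge = params.get("charge")
            ion_mode = None
            if charge:
                ion_mode = "negative" if int(charge[0]) < 0 else "positive"
            spectra.append(Spectrum(
                mz=np.asarray(block["m/z array"], dtype=float),
                intensity=np.asarray(block["intensity array"], dtype=float),
                precursor_mz=precursor,
                ion_mode=ion_mode,
                spectrum_id=str(params.get("title", "")),
            ))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as MGF (TITLE, PEPMASS, CHARGE per block)."""
    blocks = []
    for s in spectra:
        params = {"title": s.spectrum_id}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.ion_mode in _MODE_CHARGE:
            params["charge"] = _MODE_CHARGE[s.ion_mode]
        blocks.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": params,
        })
    pyteomics_mgf.write(blocks, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def _scaled(intensity: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "sqrt":
        return np.sqrt(intensity)
    if scaling == "raw":
        return intensity.copy()
    raise ValueError(f"unknown intensity scaling: {scaling!r}")


def cosine_similarity(a: Spectrum, b: Spectrum, tol_ppm: float = 10.0,
                      *, scaling: str = "sqrt") -> float:
    """ppm-tolerant cosine similarity (normalized dot product) in [0, 1].

    Peak pairs whose m/z differ by at most ``tol_ppm`` parts per million
    (relative to the larger of the two m/z) are candidate matches; pairs are
    accepted greedily by descending intensity product, each peak matched at
    most once. The score is the dot product over matched pairs divided by
    the product of the full intensity-vector norms, so it is 1 exactly when
    the spectra are identical and 0 when no pair lies within tolerance.
    Intensities are square-root scaled by default (``scaling="raw"``
    disables this).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    ia = _scaled(a.intensity, scaling)
    ib = _scaled(b.intensity, scaling)
    # pairwise tolerance test, vectorized
    diff = np.abs(a.mz[:, None] - b.mz[None, :])
    limit = np.maximum(a.mz[:, None], b.mz[None, :]) * tol_ppm * 1e-6
    ii, jj = np.nonzero(diff <= limit)
    if ii.size == 0:
        return 0.0
    products = ia[ii] * ib[jj]
    order = np.argsort(-products, kind="stable")
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    total = 0.0
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        total += products[k]
    denom = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    return min(1.0, total / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Library search
# ---------------------------------------------------------------------------

class LibraryHit(NamedTuple):
    structure_key: Optional[str]
    spectrum_id: str
    similarity: float


def library_search(
    query: Spectrum,
    library: Sequence[Spectrum],
    *,
    precursor_tol_ppm: float = 10.0,
    fragment_tol_ppm: float = 10.0,
    scaling: str = "sqrt",
) -> list[LibraryHit]:
    """Spectral-library search: precursor window filter, then cosine ranking.

    Library spectra whose precursor m/z lies within ``precursor_tol_ppm`` of
    the query's (and whose ion mode matches, when both are annotated) are
    ranked by cosine similarity, best first. Every survivor is returned even
    at low similarity — a single surviving candidate is a hit regardless of
    its score. Returns an empty list when no precursor falls in the window.
    """
    if query.precursor_mz is None:
        raise ValueError("query spectrum has no precursor m/z")
    window = query.precursor_mz * precursor_tol_ppm * 1e-6
    hits = []
    for ref in library:
        if ref.precursor_mz is None:
            continue
        if abs(ref.precursor_mz - query.precursor_mz) > window:
            continue
        if (query.ion_mode and ref.ion_mode and query.ion_mode != ref.ion_mode):
            continue
        sim = cosine_similarity(query, ref, fragment_tol_ppm, scaling=scaling)
        hits.append(LibraryHit(ref.structure_key, ref.spectrum_id, sim))
    hits.sort(key=lambda h: (-h.similarity, h.spectrum_id))
    return hits


# ---------------------------------------------------------------------------
# Training / challenge split
# ---------------------------------------------------------------------------

def split_train_challenge(
    spectra: Sequence[Spectrum],
    reference_library: Sequence[Spectrum],
    *,
    threshold: float = 0.85,
    exceptions: Iterable[str] = (),
    tol_ppm: float = 10.0,
    similarity: Optional[Callable[[Spectrum, Spectrum], float]] = None,
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Partition spectra into (training, challenge) sets by library similarity.

    A spectrum goes to *training* iff its maximum similarity against the
    reference library is strictly above *threshold* (default 0.85) — a
    spectrum at exactly the threshold is a challenge. Spectrum ids listed in
    *exceptions* are forced into the challenge set even above threshold
    (e.g. to keep enough natural products among the challenges). The
    partition is total and disjoint. *similarity* defaults to the module's
    ppm-tolerant cosine at *tol_ppm*.
    """
    if similarity is None:
        similarity = lambda a, b: cosine_similarity(a, b, tol_ppm)
    forced = set(exceptions)
    training: list[Spectrum] = []
    challenge: list[Spectrum] = []
    for spec in spectra:
        best = max((similarity(spec, ref) for ref in reference_library), default=0.0)
        if best > threshold and spec.spectrum_id not in forced:
            training.append(spec)
        else:
            challenge.append(spec)
    return training, challenge


# ---------------------------------------------------------------------------
# Deduplication and quality filtering
# ---------------------------------------------------------------------------

def dedupe_spectra(
    spectra: Sequence[Spectrum],
    substance_of: Optional[Mapping[str, str]] = None,
) -> list[Spectrum]:
    """Remove duplicate spectra, keeping order of first appearance.

    Two passes: (1) spectra with byte-identical peak lists are included only
    once; (2) when *substance_of* maps spectrum ids to substance names,
    repeated measurements of one substance in one ion mode collapse to the
    spectrum with the highest maximum intensity.
    """
    seen: set[tuple] = set()
    unique: list[Spectrum] = []
    for spec in spectra:
        sig = spec.peak_signature()
        if sig in seen:
            continue
        seen.add(sig)
        unique.append(spec)
    if substance_of is None:
        return unique
    best_by_group: dict[tuple, Spectrum] = {}
    order: list[tuple] = []
    for spec in unique:
        substance = substance_of.get(spec.spectrum_id, spec.spectrum_id)
        group = (substance, spec.ion_mode)
        if group not in best_by_group:
            best_by_group[group] = spec
            order.append(group)
        elif float(spec.intensity.max()) > float(best_by_group[group].intensity.max()):
            best_by_group[group] = spec
    return [best_by_group[g] for g in order]


def quality_filter(
    spectra: Sequence[Spectrum],
    *,
    min_peaks: int = 2,
    min_max_intensity: float = 1e5,
) -> list[Spectrum]:
    """Drop low-quality spectra: fewer than *min_peaks* peaks (default:
    single-peak spectra) or maximum intensity below *min_max_intensity*
    (default 1e5 counts)."""
    kept = [
        s for s in spectra
        if s.n_peaks >= min_peaks and float(s.intensity.max()) >= min_max_intensity
    ]
    if len(kept) < len(spectra):
        logger.info("quality_filter: removed %d of %d spectra",
                    len(spectra) - len(kept), len(spectra))
    return kept
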