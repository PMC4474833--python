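"""Dual-isotope (14N/15N) peptide chemistry and MS1 quantification.

Metabolic labeling with heavy nitrogen shifts every peptide by roughly one
Dalton per nitrogen atom, so identification and quantification need a peptide
database that carries *both* isotopic forms of every tryptic peptide.  This
module provides the in-silico layer of that workflow:

* tryptic digestion with missed cleavages,
* elemental composition and monoisotopic mass under either nitrogen label,
* isotope-envelope prediction by convolving per-element isotopologue
  distributions (with a tunable heavy-nitrogen incorporation level),
* a mass-sorted dual-label peptide index with ppm-window candidate lookup,
* MS1 area-ratio quantification R = area(14N) / area(15N) over a
  retention window.

Fragment-ion scoring and decoy-FDR filtering are out of scope: the pipeline
accepts an identification table and quantifies precursors at the MS1 level.
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _ptmass

__all__ = [
    "PeptideRecord",
    "IsotopeEnvelope",
    "MS1ScanSet",
    "PeptideIndex",
    "RatioResult",
    "digest",
    "composition_and_mass",
    "isotope_envelope",
    "build_dual_db",
    "candidate_lookup",
    "quantify_ratio",
    "PROTON_MASS",
    "N15_MASS_SHIFT",
]

PROTON_MASS = _ptmass.nist_mass["H+"][0][0]  # 1.00727646677 Da
#: monoisotopic mass difference 15N - 14N
N15_MASS_SHIFT = _ptmass.nist_mass["N"][15][0] - _ptmass.nist_mass["N"][14][0]

_WATER = {"H": 2, "O": 1}
#: carbamidomethylation of cysteine (iodoacetamide), fixed modification
_CAM_DELTA = {"C": 2, "H": 3, "N": 1, "O": 1}
#: oxidation of methionine, variable modification
_OX_DELTA = {"O": 1}

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# residue compositions restricted to the 20 canonical amino acids
_RESIDUE_COMP: dict[str, dict[str, int]] = {
    aa: {el: n for el, n in _ptmass.std_aa_comp[aa].items()} for aa in _AA20
}

# element -> list of (mass, abundance) for naturally occurring isotopes
_NATURAL_ISOTOPES: dict[str, list[tuple[float, float]]] = {}
for _el in ("C", "H", "N", "O", "S"):
    _iso = [
        (m, ab)
        for num, (m, ab) in _ptmass.nist_mass[_el].items()
        if num != 0 and ab > 0.0
    ]
    _NATURAL_ISOTOPES[_el] = sorted(_iso)


@dataclass(frozen=True)
class PeptideRecord:
    """One labeled peptide form in the theoretical database."""

    sequence: str
    protein_id: str
    missed_cleavages: int
    label: str  # "N14" | "N15"
    oxidized_positions: tuple[int, ...] = ()
    charge: int = 1
    composition: Mapping[str, int] = field(default_factory=dict)
    monoisotopic_mass: float = 0.0

    def mz(self, charge: int | None = None) -> float:
        z = self.charge if charge is None else charge
        if z < 1:
            raise ValueError(f"charge must be >= 1, got {z}")
        return (self.monoisotopic_mass + z * PROTON_MASS) / z


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Centroided isotopologue distribution of one peptide ion."""

    charge: int
    mz: np.ndarray  # strictly increasing, Th
    intensity: np.ndarray  # relative, sums to <= 1 after truncation

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("envelope m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("envelope intensities must be non-negative")

    @property
    def monoisotopic_mz(self) -> float:
        return float(self.mz[0])


@dataclass
class MS1ScanSet:
    """Centroided MS1 scans: list of (retention_index, peaks).

    ``peaks`` is a (n, 2) float array of (m/z, intensity).
    """

    scans: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        for _, peaks in self.scans:
            if peaks.size and np.any(peaks[:, 1] < 0):
                raise ValueError("scan intensities must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "MS1ScanSet":
        """Read the internal TSV format: scan_index <tab> mz <tab> intensity."""
        import pandas as pd

        df = pd.read_csv(
            path, sep="\t", names=["scan_index", "mz", "intensity"], comment="#"
        )
        scans = []
        for idx, grp in df.groupby("scan_index", sort=True):
            scans.append((float(idx), grp[["mz", "intensity"]].to_numpy(float)))
        return cls(scans=scans)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for idx, peaks in self.scans:
                for mz, inten in peaks:
                    fh.write(f"{idx:g}\t{mz:.6f}\t{inten:.6g}\n")

    @classmethod
    def from_mzml(cls, path) -> "MS1ScanSet":
        """Read MS1 spectra from an mzML file (same contract as the TSV)."""
        from pyteomics import mzml as _mzml

        scans = []
        with _mzml.MzML(str(path)) as reader:
            for i, spec in enumerate(reader):
                if spec.get("ms level", 1) != 1:
                    continue
                peaks = np.column_stack(
                    [spec["m/z array"], spec["intensity array"]]
                ).astype(float)
                scans.append((float(i), peaks))
        return cls(scans=scans)


def digest(
    protein_sequence: str,
    max_missed: int = 2,
    min_length: int = 1,
    proline_rule: bool = True,
) -> list[tuple[str, int]]:
    """Fully tryptic in-silico digestion.

    Cleaves C-terminal to K/R; with ``proline_rule`` (default) cleavage is
    suppressed when the next residue is proline.  Returns the deduplicated
    list of ``(peptide, missed_cleavages)`` for 0..max_missed missed
    cleavages, in order of appearance.

    Raises ``ValueError`` for residues outside the 20-letter alphabet,
    naming the offending position.
    """
    seq = protein_sequence.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    for pos, aa in enumerate(seq):
        if aa not in _AA20:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")

    # cleavage points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(len(seq) - 1):
        if seq[i] in "KR" and not (proline_rule and seq[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(seq))

    out: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for a in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            pep = seq[cuts[a] : cuts[b]]
            if len(pep) < min_length:
                continue
            key = (pep, missed)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def composition_and_mass(
    sequence: str,
    oxidized_positions: Iterable[int] = (),
    label: str = "N14",
    carbamidomethyl: bool = True,
) -> tuple[dict[str, int], float]:
    """Elemental composition and monoisotopic mass of a peptide.

    Sums residue compositions plus one water, applies carbamidomethyl-C as a
    fixed modification and oxidation at the given 0-based methionine
    positions.  Under the ``"N15"`` label every nitrogen atom is counted at
    the heavy-nitrogen monoisotopic mass, so

    ``mass(N15) - mass(N14) == n_N * N15_MASS_SHIFT``

    holds exactly for any composition.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    if label not in ("N14", "N15"):
        raise ValueError(f"label must be 'N14' or 'N15', got {label!r}")

    comp: Counter[str] = Counter(_WATER)
    for pos, aa in enumerate(seq):
        if aa not in _RESIDUE_COMP:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
        comp.update(_RESIDUE_COMP[aa])
        if carbamidomethyl and aa == "C":
            comp.update(_CAM_DELTA)
    for pos in oxidized_positions:
        if pos < 0 or pos >= len(seq) or seq[pos] != "M":
            raise ValueError(f"oxidation requires M at position {pos}")
        comp.update(_OX_DELTA)

    n_mass = (
        _ptmass.nist_mass["N"][15][0]
        if label == "N15"
        else _ptmass.nist_mass["N"][14][0]
    )
    monomass = 0.0
    for el, n in comp.items():
        if el == "N":
            monomass += n * n_mass
        else:
            monomass += n * _ptmass.nist_mass[el][0][0]
    return dict(comp), monomass


def _convolve_moments(
    p1: np.ndarray, m1: np.ndarray, p2: np.ndarray, m2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two (probability, first-moment) distributions on the
    integer mass-number grid; the first moment tracks centroid masses."""
    p = np.convolve(p1, p2)
    m = np.convolve(m1, p2) + np.convolve(p1, m2)
    return p, m


def _element_distribution(
    isotopes: Sequence[tuple[float, float]], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated isotopologue distribution of n atoms of one element,
    by binary exponentiation of the single-atom distribution."""
    base_mass = isotopes[0][0]
    offsets = [int(round(m - base_mass)) for m, _ in isotopes]
    size = max(offsets) + 1
    p1 = np.zeros(size)
    m1 = np.zeros(size)
    for (mass_i, ab), off in zip(isotopes, offsets):
        p1[off] += ab
        m1[off] += ab * mass_i
    # renormalize in case the table abundances do not sum exactly to 1
    tot = p1.sum()
    p1 /= tot
    m1 /= tot

    acc_p, acc_m = np.array([1.0]), np.array([0.0])
    while n:
        if n & 1:
            acc_p, acc_m = _convolve_moments(acc_p, acc_m, p1, m1)
        n >>= 1
        if n:
            p1, m1 = _convolve_moments(p1, m1, p1, m1)
    return acc_p, acc_m


def isotope_envelope(
    composition: Mapping[str, int],
    label: str = "N14",
    charge: int = 1,
    n15_incorporation: float = 0.99,
    intensity_floor: float = 1e-3,
) -> IsotopeEnvelope:
    """Predict the centroided isotope envelope of a peptide ion.

    Per-element isotopologue distributions are convolved on the integer
    mass-number grid while tracking exact centroid masses.  Nitrogen uses
    its natural distribution under ``"N14"`` and an incorporation-weighted
    {14N: 1-q, 15N: q} two-point distribution under ``"N15"``.  Peaks below
    ``intensity_floor`` (relative to the summed distribution, which is 1
    before truncation) are dropped; pass ``intensity_floor=0`` to keep the
    full distribution.
    """
    if not composition or sum(composition.values()) == 0:
        raise ValueError("empty composition")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if not (0.0 < n15_incorporation <= 1.0):
        raise ValueError("n15_incorporation must be in (0, 1]")
    if label not in ("N14", "N15"):
        raise ValueError(f"label must be 'N14' or 'N15', got {label!r}")

    p = np.array([1.0])
    m = np.array([0.0])
    for el, n in composition.items():
        if n == 0:
            continue
        if n < 0:
            raise ValueError(f"negative count for element {el}")
        if el == "N" and label == "N15":
            q = n15_incorporation
            iso = [
                (_ptmass.nist_mass["N"][14][0], 1.0 - q),
                (_ptmass.nist_mass["N"][15][0], q),
            ]
            iso = [(mi, ab) for mi, ab in iso if ab > 0.0]
        else:
            if el not in _NATURAL_ISOTOPES:
                raise ValueError(f"unsupported element {el!r}")
            iso = _NATURAL_ISOTOPES[el]
        pe, me = _element_distribution(iso, n)
        p, m = _convolve_moments(p, m, pe, me)

    # bins with vanishing probability carry no usable centroid (0/0); the
    # 1e-12 relative floor removes them while preserving the total to <1e-9
    keep = p > 1e-12 * p.max()
    if intensity_floor > 0:
        keep &= p >= intensity_floor
    masses = np.where(keep, m / np.where(keep, p, 1.0), 0.0)
    p = p[keep]
    masses = masses[keep]
    mz = (masses + charge * PROTON_MASS) / charge
    return IsotopeEnvelope(charge=charge, mz=mz, intensity=p)


class PeptideIndex:
    """Mass-sorted dual-label peptide index supporting ppm range queries."""

    def __init__(self, records: Sequence[PeptideRecord]):
        if not records:
            raise ValueError("empty peptide index")
        self._records = sorted(records, key=lambda r: r.monoisotopic_mass)
        self._masses = [r.monoisotopic_mass for r in self._records]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def query_mass(self, neutral_mass: float, tol_ppm: float) -> list[PeptideRecord]:
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        # |observed - theoretical| <= tol_ppm * theoretical * 1e-6
        lo = neutral_mass / (1.0 + tol_ppm * 1e-6)
        hi = neutral_mass / (1.0 - tol_ppm * 1e-6)
        i = bisect_left(self._masses, lo)
        j = bisect_right(self._masses, hi)
        return [
            r
            for r in self._records[i:j]
            if abs(neutral_mass - r.monoisotopic_mass)
            <= tol_ppm * r.monoisotopic_mass * 1e-6
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "sequence\tprotein_id\tmissed_cleavages\tlabel\t"
                "oxidized_positions\tmonoisotopic_mass\n"
            )
            for r in self._records:
                ox = ",".join(map(str, r.oxidized_positions))
                fh.write(
                    f"{r.sequence}\t{r.protein_id}\t{r.missed_cleavages}\t"
                    f"{r.label}\t{ox}\t{r.monoisotopic_mass:.6f}\n"
                )


def _oxidation_variants(sequence: str, max_ox: int) -> list[tuple[int, ...]]:
    met = [i for i, aa in enumerate(sequence) if aa == "M"]
    variants: list[tuple[int, ...]] = [()]
    for k in range(1, min(max_ox, len(met)) + 1):
        variants.extend(itertools.combinations(met, k))
    return variants


def build_dual_db(
    proteins: Mapping[str, str],
    max_missed: int = 2,
    min_length: int = 5,
    max_oxidations: int = 2,
    proline_rule: bool = True,
) -> PeptideIndex:
    """Build the theoretical dual-label peptide database.

    Every tryptic peptide (up to ``max_missed`` missed cleavages) of every
    protein is expanded over oxidized-methionine variants and both nitrogen
    labels, then indexed by monoisotopic mass.  ``proteins`` maps protein id
    to sequence (see :func:`turnover15n.io.read_fasta`).
    """
    if not proteins:
        raise ValueError("empty proteome")
    records: list[PeptideRecord] = []
    for pid, seq in proteins.items():
        for pep, missed in digest(
            seq, max_missed=max_missed, min_length=min_length, proline_rule=proline_rule
        ):
            for ox in _oxidation_variants(pep, max_oxidations):
                for label in ("N14", "N15"):
                    comp, monomass = composition_and_mass(pep, ox, label)
                    records.append(
                        PeptideRecord(
                            sequence=pep,
                            protein_id=pid,
                            missed_cleavages=missed,
                            label=label,
                            oxidized_positions=ox,
                            composition=comp,
                            monoisotopic_mass=monomass,
                        )
                    )
    return PeptideIndex(records)


def candidate_lookup(
    index: PeptideIndex, precursor_mz: float, charge: int, tol_ppm: float = 10.0
) -> list[PeptideRecord]:
    """Candidate peptides for an observed precursor, both labels eligible.

    The observed neutral mass is ``precursor_mz * z - z * proton`` and the
    window is ±``tol_ppm`` relative to each record's theoretical mass.
    """
    if charge <= 0:
        raise ValueError(f"charge must be positive, got {charge}")
    neutral = precursor_mz * charge - charge * PROTON_MASS
    return index.query_mass(neutral, tol_ppm)


@dataclass(frozen=True)
class RatioResult:
    """Outcome of MS1 ratio quantification; ``ratio`` is None when missing."""

    ratio: float | None
    area_n14: float
    area_n15: float
    n_scans: int
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return self.ratio is None


def _envelope_area(
    scans: list[tuple[float, np.ndarray]],
    envelope: IsotopeEnvelope,
    mz_tol_ppm: float,
    mode: str,
) -> float:
    per_scan = np.zeros(len(scans))
    for s, (_, peaks) in enumerate(scans):
        if peaks.size == 0:
            continue
        total = 0.0
        for mz in envelope.mz:
            tol = mz * mz_tol_ppm * 1e-6
            lo = np.searchsorted(peaks[:, 0], mz - tol, side="left")
            hi = np.searchsorted(peaks[:, 0], mz + tol, side="right")
            if hi > lo:
                total += float(peaks[lo:hi, 1].sum())
        per_scan[s] = total
    if mode == "sum":
        return float(per_scan.sum())
    if mode == "apex":
        return float(per_scan.max(initial=0.0))
    raise ValueError(f"unknown integration mode {mode!r}")


def quantify_ratio(
    scan_set: MS1ScanSet,
    envelope_n14: IsotopeEnvelope,
    envelope_n15: IsotopeEnvelope,
    mz_tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
    denominator_floor: float = 1e-9,
    integration: str = "sum",
) -> RatioResult:
    """14N/15N MS1 area ratio of a peptide pair over a retention window.

    Matched envelope-peak intensities (±``mz_tol_ppm`` per peak) are
    integrated across the scans inside ``rt_window`` for each label;
    ``R = area(N14) / area(N15)``.  A heavy-label area at or below
    ``denominator_floor`` yields a missing result rather than an exception.
    ``integration`` selects summed area (default) or per-scan apex.
    """
    if rt_window is not None and rt_window[0] > rt_window[1]:
        raise ValueError("invalid retention window")
    scans = [
        (rt, peaks[np.argsort(peaks[:, 0])] if peaks.size else peaks)
        for rt, peaks in scan_set.scans
        if rt_window is None or (rt_window[0] <= rt <= rt_window[1])
    ]
    if not scans:
        return RatioResult(None, 0.0, 0.0, 0, reason="no scans in window")

    a14 = _envelope_area(scans, envelope_n14, mz_tol_ppm, integration)
    a15 = _envelope_area(scans, envelope_n15, mz_tol_ppm, integration)
    if a15 <= denominator_floor:
        return RatioResult(
            None, a14, a15, len(scans), reason="denominator below floor"
        )
    return RatioResult(a14 / a15, a14, a15, len(scans))
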