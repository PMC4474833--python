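"""Synthetic-data generators with the statistical structure the pipeline
assumes, so every analysis module is testable without the study's raw data.

Each generator returns its ground truth alongside the synthetic observations
(truth tables are emitted beside FASTQ/TSV outputs), and every generator is
seeded: identical spec + seed gives byte-identical output.

What is emulated
----------------
* ``simulate_turnover``: steady-state 14N decay after a medium switch —
  R(t) = 1 / (exp(k_syn (t - t0)) - 1) — with multiplicative log-normal
  measurement noise on R and protein-specific k_syn drawn log-normally.
* ``simulate_ms1``: centroided MS1 scans containing the light and heavy
  isotope envelopes of peptide pairs at a prescribed area ratio, under a
  chromatographic elution profile plus intensity noise.
* ``simulate_trna_reads``: 3'-anchored tRNA reads (reverse transcription
  primes from the polyadenylated 3'-CCA) with 3' truncations, per-base
  substitution errors, elevated misreads at modified positions, per-species
  fold decreases under stress, and spike-in reads.
* ``simulate_growth``: exponential OD curves with an optional transient
  growth-arrest window.
* ``simulate_ct_table``: qPCR CT tables via CT = CT0 - log2(quantity).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isotopes import MS1ScanSet, PeptideRecord, isotope_envelope
from .kinetics import RatioSeries
from .trnaseq import TRNARef

__all__ = [
    "TurnoverSimSpec",
    "TrnaSimSpec",
    "SPIKE_IN_SEQUENCE",
    "simulate_turnover",
    "simulate_ms1",
    "make_trna_refs",
    "simulate_trna_reads",
    "simulate_growth",
    "simulate_ct_table",
]

#: DNA form of the in-vitro transcribed spike-in RNA (T7 transcript ending
#: in a 3'-CCA like a tRNA; >= 3 nt from every cellular tRNA).
SPIKE_IN_SEQUENCE = (
    "CGAAATTAATACGACTCACTATAGGGGAATTGTGAGCGGATAACTGACTGACTGACT"
    "AAATAATTTTGTTTAACTTTAAGAAGGAGATATACCA"
)

#: cap reported for ratios that diverge (no synthesis: R -> infinity)
RATIO_CAP = 1e6


# ---------------------------------------------------------------------------
# protein turnover


@dataclass(frozen=True)
class TurnoverSimSpec:
    """Design of a pulse-labeling turnover experiment.

    k_syn values (per minute) are drawn log-normally; under the oxidative
    condition every k_syn is multiplied by ``oxidative_attenuation``
    (synthesis nearly shut down).  ``noise_cv`` is the multiplicative
    coefficient of variation of the measured ratio.
    """

    n_proteins: int = 500
    timepoints: tuple[float, ...] = (15.0, 30.0, 60.0, 90.0)
    ksyn_log_mean: float = math.log(0.007)
    ksyn_log_sigma: float = 0.3
    noise_cv: float = 0.1
    condition: str = "normal"
    oxidative_attenuation: float = 0.05
    t0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if any(t <= self.t0 for t in self.timepoints):
            raise ValueError("timepoints must exceed t0")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.condition not in ("normal", "oxidative"):
            raise ValueError("condition must be 'normal' or 'oxidative'")
        if self.oxidative_attenuation <= 0:
            raise ValueError("oxidative_attenuation must be positive")


def true_ratio(k_syn: float, dt) -> np.ndarray | float:
    """Noise-free ratio R = 1 / (exp(k_syn dt) - 1), capped at RATIO_CAP."""
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("time since t0 must be positive")
    growth = np.expm1(k_syn * dt)
    with np.errstate(divide="ignore"):
        r = np.where(growth > 0, 1.0 / np.where(growth > 0, growth, 1.0), np.inf)
    r = np.minimum(r, RATIO_CAP)
    return float(r) if r.ndim == 0 else r


def simulate_turnover(
    spec: TurnoverSimSpec,
) -> tuple[list[RatioSeries], dict[str, float]]:
    """Simulate ratio series for a cohort; returns (series, true k_syn map).

    Noise is log-normal multiplicative with the requested CV (ratios are
    positive and MS ratio error scales with the ratio), median-preserving.
    """
    rng = np.random.default_rng(spec.seed)
    ksyn = rng.lognormal(spec.ksyn_log_mean, spec.ksyn_log_sigma, spec.n_proteins)
    if spec.condition == "oxidative":
        ksyn = ksyn * spec.oxidative_attenuation
    dt = np.asarray(spec.timepoints, dtype=float) - spec.t0
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    width = len(str(spec.n_proteins - 1))
    series = []
    truth: dict[str, float] = {}
    for i, k in enumerate(ksyn):
        pid = f"P{i:0{width}d}"
        r = true_ratio(k, dt)
        if sigma > 0:
            r = r * np.exp(rng.normal(0.0, sigma, r.shape))
        r = np.minimum(r, RATIO_CAP)
        series.append(RatioSeries(pid, tuple(spec.timepoints), tuple(r)))
        truth[pid] = float(k)
    return series, truth


# ---------------------------------------------------------------------------
# MS1 scans


def simulate_ms1(
    peptides: Sequence[PeptideRecord],
    ratio: float,
    noise: float = 0.0,
    n_scans: int = 21,
    base_intensity: float = 1e6,
    n15_incorporation: float = 0.99,
    n_noise_peaks: int = 5,
    mz_range: tuple[float, float] = (300.0, 1600.0),
    seed: int = 0,
) -> MS1ScanSet:
    """Centroided scans containing each peptide's 14N and 15N envelopes.

    The light envelope is scaled by ``ratio`` relative to the heavy one, so
    the true MS1 area ratio is exactly ``ratio``.  Peaks follow a Gaussian
    elution profile across scans; ``noise`` is the additive intensity sd
    applied to every genuine peak, and ``n_noise_peaks`` random low peaks
    are sprinkled per scan when noise is non-zero.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    envelopes = []
    for pep in peptides:
        for label, scale in (("N14", ratio), ("N15", 1.0)):
            env = isotope_envelope(
                pep.composition, label=label, charge=pep.charge,
                n15_incorporation=n15_incorporation,
            )
            envelopes.append((env, scale))
    centers = (n_scans - 1) / 2.0
    widths = max(n_scans / 6.0, 1.0)
    scans: list[tuple[float, np.ndarray]] = []
    for s in range(n_scans):
        chrom = math.exp(-0.5 * ((s - centers) / widths) ** 2)
        mzs: list[float] = []
        intens: list[float] = []
        for env, scale in envelopes:
            for mz, rel in zip(env.mz, env.intensity):
                mzs.append(float(mz))
                intens.append(base_intensity * chrom * scale * rel)
        if noise > 0:
            intens = [max(0.0, v + rng.normal(0.0, noise)) for v in intens]
            for _ in range(n_noise_peaks):
                mzs.append(float(rng.uniform(*mz_range)))
                intens.append(float(abs(rng.normal(0.0, 3.0 * noise))))
        peaks = np.column_stack([mzs, intens])
        peaks = peaks[np.argsort(peaks[:, 0])]
        scans.append((float(s), peaks))
    return MS1ScanSet(scans=scans)


# ---------------------------------------------------------------------------
# tRNA-seq


# Synthetic E. coli-like catalogue of 47 tRNA species names (amino acid +
# anticodon, numbered alphabetically).  The three tandem-CCA species carry
# the ids the study uses for them.
_SPECIES_NAMES: tuple[str, ...] = (
    "1-Ala(TGC)", "2-Ala(GGC)", "3-Arg(ACG)", "4-Arg(CCG)", "5-Arg(CCT)",
    "6-Arg(TCT)", "7-Asn(GTT)", "8-Asp(GTC)", "9-Cys(GCA)", "10-Gln(CTG)",
    "11-Gln(TTG)", "12-Glu(TTC)", "13-Gly(CCC)", "14-Gly(GCC)", "15-Gly(TCC)",
    "16-His(GTG)", "17-Ile(CAT)", "18-Ile(GAT)", "19-Leu(CAA)", "20-Leu(CAG)",
    "21-Leu(GAG)", "22-Leu(TAA)", "23-Leu(TAG)", "24-Lys(TTT)", "25-Met(CAT)",
    "26-Phe(GAA)", "27-Pro(CGG)", "28-Pro(GGG)", "29-Pro(TGG)", "30-Ser(CGA)",
    "31-Ser(GCT)", "32-Ser(GGA)", "33-Ser(TGA)", "34-Thr(CGT)", "35-Thr(GGT)",
    "36-Thr(TGT)", "37-Trp(CCA)", "38-Tyr(GTA)", "39-Val(GAC)", "40-Val(TAC)",
    "41-Val(CAC)", "42-Thr(AGT)", "43-Ser(AGA)", "44-Pro(AGG)", "45-Gly(ACC)",
    "46-His(ATG)", "47-Ile(TAT)",
)
_TANDEM_CCA_IDS = frozenset({"1-Ala(TGC)", "7-Asn(GTT)", "12-Glu(TTC)"})


def _edit_distance(a: str, b: str) -> int:
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[-1])


def make_trna_refs(
    n_species: int = 47,
    body_length: int = 73,
    n_modified: int = 8,
    seed: int = 0,
    spike_in: str = SPIKE_IN_SEQUENCE,
) -> list[TRNARef]:
    """Generate a synthetic tRNA reference set.

    Random bodies plus the universal CCA end (CCACCA for the three
    tandem-CCA species); ~``n_modified`` modified positions per species,
    kept out of the final six bases so the 3' terminus stays informative.
    Every reference is checked to deviate from the spike-in by >= 3 edits.
    """
    if n_species < 1 or n_species > len(_SPECIES_NAMES):
        raise ValueError(f"n_species must be in 1..{len(_SPECIES_NAMES)}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    refs: list[TRNARef] = []
    for name in _SPECIES_NAMES[:n_species]:
        while True:
            body = "".join(rng.choice(bases, size=body_length))
            tail = "CCACCA" if name in _TANDEM_CCA_IDS else "CCA"
            seq = body + tail
            if _edit_distance(seq, spike_in) >= 3:
                break
        n_mod = min(n_modified, len(seq) - 6)
        mask = frozenset(
            int(p) for p in rng.choice(len(seq) - 6, size=n_mod, replace=False)
        )
        refs.append(TRNARef(name, seq, mask))
    return refs


@dataclass(frozen=True)
class TrnaSimSpec:
    """Design of a tRNA-seq library simulation.

    ``species_abundance`` gives expected read counts per species under the
    normal condition; when None, relative abundances are drawn once per
    spec (log-normal across species, sigma 0.8 — cellular tRNA pools span
    roughly an order of magnitude) and shared by every condition and
    replicate.  Under stress each species' expectation is divided by its
    ``fold_change``.  The spike-in
    receives ``spike_in_fraction`` of ``read_count`` in every condition
    (its input amount per cell equivalent is fixed by the protocol; the
    fraction of the library it occupies is a free parameter here).
    ``truncation_pmf`` maps 3'-truncation lengths (0..10) to probabilities;
    substitution errors occur at ``error_rate`` per base, elevated to
    ``modified_error_rate`` at modified positions (RT misreading).
    """

    refs: tuple[TRNARef, ...] = ()
    spike_in_seq: str = SPIKE_IN_SEQUENCE
    read_count: int = 100_000
    spike_in_fraction: float = 0.10
    species_abundance: Mapping[str, float] | None = None
    fold_change: Mapping[str, float] | float = 1.0
    truncation_pmf: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.85, 1: 0.05, 2: 0.04, 3: 0.03, 4: 0.02, 5: 0.01}
    )
    error_rate: float = 0.01
    modified_error_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.refs:
            raise ValueError("reference set must be non-empty")
        if not self.spike_in_seq.upper().endswith("CCA"):
            raise ValueError("spike-in must end in CCA")
        total = sum(self.truncation_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("truncation_pmf must sum to 1")
        if any(k < 0 or p < 0 for k, p in self.truncation_pmf.items()):
            raise ValueError("truncation_pmf entries must be non-negative")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 < self.spike_in_fraction < 1.0):
            raise ValueError("spike_in_fraction must be in (0, 1)")
        folds = (
            self.fold_change.values()
            if isinstance(self.fold_change, Mapping)
            else [self.fold_change]
        )
        if any(f <= 0 for f in folds):
            raise ValueError("fold_change must be positive")

    def fold_for(self, species_id: str) -> float:
        if isinstance(self.fold_change, Mapping):
            return float(self.fold_change.get(species_id, 1.0))
        return float(self.fold_change)

    def species_weights(self) -> dict[str, float]:
        """Relative abundance per species, fixed across conditions."""
        refs = sorted(self.refs, key=lambda r: r.species_id)
        if self.species_abundance is not None:
            return {r.species_id: float(self.species_abundance[r.species_id]) for r in refs}
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 0x5EED])
        draws = rng.lognormal(0.0, 0.8, len(refs))
        return {r.species_id: float(w) for r, w in zip(refs, draws)}


def _mutate(seq: str, mask: frozenset[int], spec: TrnaSimSpec, rng) -> str:
    out = list(seq)
    for pos in range(len(out)):
        p = spec.modified_error_rate if pos in mask else spec.error_rate
        if p > 0 and rng.random() < p:
            choices = [b for b in "ACGT" if b != out[pos]]
            out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_trna_reads(
    spec: TrnaSimSpec, condition: str = "normal", replicate: int = 0
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one condition's library; returns (reads, truth table).

    Reads are 3'-anchored: reverse transcription primes from the
    polyadenylated 3'-CCA, so each read covers the reference from its 5'
    end up to ``length - k`` where k is the 3'-truncation drawn from
    ``truncation_pmf`` (truncation happens on the RNA before anchoring).
    Per-species read numbers are Poisson around the condition's expectation.
    ``replicate`` indexes independent biological replicates that share the
    spec's underlying abundances.  The truth table lists expected and
    realized counts and the applied fold.
    """
    rng = np.random.default_rng(
        [spec.seed & 0x7FFFFFFF, zlib.crc32(condition.encode()) & 0x7FFFFFFF, replicate]
    )
    refs = sorted(spec.refs, key=lambda r: r.species_id)
    n_trna_reads = spec.read_count * (1.0 - spec.spike_in_fraction)
    weights = spec.species_weights()
    wsum = sum(weights.values())

    trunc_ks = np.array(sorted(spec.truncation_pmf), dtype=int)
    trunc_ps = np.array([spec.truncation_pmf[k] for k in trunc_ks], dtype=float)

    reads: list[tuple[str, str]] = []
    rows = []
    for ref in refs:
        fold = spec.fold_for(ref.species_id) if condition != "normal" else 1.0
        expected = n_trna_reads * weights[ref.species_id] / wsum / fold
        count = int(rng.poisson(expected))
        ks = rng.choice(trunc_ks, size=count, p=trunc_ps)
        for i, k in enumerate(ks):
            template = ref.sequence[: len(ref.sequence) - int(k)]
            seq = _mutate(template, ref.modified_mask, spec, rng)
            reads.append((f"{condition}|{ref.species_id}|{i}|trunc={int(k)}", seq))
        rows.append(
            {
                "species_id": ref.species_id,
                "condition": condition,
                "expected_reads": expected,
                "true_reads": count,
                "fold_change": fold,
            }
        )

    spike_expected = spec.read_count * spec.spike_in_fraction
    spike_count = int(rng.poisson(spike_expected))
    spike_seq = spec.spike_in_seq.upper()
    for i in range(spike_count):
        reads.append((f"{condition}|SPIKE|{i}", _mutate(spike_seq, frozenset(), spec, rng)))
    rows.append(
        {
            "species_id": "SPIKE",
            "condition": condition,
            "expected_reads": spike_expected,
            "true_reads": spike_count,
            "fold_change": 1.0,
        }
    )
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth curves and CT tables


def simulate_growth(
    k: float,
    od0: float = 0.005,
    duration: float = 300.0,
    interval: float = 1.0,
    noise_sd: float = 0.0,
    arrest: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential OD time series with an optional growth-arrest window.

    ``arrest = (t_start, t_end, factor)`` multiplies the rate constant by
    ``factor`` inside the window (a transient arrest after a stress pulse).
    Additive Gaussian noise of sd ``noise_sd`` is applied to the OD.
    Returns ``(times, od)`` in minutes / OD635 units.
    """
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    times = np.arange(0.0, duration + 0.5 * interval, interval)
    # cumulative integral of the (piecewise-constant) rate
    integral = k * times
    if arrest is not None:
        t_start, t_end, factor = arrest
        if t_end <= t_start:
            raise ValueError("arrest window must have t_end > t_start")
        overlap = np.clip(np.minimum(times, t_end) - t_start, 0.0, None)
        integral = integral - k * (1.0 - factor) * overlap
    od = od0 * np.exp(integral)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, od.shape)
    return times, od


def simulate_ct_table(
    targets: Mapping[str, float],
    reference_id: str = "SPIKE",
    conditions: tuple[str, str] = ("normal", "oxidative"),
    ct0: float = 20.0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CT table for targets with known fold *decreases* under stress.

    Quantity is 1 in the first condition and ``1 / fold`` in the second;
    CT = ct0 - log2(quantity) + noise.  The reference has quantity 1 in
    both conditions.  Output columns: target_id, condition, replicate, ct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    normal, stress = conditions
    quantities = {
        tid: {normal: 1.0, stress: 1.0 / fold} for tid, fold in targets.items()
    }
    quantities[reference_id] = {normal: 1.0, stress: 1.0}
    for tid in sorted(quantities):
        for cond in conditions:
            for rep in range(n_replicates):
                ct = ct0 - math.log2(quantities[tid][cond])
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append(
                    {"target_id": tid, "condition": cond, "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows)
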