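"""Modification-aware tRNA-seq: alignment, spike-in normalization, 3' profiling.

Mature tRNAs are short (~76 nt), end in CCA, and carry post-transcriptionally
modified nucleotides that reverse transcriptase misreads, so small-RNA reads
from tRNA show systematic "mismatches" at modified positions.  Reads are
therefore aligned with a semi-global unit-cost dynamic program in which
annotated modified positions match any base.  An alignment is accepted when
it has at most ``max_errors`` errors (mismatches + insertions + deletions;
default 3) and the read is at least ``min_length`` (default 25 nt) long.

Libraries carry a synthetic spike-in RNA of known input amount that differs
from every cellular tRNA by >= 3 nt; per-species read counts divided by the
spike-in count are comparable across conditions, giving per-species fold
changes under stress.  The 3'-truncation profile counts, per species, how
many reference bases are missing from each read's 3' end — for the three
E. coli tRNAs with tandem CCACCA ends, an offset of exactly 3 marks loss of
one CCA unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._align import assign_batch, encode, semiglobal_dp

__all__ = [
    "TRNARef",
    "ReadAlignment",
    "SpeciesCounts",
    "trim_adapters",
    "align_read",
    "assign_read",
    "assign_reads",
    "count_species",
    "normalize_and_fold_change",
    "truncation_profile",
    "replicate_concordance",
    "DEFAULT_MAX_ERRORS",
    "DEFAULT_MIN_LENGTH",
]

DEFAULT_MAX_ERRORS = 3
DEFAULT_MIN_LENGTH = 25


@dataclass(frozen=True)
class TRNARef:
    """One tRNA reference species (or the spike-in) with modification mask."""

    species_id: str
    sequence: str
    modified_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq.endswith("CCA"):
            raise ValueError(f"{self.species_id}: tRNA sequence must end in CCA")
        bad = [p for p in self.modified_mask if not (0 <= p < len(seq))]
        if bad:
            raise ValueError(f"{self.species_id}: mask positions out of range: {bad}")

    @property
    def tandem_cca(self) -> bool:
        """True for species whose genomic 3' end is CCACCA."""
        return self.sequence.endswith("CCACCA")


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    species_id: str | None
    errors: int
    aligned_length: int
    three_prime_offset: int
    accepted: bool
    reason: str | None = None


@dataclass
class SpeciesCounts:
    """Accepted-read counts per tRNA species plus the spike-in count."""

    condition: str
    counts: dict[str, int]
    spike_in_count: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()) or self.spike_in_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def normalized(self) -> dict[str, float]:
        if self.spike_in_count <= 0:
            raise ValueError("normalization requires spike_in_count > 0")
        return {s: c / self.spike_in_count for s, c in self.counts.items()}


def trim_adapters(
    reads: Iterable[tuple[str, str]], adapter: str, min_overlap: int = 3
) -> list[tuple[str, str]]:
    """Remove the 3' sequencing adapter from each (read_id, sequence).

    The read is cut at the leftmost full occurrence of the adapter; failing
    that, at the longest read suffix that matches a prefix of the adapter of
    length >= ``min_overlap``.  Reads without a detectable adapter are
    returned unchanged.
    """
    adapter = adapter.upper()
    if not adapter:
        raise ValueError("adapter must be non-empty")
    out = []
    for read_id, seq in reads:
        s = seq.upper()
        cut = s.find(adapter)
        if cut < 0:
            cut = len(s)
            max_ov = min(len(adapter) - 1, len(s))
            for ov in range(max_ov, min_overlap - 1, -1):
                if s.endswith(adapter[:ov]):
                    cut = len(s) - ov
                    break
        out.append((read_id, s[:cut]))
    return out


def align_read(
    read: str,
    ref: TRNARef,
    max_errors: int = DEFAULT_MAX_ERRORS,
    min_length: int = DEFAULT_MIN_LENGTH,
    read_id: str = "read",
) -> ReadAlignment:
    """Align one read to one reference (exact full DP, no shortcuts).

    The read must align end-to-end within the reference (free reference
    ends); modified positions match any base and contribute no error.
    ``three_prime_offset`` is the number of reference bases missing from the
    read's 3' end.  Reads shorter than ``min_length`` are rejected without
    alignment.
    """
    if len(read) < min_length:
        return ReadAlignment(
            read_id, None, 0, len(read), -1, False,
            reason=f"read shorter than {min_length} nt",
        )
    enc_read = encode(read)
    enc_ref = encode(ref.sequence)
    mask = np.zeros(len(ref.sequence), dtype=np.bool_)
    if ref.modified_mask:
        mask[list(ref.modified_mask)] = True
    errors, end = semiglobal_dp(enc_read, enc_ref, mask, -1)
    offset = len(ref.sequence) - int(end)
    accepted = errors <= max_errors
    return ReadAlignment(
        read_id,
        ref.species_id if accepted else None,
        int(errors),
        len(read),
        offset,
        accepted,
        reason=None if accepted else f"more than {max_errors} errors",
    )


def _ref_arrays(refs: Sequence[TRNARef]):
    order = sorted(range(len(refs)), key=lambda i: refs[i].species_id)
    maxlen = max(len(r.sequence) for r in refs)
    enc = np.zeros((len(refs), maxlen), dtype=np.int8)
    masks = np.zeros((len(refs), maxlen), dtype=np.bool_)
    lens = np.zeros(len(refs), dtype=np.int32)
    for row, i in enumerate(order):
        r = refs[i]
        enc[row, : len(r.sequence)] = encode(r.sequence)
        if r.modified_mask:
            masks[row, list(r.modified_mask)] = True
        lens[row] = len(r.sequence)
    return [refs[i] for i in order], enc, masks, lens


def assign_read(
    read: str,
    refs: Sequence[TRNARef],
    max_errors: int = DEFAULT_MAX_ERRORS,
    min_length: int = DEFAULT_MIN_LENGTH,
    read_id: str = "read",
) -> ReadAlignment:
    """Assign one read to its best reference, or mark it unassigned.

    Best accepted alignment by (fewest errors, longest aligned length, then
    lexicographically smallest species id); the aligned length is the full
    read for every accepted alignment, so the effective tie-break is the
    species id.
    """
    return assign_reads([(read_id, read)], refs, max_errors, min_length)[0]


def assign_reads(
    reads: Sequence[tuple[str, str]],
    refs: Sequence[TRNARef],
    max_errors: int = DEFAULT_MAX_ERRORS,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[ReadAlignment]:
    """Batch read assignment against all references (spike-in included).

    Semantics are identical to calling :func:`align_read` against every
    reference and applying the deterministic tie-break; the batch kernel
    merely abandons references that can no longer win.
    """
    if not refs:
        raise ValueError("reference set must be non-empty")
    refs_sorted, enc_refs, masks, ref_lens = _ref_arrays(refs)

    keep_idx = []
    results: list[ReadAlignment | None] = []
    for i, (rid, seq) in enumerate(reads):
        if len(seq) < min_length:
            results.append(
                ReadAlignment(
                    rid, None, 0, len(seq), -1, False,
                    reason=f"read shorter than {min_length} nt",
                )
            )
        else:
            results.append(None)
            keep_idx.append(i)

    if keep_idx:
        maxlen = max(len(reads[i][1]) for i in keep_idx)
        enc_reads = np.zeros((len(keep_idx), maxlen), dtype=np.int8)
        read_lens = np.zeros(len(keep_idx), dtype=np.int32)
        for row, i in enumerate(keep_idx):
            seq = reads[i][1]
            enc_reads[row, : len(seq)] = encode(seq)
            read_lens[row] = len(seq)
        ref_idx, errors, offsets = assign_batch(
            enc_reads, read_lens, enc_refs, ref_lens, masks, max_errors
        )
        for row, i in enumerate(keep_idx):
            rid, seq = reads[i]
            if ref_idx[row] < 0:
                results[i] = ReadAlignment(
                    rid, None, int(errors[row]), len(seq), -1, False,
                    reason=f"more than {max_errors} errors against every reference",
                )
            else:
                results[i] = ReadAlignment(
                    rid,
                    refs_sorted[ref_idx[row]].species_id,
                    int(errors[row]),
                    len(seq),
                    int(offsets[row]),
                    True,
                )
    return results  # type: ignore[return-value]


def count_species(
    alignments: Iterable[ReadAlignment],
    condition: str,
    spike_in_id: str = "SPIKE",
    species_ids: Sequence[str] | None = None,
) -> SpeciesCounts:
    """Tally accepted reads per species; the spike-in is counted separately."""
    counts: dict[str, int] = {s: 0 for s in (species_ids or [])}
    spike = 0
    for a in alignments:
        if not a.accepted:
            continue
        if a.species_id == spike_in_id:
            spike += 1
        else:
            counts[a.species_id] = counts.get(a.species_id, 0) + 1
    return SpeciesCounts(condition=condition, counts=counts, spike_in_count=spike)


def normalize_and_fold_change(
    counts_normal: SpeciesCounts, counts_stress: SpeciesCounts
) -> dict:
    """Spike-in-normalized per-species fold decreases under stress.

    For each species, ``fold = (count_normal / spike_normal) /
    (count_stress / spike_stress)``; a fold of 2 means the species dropped
    two-fold under stress.  Species with zero stress counts are flagged and
    excluded from the mean.  Returns per-species folds, their arithmetic
    mean, and the ratio-of-totals fold (total tRNA normal / total stress,
    both spike-normalized) as an alternative summary.
    """
    norm_n = counts_normal.normalized
    norm_s = counts_stress.normalized
    shared = sorted(set(norm_n) & set(norm_s))
    if not shared:
        raise ValueError("no shared species between conditions")
    fold: dict[str, float] = {}
    excluded: list[str] = []
    for s in shared:
        if norm_s[s] == 0:
            excluded.append(s)
        else:
            fold[s] = norm_n[s] / norm_s[s]
    tot_n = sum(norm_n[s] for s in shared)
    tot_s = sum(norm_s[s] for s in shared)
    return {
        "fold_change": fold,
        "mean_fold_change": float(np.mean(list(fold.values()))) if fold else math.nan,
        "total_fold_change": (tot_n / tot_s) if tot_s > 0 else math.nan,
        "excluded_zero_stress": excluded,
    }


def truncation_profile(
    alignments: Iterable[ReadAlignment],
    species_id: str,
    max_offset: int = 10,
    ref: TRNARef | None = None,
) -> dict:
    """3'-truncation histogram for one species.

    Fractions of the species' accepted reads at each 3' offset 0..max_offset
    (number of reference bases missing from the read's 3' end), normalized
    by *all* accepted reads of that species.  When the reference is given
    and carries a tandem CCACCA end, the fraction at offset 3 — reads ending
    exactly at the inner CCA — is reported separately.
    """
    offsets = [
        a.three_prime_offset
        for a in alignments
        if a.accepted and a.species_id == species_id
    ]
    if not offsets:
        raise ValueError(f"no accepted alignments for species {species_id!r}")
    total = len(offsets)
    fractions = np.zeros(max_offset + 1)
    for off in offsets:
        if 0 <= off <= max_offset:
            fractions[off] += 1
    fractions /= total
    out = {
        "species_id": species_id,
        "n_reads": total,
        "offsets": np.arange(max_offset + 1),
        "fractions": fractions,
    }
    if ref is not None and ref.tandem_cca:
        out["inner_cca_fraction"] = float(fractions[3]) if max_offset >= 3 else 0.0
    return out


def replicate_concordance(
    counts_rep1: SpeciesCounts, counts_rep2: SpeciesCounts
) -> tuple[float, float]:
    """Pearson and Spearman correlation of spike-normalized counts.

    Computed over species present in both replicates; requires at least
    three shared species.
    """
    n1 = counts_rep1.normalized
    n2 = counts_rep2.normalized
    shared = sorted(set(n1) & set(n2))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared species")
    x = np.array([n1[s] for s in shared])
    y = np.array([n2[s] for s in shared])
    pear = stats.pearsonr(x, y)
    spear = stats.spearmanr(x, y)
    return float(pear.statistic), float(spear.statistic)
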