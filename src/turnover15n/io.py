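"""File I/O: FASTA/FASTQ via Biopython, TSV tables via pandas.

All tabular interchange is plain TSV so that inputs and truth tables stay
human-inspectable.  The turnover ratio table is one row per measurement
(``protein_id, time_min, ratio``) — the layout of a reshaped
protein-quantification supplement.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import RatioSeries, TurnoverEstimate
from .trnaseq import TRNARef

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_modification_table",
    "write_modification_table",
    "load_trna_refs",
    "read_ratio_table",
    "write_estimates",
]


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """FASTQ (Phred+33) as a list of (read_id, sequence)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_modification_table(path) -> dict[str, frozenset[int]]:
    """Two-column TSV (species_id, 0-based position) -> per-species mask."""
    df = pd.read_csv(path, sep="\t", names=["species_id", "position"], comment="#")
    out: dict[str, set[int]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["species_id"]), set()).add(int(row["position"]))
    return {k: frozenset(v) for k, v in out.items()}


def write_modification_table(path, refs: Sequence[TRNARef]) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            for pos in sorted(ref.modified_mask):
                fh.write(f"{ref.species_id}\t{pos}\n")


def load_trna_refs(fasta_path, modification_tsv=None) -> list[TRNARef]:
    """Assemble references from a FASTA and an optional modification TSV."""
    seqs = read_fasta(fasta_path)
    masks = read_modification_table(modification_tsv) if modification_tsv else {}
    return [
        TRNARef(sid, seq, masks.get(sid, frozenset())) for sid, seq in seqs.items()
    ]


def read_ratio_table(path) -> list[RatioSeries]:
    """TSV with columns protein_id, time_min, ratio -> per-protein series.

    Rows with a missing or non-positive ratio are dropped (quantification
    reports those as missing, they are not imputed).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "time_min", "ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"ratio table must have columns {sorted(required)}")
    df = df.dropna(subset=["ratio"])
    df = df[df["ratio"] > 0]
    out = []
    for pid, grp in df.groupby("protein_id", sort=True):
        grp = grp.sort_values("time_min").drop_duplicates("time_min")
        out.append(
            RatioSeries(
                str(pid),
                tuple(grp["time_min"].astype(float)),
                tuple(grp["ratio"].astype(float)),
            )
        )
    return out


def write_estimates(path, estimates: Sequence[TurnoverEstimate]) -> None:
    rows = [
        {
            "protein_id": e.protein_id,
            "k_syn_per_min": e.k_syn,
            "pearson_r": e.pearson_r,
            "p_value": e.p_value,
            "half_life_min": e.half_life,
            "censored": e.censored,
            "n_points": e.n_points,
            "reason": e.reason or "",
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
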