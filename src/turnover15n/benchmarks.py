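"""Summaries over externally supplied benchmark tables.

The study's supplementary protein-ratio and tRNA-count tables (and the GEO
sequencing data) can be dropped in as TSVs to reproduce the published
proteome- and tRNA-level summaries; the same entry points run on synthetic
tables from :mod:`turnover15n.simulate`, which is how they are tested here.
"""

from __future__ import annotations

import pandas as pd

from . import kinetics
from .io import read_ratio_table
from .trnaseq import SpeciesCounts, normalize_and_fold_change, replicate_concordance

__all__ = [
    "turnover_benchmark",
    "trna_count_benchmark",
    "read_count_table",
]


def turnover_benchmark(
    ratio_tsv,
    min_points: int = 3,
    fast_threshold: float = 100.0,
    strain_column: str | None = None,
) -> dict:
    """Proteome half-life summary from a ratio table.

    The TSV holds one row per (protein, timepoint) measurement with columns
    ``protein_id, time_min, ratio`` (optionally pre-filtered to one strain
    and condition).  Returns the per-protein estimates plus the cohort
    statistics: mean uncensored half-life, fraction of proteins below
    ``fast_threshold`` minutes, fraction censored above the 500-min cap,
    and the fraction of fits with P > 0.05.
    """
    series = read_ratio_table(ratio_tsv)
    estimates = kinetics.fit_many(series, min_points=min_points)
    usable = [e for e in estimates if e.reason is None]
    stats = kinetics.half_life_stats(usable, fast_threshold=fast_threshold)
    stats["fraction_p_above_0.05"] = (
        sum(e.p_value > 0.05 for e in usable) / len(usable) if usable else float("nan")
    )
    stats["estimates"] = estimates
    return stats


def read_count_table(path, spike_in_id: str = "SPIKE") -> dict[str, SpeciesCounts]:
    """Per-condition tRNA read counts from a TSV.

    Columns: ``species_id`` plus one count column per condition/replicate
    (the layout of a read-count supplement).  The spike-in row supplies the
    normalizer for each column.
    """
    df = pd.read_csv(path, sep="\t")
    if "species_id" not in df.columns:
        raise ValueError("count table must have a species_id column")
    df = df.set_index("species_id")
    if spike_in_id not in df.index:
        raise ValueError(f"count table must contain a {spike_in_id!r} row")
    out = {}
    for col in df.columns:
        counts = df[col].astype(int)
        out[col] = SpeciesCounts(
            condition=col,
            counts={s: int(c) for s, c in counts.items() if s != spike_in_id},
            spike_in_count=int(counts[spike_in_id]),
        )
    return out


def trna_count_benchmark(
    count_tsv,
    normal: str,
    stress: str | None = None,
    replicates: tuple[str, str] | None = None,
    spike_in_id: str = "SPIKE",
) -> dict:
    """Fold-change and reproducibility summary from a count table."""
    tables = read_count_table(count_tsv, spike_in_id=spike_in_id)
    out: dict = {}
    if stress is not None:
        out["fold"] = normalize_and_fold_change(tables[normal], tables[stress])
    if replicates is not None:
        r1, r2 = replicates
        pearson, spearman = replicate_concordance(tables[r1], tables[r2])
        out["replicate_pearson_r"] = pearson
        out["replicate_spearman_r"] = spearman
    return out
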