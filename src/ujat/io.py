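"""Tab-separated input/output for summary statistics, strata and cohorts.

All files are plain TSV with a header line; lines starting with '#' are
provenance comments (package version, seed, configuration) written by
:func:`write_table` and ignored on read.  P values are serialized at full
double precision and always accompanied by a log10 column, so scan hits
far below the double underflow threshold survive a round trip through the
log column.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .joint_test import JointResult, SummaryRecord
from .meta import StratumEstimate

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "write_results",
    "results_frame",
    "read_strata",
    "write_table",
    "read_table",
    "write_cohort",
    "read_cohort",
]

SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "z_ancestry",
    "z_assoc",
    "f0",
    "f2",
]

RESULT_COLUMNS = ["statistic", "p_joint", "log10_p_joint", "consistent", "degenerate"]


def write_table(path, frame: pd.DataFrame, meta: Optional[Mapping] = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"# ujat v{__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _parse_freq(value, line_no: int, name: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    f = float(value)
    if not (0.0 <= f <= 1.0):
        raise ValueError(
            f"line {line_no}: {name}={f} outside [0, 1]"
        )
    return f


def read_sumstats(path) -> List[SummaryRecord]:
    """Read per-variant summary statistics into SummaryRecords.

    Requires the columns {variant_id, chrom, pos, effect_allele,
    other_allele, z_ancestry, z_assoc, f0, f2}; any extra columns are
    preserved in each record's ``extras`` and passed through on write.
    Malformed rows are rejected with their (1-based) line numbers; empty
    frequency cells become ``None`` (degenerate downstream, never guessed).
    """
    df = read_table(path)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty summary-statistics file")
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in SUMSTAT_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = row._asdict()
        line_no = i
        z_a, z_g = float(row_d["z_ancestry"]), float(row_d["z_assoc"])
        records.append(
            SummaryRecord(
                variant_id=str(row_d["variant_id"]),
                chrom=str(row_d["chrom"]),
                pos=int(row_d["pos"]),
                effect_allele=str(row_d["effect_allele"]),
                other_allele=str(row_d["other_allele"]),
                z_ancestry=z_a,
                z_assoc=z_g,
                f0=_parse_freq(row_d["f0"], line_no, "f0"),
                f2=_parse_freq(row_d["f2"], line_no, "f2"),
                extras={c: row_d[c] for c in extra_cols} or None,
            )
        )
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def _records_frame(records: Sequence[SummaryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "variant_id": r.variant_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "z_ancestry": r.z_ancestry,
            "z_assoc": r.z_assoc,
            "f0": r.f0,
            "f2": r.f2,
        }
        if r.extras:
            row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def write_sumstats(path, records: Sequence[SummaryRecord],
                   meta: Optional[Mapping] = None) -> None:
    write_table(path, _records_frame(records), meta)


def results_frame(
    records: Sequence[SummaryRecord], results: Sequence[JointResult]
) -> pd.DataFrame:
    """Merge input records with their joint-test results, column-stable."""
    if len(records) != len(results):
        raise ValueError("records and results are not aligned")
    df = _records_frame(records)
    df["statistic"] = [r.statistic for r in results]
    df["p_joint"] = [r.p_joint for r in results]
    df["log10_p_joint"] = [r.log10_p_joint for r in results]
    df["consistent"] = [r.consistent for r in results]
    df["degenerate"] = [r.degenerate for r in results]
    df["significant"] = [r.significant for r in results]
    return df


def write_results(
    path,
    records: Sequence[SummaryRecord],
    results: Sequence[JointResult],
    meta: Optional[Mapping] = None,
) -> None:
    write_table(path, results_frame(records, results), meta)


def read_strata(path) -> Dict[str, List[StratumEstimate]]:
    """Read per-stratum estimates grouped by variant.

    Expects columns {variant_id, stratum, beta, se} with optional n;
    insertion order of variants and strata follows the file.
    """
    df = read_table(path)
    required = ["variant_id", "stratum", "beta", "se"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    grouped: Dict[str, List[StratumEstimate]] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        n = d.get("n")
        grouped.setdefault(str(d["variant_id"]), []).append(
            StratumEstimate(
                label=str(d["stratum"]),
                beta=float(d["beta"]),
                se=float(d["se"]),
                n=int(n) if n is not None and not pd.isna(n) else None,
            )
        )
    if not grouped:
        raise ValueError(f"{path}: no data rows")
    return grouped


def write_cohort(directory, cohort, meta: Optional[Mapping] = None) -> None:
    """Write a cohort as three TSVs: phenotypes, dosage, ancestry.

    Matrices are written variants x individuals (one row per variant).
    """
    import os

    os.makedirs(directory, exist_ok=True)
    write_table(
        os.path.join(directory, "phenotypes.tsv"),
        cohort.individuals.reset_index(),
        meta,
    )
    for name, frame in (("dosage", cohort.dosage), ("ancestry", cohort.ancestry)):
        mat = frame.T
        mat.index.name = "variant_id"
        write_table(os.path.join(directory, f"{name}.tsv"), mat.reset_index(), meta)


def read_cohort(directory):
    """Read a cohort directory written by :func:`write_cohort`."""
    import os

    from .assoc import CohortData

    individuals = read_table(os.path.join(directory, "phenotypes.tsv")).set_index("id")
    dosage = (
        read_table(os.path.join(directory, "dosage.tsv"))
        .set_index("variant_id")
        .T
    )
    ancestry = (
        read_table(os.path.join(directory, "ancestry.tsv"))
        .set_index("variant_id")
        .T
    )
    dosage.index.name = "id"
    ancestry.index.name = "id"
    return CohortData(
        individuals=individuals,
        dosage=dosage.astype(float),
        ancestry=ancestry.astype(int),
    )
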