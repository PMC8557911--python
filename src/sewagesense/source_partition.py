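"""Partition river ASVs into freshwater / human-fecal / sewer / uncategorized sources.

Each amplicon sequence variant (ASV) is assigned by full-length exact sequence
matching against labeled reference databases, with freshwater precedence:

1. an ASV matching a freshwater reference is ``freshwater`` (and is excluded
   from the sewage-side databases even if it also matches there);
2. otherwise, an ASV matching a human-stool or sewer reference is admitted as
   ``human_fecal`` or ``sewer`` only if its 5th-percentile relative abundance
   across river samples is strictly lower than the reference's 95th-percentile
   relative abundance across raw-sewage samples (abundant cosmopolitan river
   organisms that merely co-occur in sewage are thereby rejected);
3. anything else is ``uncategorized`` (presumed terrestrial or other origin).

Per-sample category relative abundances and the combined sewer + human-fecal
"sewage proportion" (the quantity compared against the sequence-based risk
threshold) are summarized from the partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ASVTable",
    "SourceRecord",
    "SourceDatabase",
    "PartitionResult",
    "CATEGORIES",
    "exact_match",
    "river_percentile",
    "sewage_inclusion_filter",
    "partition",
    "category_relative_abundance",
    "sewage_proportion",
    "read_asv_table",
    "read_source_fasta",
    "write_source_fasta",
]

CATEGORIES = ("freshwater", "human_fecal", "sewer", "uncategorized")
SOURCES = ("freshwater", "sewer", "human_stool")

_VALID_BASES = frozenset("ACGT")


def _validate_sequence(seq: str, context: str) -> str:
    s = str(seq).upper()
    if not s or not set(s) <= _VALID_BASES:
        raise ValueError(
            f"{context}: sequence must be nonempty over A/C/G/T "
            f"(ambiguity codes rejected): {seq[:40]!r}"
        )
    return s


@dataclass
class ASVTable:
    """Read counts (samples x ASVs) with per-ASV sequences.

    ``counts`` rows are samples, columns are ASV ids; ``sequences`` maps each
    ASV id to its validated DNA sequence.  ``taxonomy`` is an optional
    pass-through annotation.
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.sequences)
        if missing:
            raise ValueError(f"ASVs without sequences: {sorted(missing)[:5]} ...")
        self.sequences = {
            a: _validate_sequence(s, f"ASV {a}") for a, s in self.sequences.items()
        }

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; samples with zero total become NaN rows."""
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.div(totals.replace(0, np.nan), axis=0)
        return rel


@dataclass(frozen=True)
class SourceRecord:
    reference_id: str
    sequence: str
    source: str
    sewage_p95: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence, self.reference_id))
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.source == "freshwater":
            if self.sewage_p95 is not None:
                raise ValueError("freshwater references carry no sewage_p95")
        else:
            if self.sewage_p95 is None or not (0 < self.sewage_p95 <= 1):
                raise ValueError(
                    f"{self.reference_id}: sewage_p95 must be in (0, 1] for "
                    f"{self.source} references"
                )


class SourceDatabase:
    """A labeled reference database with O(1) exact-sequence lookup."""

    def __init__(self, records, source: str | None = None,
                 metadata: dict | None = None):
        self.records: list[SourceRecord] = list(records)
        self.metadata = dict(metadata or {})
        if source is not None and any(r.source != source for r in self.records):
            raise ValueError(f"records must all have source {source!r}")
        self.source = source or (self.records[0].source if self.records else None)
        self._by_sequence: dict[str, SourceRecord] = {}
        for rec in self.records:
            if rec.sequence in self._by_sequence:
                raise ValueError(
                    f"duplicate sequence within database ({rec.reference_id} vs "
                    f"{self._by_sequence[rec.sequence].reference_id})"
                )
            self._by_sequence[rec.sequence] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lookup(self, sequence: str) -> SourceRecord | None:
        return self._by_sequence.get(sequence)


@dataclass
class PartitionResult:
    """Per-ASV category assignment with provenance.

    ``assignments`` columns: asv_id, category, reference_id (nullable),
    river_p5 (nullable; only computed where the inclusion filter applied).
    ``settings`` records auditable conventions (percentile definition etc.).
    """

    assignments: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.assignments["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {bad}")
        if self.assignments["asv_id"].duplicated().any():
            raise ValueError("each ASV must appear exactly once")

    def category_of(self) -> pd.Series:
        return self.assignments.set_index("asv_id")["category"]

    def summary(self) -> dict:
        counts = self.assignments["category"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES}


def exact_match(asv_sequence: str, database: SourceDatabase) -> str | None:
    """Return the reference_id whose sequence equals the ASV's, else None.

    Matching is full-length string equality after uppercasing; there is no
    reverse-complement search (amplicons are orientation-fixed by the primers).
    """
    seq = _validate_sequence(asv_sequence, "query")
    rec = database.lookup(seq)
    return rec.reference_id if rec else None


def river_percentile(asv_id: str, table: ASVTable, q: float) -> float:
    """q-th percentile of an ASV's relative abundance across all river samples.

    Zero abundances count as observations; samples with zero total reads are
    excluded (their proportions are undefined).  Percentiles use linear
    interpolation between closest order statistics (numpy's "linear" method).
    """
    rel = table.relative_abundance()
    values = rel[asv_id].dropna().to_numpy()
    if values.size == 0:
        raise ValueError("no river sample with nonzero total reads")
    return float(np.percentile(values, q))


def sewage_inclusion_filter(river_p5: float, sewage_p95: float) -> bool:
    """True iff river_p5 < sewage_p95 (strict).

    An ASV as abundant in rivers as in raw sewage is not credibly
    sewage-derived, however exact its match.
    """
    if sewage_p95 is None:
        raise ValueError("sewage_p95 is required")
    return river_p5 < sewage_p95


def partition(table: ASVTable,
              freshwater_db: SourceDatabase,
              sewer_db: SourceDatabase,
              stool_db: SourceDatabase,
              freshwater_flags: pd.Series | None = None,
              percentile_q: float = 5.0) -> PartitionResult:
    """Assign every ASV in the table to one of the four source categories.

    Precedence is freshwater -> human_stool -> sewer -> uncategorized.  An ASV
    matching a sewage-side database is admitted only if the 5th-percentile /
    95th-percentile inclusion filter passes; otherwise it falls through to
    ``uncategorized``.

    ``freshwater_flags`` optionally supplies freshwater membership as a
    per-ASV boolean (emulating an upstream taxonomy assignment); flagged ASVs
    take freshwater precedence exactly as sequence matches do, and both paths
    feed the same downstream logic.
    """
    seqs = [table.sequences[a] for a in table.asv_ids]
    if len(set(seqs)) != len(seqs):
        dupes = pd.Series(seqs).duplicated()
        raise ValueError(
            "duplicate ASV sequences in table (dereplication assumed upstream): "
            f"{[a for a, d in zip(table.asv_ids, dupes) if d][:5]}"
        )
    rel = table.relative_abundance()

    rows = []
    for asv_id in table.asv_ids:
        seq = table.sequences[asv_id]
        category, ref_id, p5 = "uncategorized", None, None

        flagged_fw = bool(freshwater_flags.get(asv_id, False)) if freshwater_flags is not None else False
        fw_ref = exact_match(seq, freshwater_db)
        if flagged_fw or fw_ref is not None:
            category, ref_id = "freshwater", fw_ref
        else:
            for db, cat in ((stool_db, "human_fecal"), (sewer_db, "sewer")):
                rec = db.lookup(seq)
                if rec is None:
                    continue
                values = rel[asv_id].dropna().to_numpy()
                if values.size == 0:
                    raise ValueError("no river sample with nonzero total reads")
                p5 = float(np.percentile(values, percentile_q))
                if sewage_inclusion_filter(p5, rec.sewage_p95):
                    category, ref_id = cat, rec.reference_id
                break  # stool precedence over sewer: stop at the first match
        rows.append({"asv_id": asv_id, "category": category,
                     "reference_id": ref_id, "river_p5": p5})

    assignments = pd.DataFrame(rows, columns=["asv_id", "category", "reference_id", "river_p5"])
    settings = {
        "percentile_q": percentile_q,
        "percentile_method": "linear interpolation between order statistics, zeros included",
        "precedence": "freshwater > human_stool > sewer > uncategorized",
        "matching": "full-length exact equality, uppercased, no reverse complement",
    }
    return PartitionResult(assignments=assignments, settings=settings)


def category_relative_abundance(table: ASVTable, part: PartitionResult) -> pd.DataFrame:
    """Per-sample relative abundance summed within each source category.

    Rows are samples, columns the four categories; rows sum to 1 (within
    1e-9) except zero-read samples, which are all-NaN (undefined).
    """
    cat = part.category_of()
    missing = set(table.asv_ids) - set(cat.index)
    if missing:
        raise ValueError(f"partition does not cover ASVs: {sorted(missing)[:5]}")
    rel = table.relative_abundance()
    out = pd.DataFrame(index=table.counts.index, columns=list(CATEGORIES), dtype=float)
    for c in CATEGORIES:
        members = [a for a in table.asv_ids if cat[a] == c]
        out[c] = rel[members].sum(axis=1, min_count=0) if members else 0.0
    out[rel.isna().all(axis=1)] = np.nan
    return out


def sewage_proportion(table: ASVTable, part: PartitionResult,
                      include_human_fecal: bool = True) -> pd.Series:
    """Combined sewer + human-fecal relative abundance per sample.

    This is the sample-level quantity compared against the sequence-based
    pollution threshold.  ``include_human_fecal=False`` restricts to
    sewer-assigned ASVs only.
    """
    props = category_relative_abundance(table, part)
    s = props["sewer"].copy()
    if include_human_fecal:
        s = s + props["human_fecal"]
    s.name = "sewage_proportion"
    return s


# --- I/O -------------------------------------------------------------------

def read_asv_table(counts_tsv, fasta_path) -> ASVTable:
    """Load an ASVTable from a counts TSV (samples x ASVs) and an ASV FASTA."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    return ASVTable(counts=counts, sequences=seqs)


def _parse_description(desc: str) -> dict:
    out = {}
    for token in desc.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def read_source_fasta(path, source: str | None = None) -> SourceDatabase:
    """Load a reference database from FASTA with ``source=``/``sewage_p95=``
    key-value pairs on the description line."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = _parse_description(rec.description)
        src = kv.get("source", source)
        if src is None:
            raise ValueError(f"{rec.id}: no source= tag and no source argument")
        p95 = float(kv["sewage_p95"]) if "sewage_p95" in kv else None
        records.append(SourceRecord(rec.id, str(rec.seq), src, p95))
    return SourceDatabase(records, source=source)


def write_source_fasta(db: SourceDatabase, path) -> None:
    recs = []
    for r in db:
        desc = f"source={r.source}"
        if r.sewage_p95 is not None:
            desc += f" sewage_p95={r.sewage_p95:.6g}"
        recs.append(SeqRecord(Seq(r.sequence), id=r.reference_id, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def write_partition(part: PartitionResult, tsv_path, json_path=None) -> None:
    part.assignments.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {"settings": part.settings, "category_counts": part.summary()}
        Path(json_path).write_text(json.dumps(payload, indent=2))
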