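"""Readers and writers for the FASTA/TSV/JSON formats of the pipeline.

Haplotypes travel either as a FASTA whose record ids parse as
``sample_id.target_id.allele_index`` plus a tab-separated metadata table, or
as a single combined haplotype table with columns ``sample_id, target_id,
allele_index, sequence, read_count``.  Assignment results are written as a
TSV with the proportion vectors serialized as JSON columns, and read back
losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .assign import AssignmentResult
from .samples import Sample, TargetHaplotype

__all__ = [
    "ParseError",
    "ParseReport",
    "read_haplotypes",
    "read_haplotype_table",
    "write_haplotypes",
    "write_results",
    "read_results",
    "load_config",
]

_TABLE_COLUMNS = ["sample_id", "target_id", "allele_index", "sequence", "read_count"]
_VALID = set("ACGTN")


class ParseError(ValueError):
    """Unrecoverable problem in an input file (exit code 3 at the CLI)."""


@dataclass
class ParseReport:
    """Per-file account of records read, skipped and why."""

    n_read: int = 0
    n_skipped: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def skip(self, record: str, reason: str) -> None:
        self.n_skipped += 1
        self.skipped.append((record, reason))


def _build_samples(
    rows: list[tuple[str, str, int, str, int]],
    meta: pd.DataFrame | None,
    report: ParseReport,
) -> list[Sample]:
    seen: set[tuple[str, str, int]] = set()
    by_sample: dict[str, list[TargetHaplotype]] = {}
    for sample_id, target_id, allele, seq, reads in rows:
        key = (sample_id, target_id, allele)
        if key in seen:
            raise ParseError(
                f"duplicate haplotype key (sample={sample_id!r}, "
                f"target={target_id!r}, allele={allele})"
            )
        seen.add(key)
        by_sample.setdefault(sample_id, []).append(
            TargetHaplotype(target_id, allele, seq, reads)
        )
    meta_by_id: dict[str, dict] = {}
    if meta is not None:
        if "sample_id" not in meta.columns:
            raise ParseError("metadata table lacks a 'sample_id' column")
        meta_by_id = {
            str(row["sample_id"]): dict(row) for _, row in meta.iterrows()
        }
    samples = []
    for sample_id in sorted(by_sample):
        info = meta_by_id.get(sample_id, {})
        samples.append(
            Sample.from_haplotypes(
                sample_id,
                by_sample[sample_id],
                country=str(info.get("country", "") or ""),
                species_label=(str(info["species"]) if info.get("species") else None),
                metadata={
                    k: v
                    for k, v in info.items()
                    if k not in ("sample_id", "country", "species")
                },
            )
        )
    return samples


def read_haplotypes(
    fasta_path, meta_path=None
) -> tuple[list[Sample], ParseReport]:
    """Read per-sample haplotypes from FASTA (+ optional metadata TSV).

    Record ids must parse as ``sample_id.target_id.allele_index``; sequences
    are uppercased and validated over {A,C,G,T,N}.  Records with invalid
    characters or unparseable ids are skipped and listed in the report;
    duplicate keys hard-fail with :class:`ParseError`.
    """
    report = ParseReport()
    rows: list[tuple[str, str, int, str, int]] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        report.n_read += 1
        try:
            sample_id, target_id, allele_s = record.id.rsplit(".", 2)
            allele = int(allele_s)
        except ValueError:
            report.skip(record.id, "id does not parse as sample.target.allele")
            continue
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            report.skip(record.id, f"invalid characters {sorted(bad)}")
            continue
        rows.append((sample_id, target_id, allele, seq, 0))
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    return _build_samples(rows, meta, report), report


def read_haplotype_table(tsv_path) -> tuple[list[Sample], ParseReport]:
    """Read a combined haplotype table (five required columns + optional
    ``country``/``species`` metadata columns)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(
            f"haplotype table {tsv_path} is missing columns {sorted(missing)}"
        )
    report = ParseReport()
    rows: list[tuple[str, str, int, str, int]] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        report.n_read += 1
        seq = str(row.sequence).upper()
        bad = set(seq) - _VALID
        if bad:
            report.skip(f"line {line_no}", f"invalid characters {sorted(bad)}")
            continue
        try:
            allele = int(row.allele_index)
            reads = int(row.read_count or 0)
        except ValueError:
            report.skip(f"line {line_no}", "non-integer allele_index or read_count")
            continue
        rows.append((str(row.sample_id), str(row.target_id), allele, seq, reads))
    meta_cols = [c for c in ("sample_id", "country", "species") if c in df.columns]
    meta = df[meta_cols].drop_duplicates("sample_id") if "sample_id" in meta_cols else None
    return _build_samples(rows, meta, report), report


def write_haplotypes(samples: Sequence[Sample], fasta_path, meta_path=None) -> None:
    """Write samples as FASTA (+ optional metadata TSV), fully sorted."""
    lines = []
    for s in sorted(samples, key=lambda x: x.sample_id):
        if "." in s.sample_id:
            raise ValueError(f"sample id {s.sample_id!r} must not contain '.'")
        for hap in s.iter_haplotypes():
            lines.append(f">{s.sample_id}.{hap.target_id}.{hap.allele_index}\n{hap.sequence}")
    Path(fasta_path).write_text("\n".join(lines) + "\n")
    if meta_path is not None:
        rows = [
            {
                "sample_id": s.sample_id,
                "country": s.country,
                "species": s.species_label or "",
            }
            for s in sorted(samples, key=lambda x: x.sample_id)
        ]
        pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


_RESULT_COLUMNS = [
    "sample_id",
    "n_targets",
    "contamination",
    "call_level",
    "call_label",
    "top_proportion",
    "proportions_fine",
    "proportions_intermediate",
    "proportions_coarse",
]


def _round_props(props: dict[str, float]) -> dict[str, float]:
    return {k: round(v, 12) for k, v in sorted(props.items())}


def write_results(results: Sequence[AssignmentResult], path) -> None:
    """Write assignment results as a TSV (stable column order, JSON
    proportion columns); an empty result list yields a header-only file."""
    rows = []
    for r in sorted(results, key=lambda x: x.sample_id):
        top = r.top("fine")
        rows.append(
            {
                "sample_id": r.sample_id,
                "n_targets": r.n_targets,
                "contamination": r.contamination or "",
                "call_level": r.call_level,
                "call_label": r.call_label or "",
                "top_proportion": "" if top is None else repr(top[1]),
                "proportions_fine": json.dumps(_round_props(r.proportions_fine)),
                "proportions_intermediate": json.dumps(
                    _round_props(r.proportions_intermediate)
                ),
                "proportions_coarse": json.dumps(_round_props(r.proportions_coarse)),
            }
        )
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path) -> list[AssignmentResult]:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"results table is missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssignmentResult(
                sample_id=row.sample_id,
                n_targets=int(row.n_targets),
                contamination=row.contamination or None,
                call_level=row.call_level,
                call_label=row.call_label or None,
                proportions_fine=json.loads(row.proportions_fine),
                proportions_intermediate=json.loads(row.proportions_intermediate),
                proportions_coarse=json.loads(row.proportions_coarse),
            )
        )
    return out


def load_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
    config: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{line_no}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config
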