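"""Reading and writing of event tables, variant tables and results.

Formats:

* Event tables: CSV with columns ``FSC, SSC, PW, FSC_W`` plus one or
  more fluorescence channels.
* Pooled variant tables: TSV with columns ``chrom, pos (1-based), ref,
  alt, effect, evo_alt, evo_cov, anc_alt, anc_cov, ctrl_alt``; or
  VCF 4.2 with samples ``EVO`` / ``ANC`` carrying ``AD`` (ref,alt depth)
  fields, the effect annotation in ``INFO/EFF`` and the control-clone
  alt-read count in ``INFO/CTRL_ALT``.
* Threshold tables, gate reports and noise estimates round-trip as
  TSV / JSON via plain pandas / json.

Both variant dialects are lossless for the columns above and preserve
1-based coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_pooled_variants",
    "write_pooled_variants",
    "write_candidates",
    "validate_pooled_variants",
    "to_json",
]

EVENT_COLUMNS = ("FSC", "SSC", "PW", "FSC_W")
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "effect",
                   "evo_alt", "evo_cov", "anc_alt", "anc_cov", "ctrl_alt")


def read_event_table(path) -> pd.DataFrame:
    """Read a CSV event table, checking the scatter/pulse columns."""
    table = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing event column(s) {missing}")
    if not np.isfinite(table.select_dtypes("number").to_numpy()).all():
        raise ValueError(f"{path}: event table contains non-finite values")
    return table


def write_event_table(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def validate_pooled_variants(table: pd.DataFrame, source: str = "table") -> None:
    """Schema and invariant checks; raises with the offending row number."""
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    for pool in ("evo", "anc"):
        alt = table[f"{pool}_alt"].to_numpy()
        cov = table[f"{pool}_cov"].to_numpy()
        bad = np.flatnonzero((alt < 0) | (alt > cov))
        if bad.size:
            raise ValueError(
                f"{source}: row {bad[0] + 1}: {pool}_alt outside "
                f"[0, {pool}_cov]")
    dup = table.duplicated(subset=["chrom", "pos", "alt"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{source}: row {row + 1}: duplicate (chrom, pos, alt)")


def _read_variants_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_pooled_variants(table, source=str(path))
    return table


def _read_variants_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for name in ("EVO", "ANC"):
            if name not in samples:
                raise ValueError(f"{path}: VCF must carry sample {name!r}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record at {rec.chrom}:{rec.pos} is not "
                    "biallelic")
            row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                   "alt": rec.alts[0],
                   "effect": rec.info.get("EFF", "other"),
                   "ctrl_alt": int(rec.info.get("CTRL_ALT", 0))}
            for name, label in (("EVO", "evo"), ("ANC", "anc")):
                ad = rec.samples[name]["AD"]
                row[f"{label}_alt"] = int(ad[1])
                row[f"{label}_cov"] = int(ad[0]) + int(ad[1])
            rows.append(row)
    table = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    validate_pooled_variants(table, source=str(path))
    return table


def read_pooled_variants(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a pooled variant table from TSV or VCF (by extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        return _read_variants_tsv(path)
    if fmt == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown format {fmt!r}")


def _write_variants_vcf(table: pd.DataFrame, path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom in pd.unique(table["chrom"]):
        length = int(table.loc[table["chrom"] == chrom, "pos"].max()) + 1
        header.contigs.add(str(chrom), length=length)
    header.info.add("EFF", 1, "String", "Variant effect class")
    header.info.add("CTRL_ALT", 1, "Integer",
                    "Alt reads in the ancestral control clone")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample("EVO")
    header.add_sample("ANC")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in table.iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])))
            rec.info["EFF"] = str(row["effect"])
            rec.info["CTRL_ALT"] = int(row["ctrl_alt"])
            for name, label in (("EVO", "evo"), ("ANC", "anc")):
                alt = int(row[f"{label}_alt"])
                cov = int(row[f"{label}_cov"])
                rec.samples[name]["AD"] = (cov - alt, alt)
            vcf.write(rec)


def write_pooled_variants(table: pd.DataFrame, path,
                          fmt: str | None = None) -> None:
    """Write a pooled variant table as TSV or VCF (by extension)."""
    validate_pooled_variants(table)
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        table.loc[:, list(VARIANT_COLUMNS)].to_csv(path, sep="\t", index=False)
    elif fmt == "vcf":
        _write_variants_vcf(table, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_candidates(result, path) -> None:
    """Write a candidate list (and its audit columns) as TSV."""
    table = result.candidates if hasattr(result, "candidates") else result
    table.to_csv(path, sep="\t", index=False)


def to_json(obj, path=None):
    """Serialize dataclass results (gate reports, estimates) to JSON."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"cannot serialize {type(o)}")

    text = json.dumps(obj, default=default, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
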