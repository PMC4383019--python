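"""Packaged cohort fixtures, the driver-gene recurrence filter and reporting.

Two fixtures ship with the package under ``papevo/data`` with a SHA-256
manifest:

* ``table1`` — per-sample clinicopathological and summary mutation data for
  the 31-tumour discovery cohort (SNV counts, dN/dS, Ts:Tv, arm-level
  chromosomal gain/deletion strings, total change counts).  Two samples with
  highly complex genomes carry the sentinel 'Complex' and are excluded from
  arm-count arithmetic; the 23 samples P01–P23 form the SNP-array subset used
  for cohort SCNA accounting.
* ``table2`` — the 50 putative somatic driver mutations (chrom, position,
  alleles, mutation class, sample, gene, DNA and protein change).

Two of the 31 rows of table 1 print a total-change count that differs by one
from the number of listed gain/deletion strings; validation records these as
``discrepancies`` (the printed totals are authoritative for cohort
accounting) rather than failing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CohortFixture",
    "load_cohort_fixture",
    "snp_array_samples",
    "parse_scna_strings",
    "table1_scna_summary",
    "recurrent_gene_filter",
    "cohort_report",
]

SCHEMA_VERSION = "1.0"
COMPLEX = "Complex"
#: the SNP-array genotyped subset (23 tumours)
SNP_ARRAY_IDS = tuple(f"P{i:02d}" for i in range(1, 24))


class CorruptFixtureError(RuntimeError):
    """A packaged fixture does not match its manifest checksum."""


@dataclass
class CohortFixture:
    name: str
    data: pd.DataFrame
    discrepancies: list = field(default_factory=list)


def _fixture_bytes(filename: str) -> bytes:
    return (resources.files("papevo") / "data" / filename).read_bytes()


def _check_manifest(filename: str, raw: bytes) -> None:
    manifest = json.loads(_fixture_bytes("manifest.json"))
    expected = manifest.get(filename)
    digest = hashlib.sha256(raw).hexdigest()
    if expected is None or digest != expected:
        raise CorruptFixtureError(
            f"fixture {filename} checksum mismatch: {digest} != {expected}"
        )


def load_cohort_fixture(name: str) -> CohortFixture:
    """Load and validate a packaged fixture ('table1' or 'table2')."""
    if name not in ("table1", "table2"):
        raise ValueError(f"unknown fixture {name!r}")
    filename = f"{name}.tsv"
    raw = _fixture_bytes(filename)
    _check_manifest(filename, raw)
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", dtype=str, keep_default_na=False)
    discrepancies = []
    if name == "table1":
        for col in ("age", "snv_count"):
            df[col] = df[col].astype(int)
        for col in ("coverage_gt30x", "dn_ds", "ts_tv"):
            df[col] = df[col].astype(float)
        for row in df.itertuples():
            if row.total_changes == COMPLEX:
                continue
            gains = parse_scna_strings(row.gains)
            dels = parse_scna_strings(row.deletions)
            if int(row.total_changes) != len(gains) + len(dels):
                discrepancies.append(
                    (row.id, len(gains) + len(dels), int(row.total_changes))
                )
    else:
        df["start"] = df["start"].astype(int)
        dup = df.duplicated(subset=["sample", "gene", "dna_change"])
        if dup.any():
            raise CorruptFixtureError("table2 rows not unique on (sample, gene, DNA change)")
    return CohortFixture(name=name, data=df, discrepancies=discrepancies)


def snp_array_samples(table1: pd.DataFrame) -> pd.DataFrame:
    """The 23-tumour SNP-array subset (samples P01–P23)."""
    return table1[table1["id"].isin(SNP_ARRAY_IDS)]


def parse_scna_strings(cell: str) -> list:
    """Split a Table-1 gain/deletion cell into arm labels.

    Empty cells ('—' in print) mean no events; 'NA' means data not obtained;
    'Complex' is the complex-genome sentinel — all three yield [].
    """
    if cell in ("", "NA", COMPLEX):
        return []
    return [s.strip() for s in cell.split(",") if s.strip()]


def _involves(label: str, query: str) -> bool:
    chrom = label.rstrip("pq")
    if query.endswith(("p", "q")):
        return label == query or (label == query.rstrip("pq"))
    return chrom == query


def table1_scna_summary(table1: pd.DataFrame) -> dict:
    """Cohort SCNA accounting over the SNP-array subset.

    Totals, median and range come from the printed total-changes column
    (authoritative); per-arm recurrence counts samples whose gain/deletion
    strings involve the queried arm or chromosome (a whole-chromosome label
    involves both arms).  Complex-genome samples contribute no events.
    """
    sub = snp_array_samples(table1)
    totals = [int(t) for t in sub["total_changes"] if t != COMPLEX]
    gains = {r.id: parse_scna_strings(r.gains) for r in sub.itertuples()}
    dels = {r.id: parse_scna_strings(r.deletions) for r in sub.itertuples()}

    queries = set()
    for labels in list(gains.values()) + list(dels.values()):
        for lab in labels:
            chrom = lab.rstrip("pq")
            queries.add(chrom)
            if lab != chrom:
                queries.add(lab)
    recurrence = {}
    for q in sorted(queries):
        n_gain = sum(1 for labs in gains.values() if any(_involves(l, q) for l in labs))
        n_del = sum(1 for labs in dels.values() if any(_involves(l, q) for l in labs))
        if n_gain:
            recurrence[f"{q}:gain"] = n_gain
        if n_del:
            recurrence[f"{q}:loss"] = n_del
    n_gain_events = sum(len(v) for v in gains.values())
    n_del_events = sum(len(v) for v in dels.values())
    return {
        "n_samples": len(sub),
        "n_with_large_scna": sum(1 for t in totals if t > 0)
        + sum(1 for t in sub["total_changes"] if t == COMPLEX),
        "total_changes": int(np.sum(totals)),
        "median_per_genome": float(np.median(totals)),
        "min_per_genome": int(np.min(totals)),
        "max_per_genome": int(np.max(totals)),
        "n_gain_events": n_gain_events,
        "n_deletion_events": n_del_events,
        "gain_loss_ratio": n_gain_events / n_del_events if n_del_events else None,
        "recurrence": recurrence,
    }


def recurrent_gene_filter(mutations: pd.DataFrame, min_cancers: int = 3) -> pd.DataFrame:
    """Genes somatically mutated in at least ``min_cancers`` distinct samples.

    ``mutations`` needs 'gene' and 'sample' columns (table2-like).  Returns a
    gene-indexed frame with n_samples and the sorted sample list, restricted
    to genes meeting the threshold.
    """
    g = mutations.groupby("gene")["sample"].agg(lambda s: sorted(set(s)))
    out = pd.DataFrame({"samples": g})
    out["n_samples"] = out["samples"].map(len)
    out = out[out["n_samples"] >= min_cancers].sort_index()
    return out[["n_samples", "samples"]]


def cohort_report(
    spectra: pd.DataFrame | None = None,
    scna_summary: dict | None = None,
    clonality: dict | None = None,
    phylogeny: dict | None = None,
    driver_genes: pd.DataFrame | None = None,
) -> dict:
    """Aggregate stage outputs into one versioned JSON-ready report."""
    report = {"schema_version": SCHEMA_VERSION, "sections": {}}
    if spectra is not None:
        report["sections"]["spectra"] = spectra.to_dict(orient="records")
    if scna_summary is not None:
        report["sections"]["scna"] = scna_summary
    if clonality is not None:
        report["sections"]["clonality"] = clonality
    if phylogeny is not None:
        report["sections"]["phylogeny"] = phylogeny
    if driver_genes is not None:
        report["sections"]["driver_genes"] = {
            gene: row["samples"] for gene, row in driver_genes.iterrows()
        }
    return report
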