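"""Readers and writers for the pipeline's tabular and VCF interchange formats.

Read-count tables and probe tables are plain TSV; ground truth is JSON;
scenario configs are YAML.  Simulated SNVs can be exported as VCF v4.2 with
one sample column per tumour region (GT:AD:DP), via pysam.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

READCOUNT_COLUMNS = ["mutation_id", "chrom", "pos", "ref", "alt", "region",
                     "depth", "alt_count"]
PROBE_COLUMNS = ["probe_id", "chrom", "pos", "region", "logR", "BAF",
                 "is_het_germline"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "logR", "q"]


def write_readcounts(df: pd.DataFrame, path) -> None:
    df[READCOUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_readcounts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(READCOUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read-count table missing columns {sorted(missing)}")
    return df


def write_probes(df: pd.DataFrame, path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns {sorted(missing)}")
    df["is_het_germline"] = df["is_het_germline"].astype(bool)
    return df


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_segments(profiles: dict, path) -> None:
    """SEG-style TSV for a dict of region -> SegmentProfile."""
    rows = []
    for region, profile in profiles.items():
        for s in profile.segments.itertuples():
            rows.append((region, s.chrom, s.start, s.end, s.n_probes,
                         round(s.logR, 6), getattr(s, "q", "")))
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def export_vcf(counts: pd.DataFrame, path) -> None:
    """Write a long-format read-count table as a multi-sample VCF v4.2.

    One sample column per region; FORMAT GT:AD:DP with AD as ref,alt depths.
    Genotypes are ./. (somatic calls carry no germline genotype).
    """
    import pysam

    regions = sorted(counts["region"].unique())
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for chrom in pd.unique(counts["chrom"]):
        header.contigs.add(str(chrom))
    for region in regions:
        header.add_sample(str(region))

    wide = counts.pivot_table(
        index=["mutation_id", "chrom", "pos", "ref", "alt"],
        columns="region",
        values=["depth", "alt_count"],
        aggfunc="first",
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        order = counts.drop_duplicates("mutation_id").sort_values(["chrom", "pos"])
        for row in order.itertuples():
            key = (row.mutation_id, row.chrom, row.pos, row.ref, row.alt)
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
                id=str(row.mutation_id),
            )
            for region in regions:
                dp = wide.loc[key, ("depth", region)]
                ad = wide.loc[key, ("alt_count", region)]
                sample = rec.samples[str(region)]
                sample["GT"] = (None, None)
                if not (pd.isna(dp) or pd.isna(ad)):
                    sample["AD"] = (int(dp) - int(ad), int(ad))
                    sample["DP"] = int(dp)
            vcf.write(rec)


def read_vcf_readcounts(path) -> pd.DataFrame:
    """Read a multi-sample VCF with AD/DP back into the long table format."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for region, sample in rec.samples.items():
                dp = sample.get("DP")
                ad = sample.get("AD")
                if dp is None or ad is None or ad[1] is None:
                    continue
                rows.append(
                    (rec.id or f"{rec.contig}:{rec.pos}", rec.contig, rec.pos,
                     rec.ref, rec.alts[0], region, int(dp), int(ad[1]))
                )
    return pd.DataFrame(rows, columns=READCOUNT_COLUMNS)
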