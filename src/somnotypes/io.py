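"""Readers and writers for the pipeline's text formats.

Summary statistics are tab-delimited with header SNP, CHR, POS, EA, OA, EAF,
BETA, SE, P (1-based positions).  Genotype dosages travel either as a wide
CSV (rows = individuals keyed by person_id, columns = variant IDs) or as a
VCF with a DS FORMAT field.  Accelerometer traces are CSV epoch series with
ISO-8601 timestamps and either a native z_angle_deg column or raw ax/ay/az.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .actigraphy import AccelEpochSeries, z_angle_from_triaxial
from .simulate import Z_COLUMNS

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_dosage_vcf",
    "write_dosage_vcf",
    "read_trace_csv",
    "write_trace_csv",
    "read_z_matrix",
    "write_z_matrix",
]

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]


def read_summary_stats(path) -> pd.DataFrame:
    """Read a tab-delimited GWAS summary-statistics table, indexed by SNP."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "EA": str, "OA": str})
    missing = {"SNP", "EA", "OA", "BETA", "SE"} - set(df.columns)
    if missing:
        raise ValueError(f"summary stats missing columns: {sorted(missing)}")
    return df.set_index("SNP")


def write_summary_stats(df: pd.DataFrame, path) -> None:
    out = df.reset_index() if df.index.name == "SNP" else df
    out.to_csv(path, sep="\t", index=False)


def read_dosage_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="person_id")


def write_dosage_csv(dosages: pd.DataFrame, path) -> None:
    dosages.to_csv(path, index_label="person_id")


def read_dosage_vcf(path) -> pd.DataFrame:
    """Effect-allele dosages (DS field, ALT-coded) from a VCF, person x variant."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            gts = np.array([sum(g[:2]) for g in var.genotypes], dtype=float)
        else:
            gts = np.asarray(ds, dtype=float).reshape(-1)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(gts)
    return pd.DataFrame(np.column_stack(cols) if cols else [],
                        index=pd.Index(samples, name="person_id"),
                        columns=ids)


def write_dosage_vcf(dosages: pd.DataFrame, path,
                     variants: pd.DataFrame | None = None) -> None:
    """Write dosages as a minimal VCFv4.2 with a DS FORMAT field.

    ``variants`` may supply CHR/POS/EA/OA per variant ID (EA is written as
    ALT, the dosage-counted allele); otherwise placeholders are used.
    """
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, vid in enumerate(dosages.columns):
            if variants is not None and vid in variants.index:
                v = variants.loc[vid]
                chrom, pos = v.get("CHR", 1), v.get("POS", j + 1)
                ref, alt = v.get("OA", "A"), v.get("EA", "G")
            else:
                chrom, pos, ref, alt = 1, j + 1, "A", "G"
            ds = "\t".join(f"{x:g}" for x in dosages[vid].to_numpy())
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tDS\t{ds}\n")


def read_trace_csv(path, person_id: str | None = None) -> AccelEpochSeries:
    """Read an accelerometer epoch series from CSV.

    Requires a ``timestamp`` column plus either ``z_angle_deg`` or raw
    ``ax, ay, az`` (converted to the z-angle), and ``activity``.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    ts = df["timestamp"]
    steps = ts.diff().dropna().dt.total_seconds()
    if steps.empty or steps.nunique() > 1:
        raise ValueError("trace must be uniformly sampled")
    if "z_angle_deg" in df:
        z = df["z_angle_deg"].to_numpy(dtype=float)
    elif {"ax", "ay", "az"} <= set(df.columns):
        z = z_angle_from_triaxial(df["ax"], df["ay"], df["az"])
    else:
        raise ValueError("need z_angle_deg or ax/ay/az columns")
    return AccelEpochSeries(
        person_id=person_id or str(path),
        epoch_seconds=float(steps.iloc[0]),
        start_time=ts.iloc[0],
        z_angle=z,
        activity=df["activity"].to_numpy(dtype=float),
    )


def write_trace_csv(trace: AccelEpochSeries, path) -> None:
    ts = trace.start_time + pd.to_timedelta(
        np.arange(trace.n_epochs) * trace.epoch_seconds, unit="s")
    pd.DataFrame({
        "timestamp": ts,
        "z_angle_deg": trace.z_angle,
        "activity": trace.activity,
    }).to_csv(path, index=False)


def read_z_matrix(path) -> pd.DataFrame:
    """Read a locus x trait z-score table (tab-delimited).

    Expects a ``locus`` column plus the four z-score columns in the fixed
    trait order (efficiency, duration, bouts, insomnia).
    """
    df = pd.read_csv(path, sep="\t").set_index("locus")
    missing = set(Z_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"z-matrix missing columns: {sorted(missing)}")
    return df[Z_COLUMNS].astype(float)


def write_z_matrix(z: pd.DataFrame, path) -> None:
    z.rename_axis("locus").reset_index().to_csv(path, sep="\t", index=False)
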