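"""Readers and writers for the package's tabular and JSON formats.

All tables are TSV with a header row; posteriors travel as JSON.  The
mutation dialect has columns tumor_id, chrom_arm, pos, ref, alt, alt_count,
ref_count, context (plus optional driver/truth columns); segments are
SEG-style (tumor_id, chrom_arm, start, end, major_cn, minor_cn); metadata
holds tumor_id, purity, age, hpv_status, site.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .timing import PatientTiming

MUTATION_COLUMNS = ["tumor_id", "chrom_arm", "pos", "ref", "alt",
                    "alt_count", "ref_count", "context"]
SEGMENT_COLUMNS = ["tumor_id", "chrom_arm", "start", "end",
                   "major_cn", "minor_cn"]
METADATA_COLUMNS = ["tumor_id", "purity", "age", "hpv_status", "site"]


def _read_tsv(path, required):
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_mutations(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, MUTATION_COLUMNS)


def read_segments(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, SEGMENT_COLUMNS)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, METADATA_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_vcf_mutations(path: str | Path, tumor_id: str = "tumor",
                       ) -> pd.DataFrame:
    """Minimal VCF adapter: maps the first sample's AD field to
    ref/alt counts.  CHROM is taken as the arm label."""
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                continue
            f = line.rstrip("\n").split("\t")
            fmt = f[8].split(":")
            sample = f[9].split(":")
            ad = sample[fmt.index("AD")].split(",")
            rows.append({"tumor_id": tumor_id, "chrom_arm": f[0],
                         "pos": int(f[1]) - 1, "ref": f[3], "alt": f[4],
                         "ref_count": int(ad[0]), "alt_count": int(ad[1]),
                         "context": "other"})
    if header is None:
        raise ValueError(f"{path}: no VCF header line")
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def write_timing_json(timings: list[PatientTiming], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = [t.to_dict() for t in timings]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_timing_json(path: str | Path) -> list[PatientTiming]:
    payload = json.loads(Path(path).read_text())
    return [PatientTiming.from_dict(d) for d in payload]
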