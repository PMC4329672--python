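"""File formats and run configuration.

All coordinates in files and reports are 1-based inclusive; the 0-based
internal representation is crossed only here and in the report writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exondef import GapSurprisalModel
from .infomodel import InfoModel, read_model, write_model  # re-exported
from .variants import VariantRecord, NaturalSite

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_model",
    "write_model",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_vcf",
    "read_exon_table",
    "read_natural_sites",
    "write_natural_sites",
    "read_distribution",
    "write_distribution",
    "RunConfig",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_training_sequences(path) -> list[str]:
    """Aligned training sites: FASTA if the file starts with '>', otherwise
    one sequence per line."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return [line.strip() for line in text.splitlines() if line.strip()]


def read_variants_tsv(path) -> list[VariantRecord]:
    """Simple variant table: seq_id, pos (1-based), ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"seq_id", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"variant TSV must have columns {sorted(required)}")
    return [
        VariantRecord(row["seq_id"], int(row["pos"]), row["ref"], row["alt"])
        for _, row in df.iterrows()
    ]


def write_variants_tsv(variants: list[VariantRecord], path) -> None:
    pd.DataFrame(
        [
            {"seq_id": v.seq_id, "pos": v.position, "ref": v.ref_allele, "alt": v.alt_allele}
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def read_vcf(path) -> list[VariantRecord]:
    """Minimal VCF v4 reader (CHROM, POS, REF, ALT); multi-allelic rows are
    split into one record per ALT allele."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(
                        seq_id=rec.chrom,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        notation_source="genomic",
                        original_text=f"{rec.chrom}:{rec.pos}{rec.ref}>{alt}",
                    )
                )
    return out


def read_exon_table(path) -> pd.DataFrame:
    """Exon table TSV: exon index, genomic start, genomic end (1-based), strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"exon", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"exon table must have columns {sorted(required)}")
    if "strand" in df.columns and (df["strand"] != "+").any():
        raise ValueError("only plus-strand exon tables are supported")
    return df.sort_values("exon").reset_index(drop=True)


def read_natural_sites(path) -> list[NaturalSite]:
    """Annotated natural sites: seq_id, site_kind, coordinate (1-based), strand."""
    df = pd.read_csv(path, sep="\t")
    return [
        NaturalSite(
            site_kind=row["site_kind"],
            zero_coord=int(row["coordinate"]) - 1,
            strand=row.get("strand", "+"),
            name=str(row.get("name", "")),
        )
        for _, row in df.iterrows()
    ]


def write_natural_sites(sites: list[NaturalSite], path, seq_id: str = "") -> None:
    pd.DataFrame(
        [
            {
                "seq_id": seq_id,
                "site_kind": s.site_kind,
                "coordinate": s.zero_coord + 1,
                "strand": s.strand,
                "name": s.name,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_distribution(path, kind: str = "exon_length") -> GapSurprisalModel:
    """Two-column TSV (upper bin edge, probability); must sum to 1."""
    df = pd.read_csv(path, sep="\t")
    return GapSurprisalModel.from_table(df, kind=kind)


def write_distribution(model: GapSurprisalModel, path) -> None:
    model.to_table().to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Analysis thresholds; defaults follow the tool conventions documented
    in each module."""

    model_paths: list[str] = field(default_factory=list)
    r_i_min: float = 1.6  # 2.4 for the legacy curated models
    significance_bits: float = 1.0
    window_nt: int = 54
    skip_threshold_bits: float = 7.0
    bps_search_nt: int = 100
    bps_hard_max_nt: int = 400
    distance_cutoff: int = 400
    strand_policy: str = "annotated"  # or 'both'
    seed: int = 0
    output_format: str = "tsv"  # or 'json'

    def __post_init__(self) -> None:
        for name in ("r_i_min", "significance_bits", "skip_threshold_bits"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.window_nt < 1:
            raise ValueError("window_nt must be positive")
        if self.strand_policy not in ("annotated", "both"):
            raise ValueError("strand_policy must be 'annotated' or 'both'")
        if self.output_format not in ("tsv", "json"):
            raise ValueError("output_format must be 'tsv' or 'json'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def validate_models(self, models) -> None:
        max_len = max((m.length for m in models), default=0)
        if self.window_nt < max_len:
            raise ValueError(
                f"window_nt ({self.window_nt}) smaller than the largest model "
                f"window ({max_len} nt); refusing to truncate the analysis window"
            )
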