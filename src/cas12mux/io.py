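"""Readers and writers: FASTA/FASTQ, target manifests, tabular reports.

Manifest format (TSV with header, or a JSON list of objects) — columns:

    gene_id  amplicon_id  spacer  pam  strand  offset  [spacer_len]

``offset`` is the 0-based start of the PAM on the protospacer strand: for a
plus-strand site it counts on the amplicon as given; for a minus-strand site
it counts on the reverse complement of the amplicon. The spacer begins
immediately after the PAM.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    Allele,
    AlleleCall,
    Cas12muxError,
    GeneZygosity,
    GerminationRecord,
    GerminationType,
    InputError,
    ManifestError,
    PlantGenotype,
    TargetSite,
    Zygosity,
    minus_to_plus_interval,
)

__all__ = [
    "read_sequences",
    "read_fasta_dict",
    "parse_target_manifest",
    "write_target_manifest",
    "write_genotype_table",
    "read_genotype_table",
    "write_germination_table",
    "read_germination_table",
    "write_fastq",
]


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(
    path: Union[str, Path], format: str = None
) -> Iterator[Tuple[str, str, Optional[str]]]:
    """Stream ``(id, sequence, quality)`` records from FASTA/FASTQ, plain or gzip.

    Sequences are uppercased; record order is preserved; ``quality`` is None
    for FASTA. The format is inferred from the file name when not given.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        if stem.endswith((".fq", ".fastq")):
            format = "fastq"
        elif stem.endswith((".fa", ".fasta", ".fna")):
            format = "fasta"
        else:
            raise InputError(f"cannot infer sequence format of {path.name}")
    if format not in ("fasta", "fastq"):
        raise InputError(f"unsupported format {format!r}")
    with _open_text(path) as fh:
        index = 0
        try:
            for rec in SeqIO.parse(fh, format):
                qual = None
                if format == "fastq":
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                yield rec.id, str(rec.seq).upper(), qual
                index += 1
        except ValueError as exc:  # Biopython parse failure
            raise InputError(f"malformed {format} record at index {index}: {exc}") from exc


def read_fasta_dict(path: Union[str, Path]) -> Dict[str, str]:
    return {name: seq for name, seq, _ in read_sequences(path, "fasta")}


def write_fastq(path: Union[str, Path], reads: Iterable[Tuple[str, str]], qual_char: str = "I") -> None:
    """Write ``(id, seq)`` pairs as FASTQ with a flat quality string."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


# --------------------------------------------------------------------------
# target manifest

_MANIFEST_COLS = ["gene_id", "amplicon_id", "spacer", "pam", "strand", "offset"]


def parse_target_manifest(
    path: Union[str, Path],
    amplicons: Union[Dict[str, str], str, Path],
    window_pad: int = 10,
    pam_pattern: str = "TTTV",
) -> List[TargetSite]:
    """Parse and validate a TSV/JSON target manifest against its amplicons.

    Every returned :class:`TargetSite` is validated by exact string search:
    the declared spacer and PAM must be found at the declared offset.
    """
    if not isinstance(amplicons, dict):
        amplicons = read_fasta_dict(amplicons)
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _MANIFEST_COLS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        rows = df.to_dict("records")

    sites: List[TargetSite] = []
    seen = set()
    for row in rows:
        gene = str(row["gene_id"])
        if gene in seen:
            raise ManifestError(f"duplicate gene_id {gene!r} in manifest")
        seen.add(gene)
        amp_id = str(row["amplicon_id"])
        if amp_id not in amplicons:
            raise ManifestError(f"{gene}: amplicon {amp_id!r} not found in references")
        amp = amplicons[amp_id].upper()
        spacer = str(row["spacer"]).upper()
        pam = str(row["pam"]).upper()
        strand = str(row["strand"])
        offset = int(row["offset"])
        plen, slen = len(pam), len(spacer)
        # offset counts on the protospacer strand; convert to plus coordinates
        if strand == "+":
            interval = (offset + plen, offset + plen + slen)
        elif strand == "-":
            interval = minus_to_plus_interval(offset + plen, offset + plen + slen, len(amp))
        else:
            raise ManifestError(f"{gene}: strand must be '+' or '-', got {strand!r}")
        try:
            site = TargetSite(
                gene_id=gene,
                amplicon_id=amp_id,
                amplicon_seq=amp,
                pam_seq=pam,
                spacer_seq=spacer,
                strand=strand,
                spacer_interval=interval,
                window_pad=window_pad,
                pam_pattern=pam_pattern,
            )
        except ManifestError as exc:
            raise ManifestError(f"manifest row for {gene} (offset {offset}): {exc}") from exc
        sites.append(site)
    return sites


def write_target_manifest(sites: Sequence[TargetSite], path: Union[str, Path]) -> None:
    rows = []
    for s in sites:
        st, en = s.spacer_interval
        plen = len(s.pam_seq)
        if s.strand == "+":
            offset = st - plen
        else:
            offset = len(s.amplicon_seq) - en - plen
        rows.append(
            dict(gene_id=s.gene_id, amplicon_id=s.amplicon_id, spacer=s.spacer_seq,
                 pam=s.pam_seq, strand=s.strand, offset=offset)
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# genotype tables

_GENO_COLS = [
    "plant_id", "gene_id", "zygosity_class", "alleles", "fractions",
    "read_counts", "wt_fraction", "is_sextuple_no_wt", "is_full_lof",
    "predicted_type3", "unresolved", "germination_type",
]


def write_genotype_table(plants: Sequence[PlantGenotype], path: Union[str, Path]) -> None:
    """One row per plant x gene; deterministic column order; round-trips
    through :func:`read_genotype_table`."""
    rows = []
    for p in plants:
        for gene_id, call in p.gene_calls.items():
            row = dict(
                plant_id=p.plant_id,
                gene_id=gene_id,
                zygosity_class=call.zygosity_class.value if call else "no-call",
                alleles="|".join(c.allele.key() for c in call.allele_calls) if call else "",
                fractions="|".join(f"{c.fraction:.6g}" for c in call.allele_calls) if call else "",
                read_counts="|".join(str(c.read_count) for c in call.allele_calls) if call else "",
                wt_fraction=f"{call.wt_fraction:.6g}" if call else "",
                is_sextuple_no_wt=p.is_sextuple_no_wt,
                is_full_lof=p.is_full_lof,
                predicted_type3=p.predicted_type3,
                unresolved=p.unresolved,
                germination_type=p.germination_type.value if p.germination_type else "",
            )
            rows.append(row)
    pd.DataFrame(rows, columns=_GENO_COLS).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: Union[str, Path]) -> List[PlantGenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    plants: Dict[str, PlantGenotype] = {}
    for _, row in df.iterrows():
        pid = row["plant_id"]
        if pid not in plants:
            gt = row["germination_type"]
            plants[pid] = PlantGenotype(
                plant_id=pid,
                gene_calls={},
                is_sextuple_no_wt=row["is_sextuple_no_wt"] == "True",
                is_full_lof=row["is_full_lof"] == "True",
                predicted_type3=row["predicted_type3"] == "True",
                germination_type=GerminationType(gt) if gt else None,
                unresolved=row["unresolved"] == "True",
            )
        if row["zygosity_class"] == "no-call":
            call = None
        else:
            keys = row["alleles"].split("|") if row["alleles"] else []
            fracs = [float(x) for x in row["fractions"].split("|")] if row["fractions"] else []
            counts = [int(x) for x in row["read_counts"].split("|")] if row["read_counts"] else []
            calls = tuple(
                AlleleCall(Allele.from_key(k), n, f)
                for k, n, f in zip(keys, counts, fracs)
            )
            call = GeneZygosity(
                gene_id=row["gene_id"],
                zygosity_class=Zygosity(row["zygosity_class"]),
                allele_calls=calls,
                wt_fraction=float(row["wt_fraction"]) if row["wt_fraction"] else 0.0,
            )
        plants[pid].gene_calls[row["gene_id"]] = call  # type: ignore[index]
    return list(plants.values())


# --------------------------------------------------------------------------
# germination tables

_GERM_COLS = ["plant_id", "germinated", "day_of_germination", "stunted", "observation_horizon"]


def write_germination_table(records: Sequence[GerminationRecord], path: Union[str, Path]) -> None:
    rows = [
        dict(
            plant_id=r.plant_id,
            germinated=r.germinated,
            day_of_germination="" if r.day_of_germination is None else r.day_of_germination,
            stunted=r.stunted,
            observation_horizon=r.observation_horizon,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_GERM_COLS).to_csv(path, sep="\t", index=False)


def read_germination_table(path: Union[str, Path]) -> List[GerminationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        day = row["day_of_germination"]
        out.append(
            GerminationRecord(
                plant_id=row["plant_id"],
                germinated=row["germinated"] == "True",
                day_of_germination=int(float(day)) if day else None,
                stunted=row["stunted"] == "True",
                observation_horizon=int(row["observation_horizon"]),
            )
        )
    return out
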