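"""FASTA input and BED/TSV/JSON output for the annotation pipeline."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .decompose import Block, MonomerTemplate
from .hors import Annotation
from .pipeline import PipelineResult, RunConfig

__all__ = [
    "read_fasta_record",
    "read_template",
    "write_block_bed",
    "write_hor_bed",
    "write_hor_summary",
    "write_run_metadata",
    "write_report",
]


def read_fasta_record(path: str | Path) -> tuple[str, str]:
    """(name, sequence) of the first record; warns if the file has more."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} has {len(records)} records; using the first", stacklevel=2
        )
    r = records[0]
    return r.id, str(r.seq).upper()


def read_template(path: str | Path) -> MonomerTemplate:
    name, seq = read_fasta_record(path)
    return MonomerTemplate(name=name, sequence=seq)


def write_block_bed(
    path: str | Path, chrom: str, blocks: list[Block], monomer_ids=None
) -> None:
    """BED4: chrom, start, end, name (block index, or block_index:monomer_id)."""
    with open(path, "w") as fh:
        for b in blocks:
            name = str(b.index)
            if monomer_ids is not None:
                name = f"{b.index}:{monomer_ids[b.index]}"
            fh.write(f"{chrom}\t{b.start}\t{b.end}\t{name}\n")


def write_hor_bed(path: str | Path, chrom: str, intervals) -> None:
    """BED-like per-instance file: chrom, start, end, HOR name, expanded pattern."""
    with open(path, "w") as fh:
        for start, end, name, pattern in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{pattern}\n")


def write_hor_summary(path: str | Path, annotation: Annotation) -> None:
    rows = [
        {
            "name": h.name,
            "canonical_pattern": "_".join(map(str, h.canonical_pattern)),
            "unit_len": h.unit_len,
            "rn": h.rn,
            "hor_len": h.hor_len,
            "cr": h.cr,
            "pr": h.pr,
            "score": h.score,
            "n_instances": len(h.instances),
        }
        for h in annotation.hors
    ]
    pd.DataFrame(
        rows,
        columns=[
            "name",
            "canonical_pattern",
            "unit_len",
            "rn",
            "hor_len",
            "cr",
            "pr",
            "score",
            "n_instances",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_run_metadata(
    path: str | Path, config: RunConfig, result: PipelineResult
) -> None:
    ann = result.annotation
    meta = {
        "min_similarity": config.min_similarity,
        "step": config.step,
        "max_unit_len": config.max_unit_len,
        "seed": config.seed,
        "selected_threshold": ann.threshold,
        "monomer_count": ann.monomer_count,
        "n_blocks": len(result.blocks),
        "coverage": ann.coverage,
        "breakpoints": ann.breakpoints,
        "sweep": [
            {
                "threshold": a.threshold,
                "monomer_count": a.monomer_count,
                "coverage": a.coverage,
            }
            for a in result.sweep
        ],
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def write_report(path: str | Path, annotation: Annotation) -> None:
    """Human-readable summary: the top five HORs with repeat number > 10."""
    top = [h for h in annotation.hors if h.rn > 10][:5]
    with open(path, "w") as fh:
        fh.write(
            f"threshold={annotation.threshold}\t"
            f"monomers={annotation.monomer_count}\t"
            f"coverage={annotation.coverage:.4f}\n"
        )
        if not top:
            fh.write("no HOR with repeat number > 10\n")
        for h in top:
            fh.write(
                f"{h.name}\tpattern={'_'.join(map(str, h.canonical_pattern))}\t"
                f"rn={h.rn}\tscore={h.score:.4f}\n"
            )
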