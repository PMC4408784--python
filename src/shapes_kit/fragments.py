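"""Fragment records and their I/O.

A *fragment* is one reverse-transcription product mapped back to its RNA:
the left end is the cDNA termination position (one nucleotide 3' of the
blocking adduct, or position 1 for a run-off that reached the RNA 5' end)
and the right end is the priming position. Internally all coordinates are
1-based inclusive on the RNA; BED I/O converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: cause labels attached by the simulator
CAUSES = ("modification", "dropoff", "runoff")


@dataclass(frozen=True, order=True)
class FragmentRecord:
    """One cDNA fragment in 1-based inclusive RNA coordinates.

    ``left`` is the termination end (last reverse-transcribed nucleotide),
    ``right`` the priming end; ``cause`` is only set by the simulator.
    """

    rna_id: str
    left: int
    right: int
    cause: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.left <= self.right):
            raise DataError(
                f"invalid fragment {self.rna_id}:{self.left}-{self.right}: "
                "require 1 <= left <= right"
            )

    @property
    def length(self) -> int:
        return self.right - self.left + 1


def _check_lengths(rec: FragmentRecord, lengths: Mapping[str, int] | None) -> None:
    if lengths is None:
        return
    if rec.rna_id not in lengths:
        raise DataError(f"unknown reference name {rec.rna_id!r}")
    if rec.right > lengths[rec.rna_id]:
        raise DataError(
            f"fragment {rec.rna_id}:{rec.left}-{rec.right} extends beyond "
            f"reference length {lengths[rec.rna_id]}"
        )


def read_bed(path: str | Path, lengths: Mapping[str, int] | None = None) -> list[FragmentRecord]:
    """Read fragments from a BED file (0-based, half-open).

    Columns beyond the first three are optional; column 4 (name), when not
    ".", is kept as the termination cause. Malformed lines are skipped with
    a warning; minus-strand records are discarded (references are
    single-stranded RNAs).
    """
    records: list[FragmentRecord] = []
    n_bad = n_minus = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError("fewer than 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start < 0 or end <= start:
                    raise ValueError("bad interval")
            except ValueError as exc:
                n_bad += 1
                logger.warning("skipping malformed BED line %d: %s (%s)", lineno, line, exc)
                continue
            if len(fields) >= 6 and fields[5] == "-":
                n_minus += 1
                logger.warning("discarding minus-strand record at line %d", lineno)
                continue
            cause = None
            if len(fields) >= 4 and fields[3] not in (".", ""):
                cause = fields[3]
            rec = FragmentRecord(chrom, start + 1, end, cause)
            _check_lengths(rec, lengths)
            records.append(rec)
    if n_bad or n_minus:
        logger.info("read_bed: %d malformed and %d minus-strand records skipped", n_bad, n_minus)
    return records


def read_sam(path: str | Path, lengths: Mapping[str, int] | None = None) -> list[FragmentRecord]:
    """Read fragments from properly paired SAM/BAM alignments.

    Each properly paired template yields one fragment spanning the outermost
    aligned bases of the pair (taken from the forward read's TLEN).
    Unmapped, secondary, supplementary and improperly paired records are
    skipped with a logged count.
    """
    import pysam

    records: list[FragmentRecord] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
                or not read.is_proper_pair
                or read.template_length <= 0
            ):
                n_skipped += 1
                continue
            left = read.reference_start + 1  # pysam is 0-based
            right = read.reference_start + read.template_length
            rec = FragmentRecord(read.reference_name, left, right)
            _check_lengths(rec, lengths)
            records.append(rec)
    if n_skipped:
        logger.info("read_sam: %d records skipped (unmapped/secondary/unpaired)", n_skipped)
    return records


def read_tsv(path: str | Path, lengths: Mapping[str, int] | None = None) -> list[FragmentRecord]:
    """Read a fragment dump written by :func:`write_fragments` (TSV)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["rna_id", "left", "right"]:
            raise DataError(f"{path}: not a fragment TSV (header {header})")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            cause = fields[3] if len(fields) > 3 and fields[3] != "." else None
            rec = FragmentRecord(fields[0], int(fields[1]), int(fields[2]), cause)
            _check_lengths(rec, lengths)
            records.append(rec)
    return records


def read_fragments(
    path: str | Path,
    format: str = "bed",
    lengths: Mapping[str, int] | None = None,
) -> list[FragmentRecord]:
    """Read fragments from ``bed``, ``sam``/``bam`` or ``tsv`` input."""
    fmt = format.lower()
    if fmt == "bed":
        return read_bed(path, lengths)
    if fmt in ("sam", "bam"):
        return read_sam(path, lengths)
    if fmt == "tsv":
        return read_tsv(path, lengths)
    raise ConfigurationError(f"unknown fragment format {format!r}")


def write_fragments(
    records: Iterable[FragmentRecord], path: str | Path, format: str = "bed"
) -> None:
    """Write fragments as BED6 (0-based half-open, name = cause, score 0,
    strand '+') or as a TSV dump (rna_id, left, right, cause)."""
    fmt = format.lower()
    with open(path, "w") as fh:
        if fmt == "bed":
            for r in records:
                name = r.cause if r.cause is not None else "."
                fh.write(f"{r.rna_id}\t{r.left - 1}\t{r.right}\t{name}\t0\t+\n")
        elif fmt == "tsv":
            fh.write("rna_id\tleft\tright\tcause\n")
            for r in records:
                fh.write(f"{r.rna_id}\t{r.left}\t{r.right}\t{r.cause or '.'}\n")
        else:
            raise ConfigurationError(f"unknown fragment format {format!r}")


def trim_untemplated(read_bases: str, ref_bases: str, max_trim: int = 3) -> int:
    """Number of leading untemplated nucleotides to trim from a fragment.

    Reverse transcriptases with terminal-transferase activity can append a
    few non-templated nucleotides to the cDNA 3' end, which after mapping
    appear as mismatches at the fragment's left (termination) end. Scanning
    from the read's 5' end, the shift is the count of contiguous bases that
    mismatch the reference, capped at ``max_trim``.
    """
    shift = 0
    for rb, xb in zip(read_bases.upper(), ref_bases.upper()):
        if shift >= max_trim or rb == xb:
            break
        shift += 1
    return shift


def apply_trim(
    record: FragmentRecord, read_bases: str, ref_bases: str, max_trim: int = 3
) -> FragmentRecord | None:
    """Shift a fragment's left end by its untemplated-nucleotide trim.

    Returns None (with a warning) when the shift would invert the fragment.
    """
    shift = trim_untemplated(read_bases, ref_bases, max_trim)
    if record.left + shift > record.right:
        logger.warning(
            "discarding fragment %s:%d-%d: trim shift %d exceeds fragment",
            record.rna_id, record.left, record.right, shift,
        )
        return None
    return replace(record, left=record.left + shift) if shift else record


def fragment_counts_by_rna(records: Sequence[FragmentRecord]) -> dict[str, int]:
    """Count fragments per reference RNA."""
    out: dict[str, int] = {}
    for r in records:
        out[r.rna_id] = out.get(r.rna_id, 0) + 1
    return out
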