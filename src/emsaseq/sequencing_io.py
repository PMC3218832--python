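"""Reading oligo-pool sequencing data and recovering degenerate regions.

Library molecules are fixed-layout oligos: a degenerate region (10 or 20
random bases) embedded between constant flanking sequences.  This module
parses FASTQ/FASTA pools, locates the flanks in each read, extracts the
degenerate window and filters unusable reads.  The downstream enrichment
model assumes a strict 4-letter alphabet, so any read whose degenerate
region contains an N is rejected rather than patched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .kmer_counting import _VALID


@dataclass(frozen=True)
class OligoDesign:
    """Fixed layout of one oligo library.

    ``flank5`` and ``flank3`` are the constant sequences surrounding the
    degenerate region; ``offset`` is the position of ``flank5`` within
    the read (0 for un-barcoded libraries).  ``max_flank_mismatch`` is a
    per-flank mismatch budget.  ``anchored`` matches the flanks at their
    fixed offsets; disabling it slides the layout along the read and
    keeps the best-matching placement (for ragged reads).
    """

    degenerate_length: int
    flank5: str
    flank3: str
    max_flank_mismatch: int = 0
    offset: int = 0
    anchored: bool = True
    min_mean_quality: float = 20.0

    def __post_init__(self):
        if self.degenerate_length <= 0:
            raise ValueError("degenerate_length must be positive")
        for name in ("flank5", "flank3"):
            flank = getattr(self, name)
            if not _VALID.issuperset(flank):
                raise ValueError(f"{name} contains non-ACGT characters: {flank!r}")

    @property
    def span(self) -> int:
        return len(self.flank5) + self.degenerate_length + len(self.flank3)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OligoDesign":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "degenerate_length": self.degenerate_length,
            "flank5": self.flank5,
            "flank3": self.flank3,
            "max_flank_mismatch": self.max_flank_mismatch,
            "offset": self.offset,
            "anchored": self.anchored,
            "min_mean_quality": self.min_mean_quality,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass
class CleanPool:
    """Accepted degenerate regions of one pool, with filtering statistics."""

    sequences: list[str]
    n_input_reads: int
    n_accepted: int
    rejections: dict[str, int] = field(default_factory=dict)

    def write_rejection_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\n")
            fh.write(f"accepted\t{self.n_accepted}\n")
            for reason in sorted(self.rejections):
                fh.write(f"{reason}\t{self.rejections[reason]}\n")


def read_pool(path: str | Path, format: str = "fastq"):
    """Parse a FASTQ/FASTA pool into a list of ``SeqRecord``.

    A malformed record raises ``ValueError`` naming the 1-based index of
    the record at which parsing failed.
    """
    if format not in ("fastq", "fasta"):
        raise ValueError(f"unsupported format {format!r}")
    records = []
    parser = SeqIO.parse(str(path), format)
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(
                f"{path}: parse error at record {len(records) + 1}: {exc}"
            ) from exc
        records.append(rec)
    return records


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extract_at(seq: str, design: OligoDesign, offset: int):
    """Try the fixed layout at ``offset``; return (region, total mismatches) or None."""
    f5, f3, dlen = design.flank5, design.flank3, design.degenerate_length
    if offset + design.span > len(seq):
        return None
    m5 = _mismatches(seq[offset : offset + len(f5)], f5)
    if m5 > design.max_flank_mismatch:
        return None
    start = offset + len(f5)
    m3 = _mismatches(seq[start + dlen : start + dlen + len(f3)], f3)
    if m3 > design.max_flank_mismatch:
        return None
    return seq[start : start + dlen], m5 + m3


def _locate_degenerate(read: str, design: OligoDesign):
    """Return (region, region start offset) or None."""
    if len(read) < design.span:
        return None
    if design.anchored:
        hit = _extract_at(read, design, design.offset)
        if hit is None:
            return None
        return hit[0], design.offset + len(design.flank5)
    best = None
    for offset in range(len(read) - design.span + 1):
        hit = _extract_at(read, design, offset)
        if hit is not None and (best is None or hit[1] < best[1]):
            best = (hit[0], offset + len(design.flank5), hit[1])
    return best[:2] if best is not None else None


def extract_degenerate(read: str, design: OligoDesign) -> str | None:
    """Extract the degenerate window between matched flanks, or ``None``.

    Rejection is a return state, not an error; callers count rejects.
    """
    hit = _locate_degenerate(read.upper(), design)
    return hit[0] if hit is not None else None


def clean_pool_file(
    path: str | Path, format: str, design: OligoDesign
) -> CleanPool:
    """Stream a pool file through extraction and filtering.

    Equivalent to ``clean_pool(read_pool(path, format), design)`` but
    without materializing per-record objects, which matters for
    multi-million-read pools.
    """
    if format == "fastq":
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        with open(path) as fh:
            records = (
                (seq, qual) for _title, seq, qual in FastqGeneralIterator(fh)
            )
            return _clean_stream(records, design)
    if format == "fasta":
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        with open(path) as fh:
            records = ((seq, None) for _title, seq in SimpleFastaParser(fh))
            return _clean_stream(records, design)
    raise ValueError(f"unsupported format {format!r}")


def _clean_stream(records, design: OligoDesign) -> CleanPool:
    accepted: list[str] = []
    rejections = {"flank_mismatch": 0, "contains_N": 0, "low_quality": 0}
    n_input = 0
    for seq, qual in records:
        n_input += 1
        seq = seq.upper()
        hit = _locate_degenerate(seq, design)
        if hit is None:
            rejections["flank_mismatch"] += 1
            continue
        region, start = hit
        if not _VALID.issuperset(region):
            rejections["contains_N"] += 1
            continue
        if qual is not None:
            window = qual[start : start + design.degenerate_length].encode("ascii")
            if (sum(window) / len(window)) - 33.0 < design.min_mean_quality:
                rejections["low_quality"] += 1
                continue
        accepted.append(region)
    return CleanPool(
        sequences=accepted,
        n_input_reads=n_input,
        n_accepted=len(accepted),
        rejections={k: v for k, v in rejections.items() if v},
    )


def clean_pool(records, design: OligoDesign) -> CleanPool:
    """Extract and filter all reads of a pool.

    Filters applied in order: flank match (anchored or sliding), N-free
    degenerate region, and — for FASTQ records carrying qualities —
    mean Phred over the degenerate region at least
    ``design.min_mean_quality``.
    """
    accepted: list[str] = []
    rejections = {"flank_mismatch": 0, "contains_N": 0, "low_quality": 0}
    n_input = 0
    for rec in records:
        n_input += 1
        seq = str(rec.seq).upper()
        hit = _locate_degenerate(seq, design)
        if hit is None:
            rejections["flank_mismatch"] += 1
            continue
        region, start = hit
        if not _VALID.issuperset(region):
            rejections["contains_N"] += 1
            continue
        quals = rec.letter_annotations.get("phred_quality")
        if quals is not None:
            window = quals[start : start + design.degenerate_length]
            if sum(window) / len(window) < design.min_mean_quality:
                rejections["low_quality"] += 1
                continue
        accepted.append(region)
    return CleanPool(
        sequences=accepted,
        n_input_reads=n_input,
        n_accepted=len(accepted),
        rejections={k: v for k, v in rejections.items() if v},
    )
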