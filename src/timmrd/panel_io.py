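"""Domain types and text I/O for targeted bisulfite methylation panels.

A panel is a set of genomic *blocks* (clusters of neighbouring CpG sites).
For every plasma or tissue sample the assay reports, per block, the total
number of CpG observations ``N`` and the number observed methylated ``M``.
Two scalar per-sample summaries are computed here:

* ``MethylMean`` — the tumor-naive average methylation level across blocks;
* ``maxAF``     — the maximum somatic-variant allele fraction, the
  tumor-informed mutation readout (0 when no variant is detected).

All file formats are plain TSV with ``#`` comment lines; block coordinates
follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, UndefinedResultError, ValidationError

VALID_TIMEPOINTS = ("A", "B", "C", "F")


@dataclass(frozen=True)
class BlockDef:
    """One methylation block: a cluster of ``n_cpg`` CpG sites."""

    block_id: str
    chrom: str
    start: int
    end: int
    n_cpg: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"block {self.block_id}: negative coordinate")
        if not self.start < self.end:
            raise ValidationError(
                f"block {self.block_id}: start {self.start} must be < end {self.end}"
            )
        if self.n_cpg < 1:
            raise ValidationError(f"block {self.block_id}: n_cpg must be >= 1")


@dataclass
class BlockCounts:
    """Per-block (N, M) methylation counts for one sample.

    Blocks absent from ``counts`` are treated as uncovered (N = 0).
    """

    sample_id: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def add(self, block_id: str, n_total: int, n_meth: int) -> None:
        if n_total < 0 or n_meth < 0:
            raise ValidationError(
                f"sample {self.sample_id}, block {block_id}: negative count"
            )
        if n_meth > n_total:
            raise ValidationError(
                f"sample {self.sample_id}, block {block_id}: "
                f"methylated count {n_meth} exceeds total {n_total}"
            )
        self.counts[block_id] = (n_total, n_meth)

    def get(self, block_id: str) -> tuple[int, int]:
        return self.counts.get(block_id, (0, 0))

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class TissueMethylome:
    """Per-block methylation level for one tissue (or healthy plasma) sample.

    ``levels[block_id] = (level, depth)``; a level is only meaningful where
    depth >= 1.
    """

    sample_id: str
    tissue_role: str  # tumor | adjacent_normal | plasma_healthy
    levels: dict[str, tuple[float, int]] = field(default_factory=dict)

    def add(self, block_id: str, level: float, depth: int) -> None:
        if not 0.0 <= level <= 1.0:
            raise ValidationError(
                f"sample {self.sample_id}, block {block_id}: level {level} not in [0,1]"
            )
        if depth < 0:
            raise ValidationError(
                f"sample {self.sample_id}, block {block_id}: negative depth"
            )
        self.levels[block_id] = (float(level), int(depth))

    def level(self, block_id: str) -> float | None:
        entry = self.levels.get(block_id)
        if entry is None or entry[1] < 1:
            return None
        return entry[0]


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observed in a plasma sample."""

    sample_id: str
    variant_id: str
    gene: str
    allele_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValidationError(
                f"variant {self.variant_id}: allele fraction "
                f"{self.allele_fraction} not in [0,1]"
            )


@dataclass
class SampleSummary:
    """Scalar summaries of one plasma sample on the clinical timeline."""

    sample_id: str
    timepoint_label: str
    day_from_surgery: int
    methyl_mean: float | None = None
    max_af: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint_label not in VALID_TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id}: timepoint {self.timepoint_label!r} "
                f"not in {VALID_TIMEPOINTS}"
            )
        for name in ("methyl_mean", "max_af"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"sample {self.sample_id}: {name} {v} not in [0,1]"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_block_defs(path: str | Path) -> list[BlockDef]:
    """Read block definitions from a BED-like TSV.

    Columns: chrom, start, end, block_id, n_cpg. Ordering is preserved;
    duplicate block ids are rejected.
    """
    blocks: list[BlockDef] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        chrom, start_s, end_s, block_id, n_cpg_s = fields
        try:
            start, end, n_cpg = int(start_s), int(end_s), int(n_cpg_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
        if block_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate block id {block_id!r}")
        seen.add(block_id)
        blocks.append(BlockDef(block_id, chrom, start, end, n_cpg))
    return blocks


def write_block_defs(blocks: Sequence[BlockDef], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#chrom\tstart\tend\tblock_id\tn_cpg\n")
        for b in blocks:
            handle.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\t{b.n_cpg}\n")


def read_block_counts(
    path: str | Path, blocks: Sequence[BlockDef] | None = None
) -> dict[str, BlockCounts]:
    """Read per-sample per-block counts from a TSV.

    Columns: sample_id, block_id, n_total, n_meth. Returns one
    :class:`BlockCounts` per distinct sample id, in first-seen order.
    Block ids not present in ``blocks`` (when given) are rejected.
    """
    known = None if blocks is None else {b.block_id for b in blocks}
    out: dict[str, BlockCounts] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        sample_id, block_id, n_s, m_s = fields
        try:
            n_total, n_meth = int(n_s), int(m_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer count ({exc})") from exc
        if known is not None and block_id not in known:
            raise ValidationError(f"{path}:{lineno}: unknown block id {block_id!r}")
        sample = out.setdefault(sample_id, BlockCounts(sample_id))
        try:
            sample.add(block_id, n_total, n_meth)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_block_counts(
    samples: Iterable[BlockCounts], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#sample_id\tblock_id\tn_total\tn_meth\n")
        for sample in samples:
            for block_id, (n, m) in sample.counts.items():
                handle.write(f"{sample.sample_id}\t{block_id}\t{n}\t{m}\n")


def read_variants(path: str | Path) -> dict[str, list[VariantCall]]:
    """Read somatic variant calls (sample_id, variant_id, gene, allele_fraction)."""
    out: dict[str, list[VariantCall]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        sample_id, variant_id, gene, af_s = fields
        try:
            af = float(af_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad allele fraction ({exc})") from exc
        try:
            call = VariantCall(sample_id, variant_id, gene, af)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        out.setdefault(sample_id, []).append(call)
    return out


def read_manifest(path: str | Path) -> list[dict]:
    """Read a sample manifest (sample_id, patient_id, timepoint_label, day_from_surgery)."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        sample_id, patient_id, label, day_s = fields
        try:
            day = int(day_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad day ({exc})") from exc
        if label not in VALID_TIMEPOINTS:
            raise ValidationError(f"{path}:{lineno}: unknown timepoint {label!r}")
        rows.append(
            {
                "sample_id": sample_id,
                "patient_id": patient_id,
                "timepoint_label": label,
                "day_from_surgery": day,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# per-sample summaries
# ---------------------------------------------------------------------------

def compute_methylmean(
    counts: BlockCounts, min_depth: int = 1, depth_weighted: bool = False
) -> float:
    """Average methylation level across blocks with depth >= ``min_depth``.

    By default the unweighted mean of per-block ratios M/N; set
    ``depth_weighted`` to weight each block by its depth N instead.
    """
    if min_depth < 1:
        raise ValidationError("min_depth must be >= 1")
    num = 0.0
    den = 0.0
    for n, m in counts.counts.values():
        if n < min_depth:
            continue
        if depth_weighted:
            num += m
            den += n
        else:
            num += m / n
            den += 1.0
    if den == 0.0:
        raise UndefinedResultError(
            f"sample {counts.sample_id}: no block with depth >= {min_depth}"
        )
    return num / den


def compute_maxaf(variants: Iterable[VariantCall]) -> float:
    """Maximum allele fraction in a sample; 0 when no variant was detected.

    maxAF > 0 is the ctDNA-mutation-positive convention.
    """
    best = 0.0
    for v in variants:
        if v.allele_fraction > best:
            best = v.allele_fraction
    return best


def bisulfite_conversion_rate(non_cpg_total: int, non_cpg_methylated: int) -> float:
    """Fraction of non-CpG cytosines successfully converted by bisulfite.

    Non-CpG cytosines are essentially unmethylated in human DNA, so any
    apparent methylation there measures conversion failure.
    """
    if non_cpg_total < 1:
        raise UndefinedResultError("no non-CpG observations")
    if not 0 <= non_cpg_methylated <= non_cpg_total:
        raise ValidationError("non_cpg_methylated must be in [0, non_cpg_total]")
    return 1.0 - non_cpg_methylated / non_cpg_total
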