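"""Per-block beta prior for the background plasma methylation level.

In plasma from healthy donors the methylation level of block *j* varies
from person to person; the model treats it as a latent draw from
Beta(p_j, q_j). These shapes are estimated here from a healthy-plasma
count table by the method of moments, block by block, and reused as the
prior on the background component of every patient plasma sample.

Moment fits are closed-form and deterministic: with sample mean m and
unbiased variance v the common concentration is c = m(1-m)/v - 1, giving
p = m*c and q = (1-m)*c. Blocks whose ratios are (nearly) constant have
no usable variance; they fall back to a pseudocount fit at a configured
concentration so that every block keeps a proper, strictly positive prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, ParseError, UndefinedResultError
from .panel_io import BlockCounts, BlockDef, _data_lines

MOMENTS = "moments"
PSEUDOCOUNT = "pseudocount_fallback"


@dataclass(frozen=True)
class PriorEntry:
    p: float
    q: float
    n_samples_used: int
    fit_method: str

    @property
    def mean(self) -> float:
        return self.p / (self.p + self.q)

    @property
    def concentration(self) -> float:
        return self.p + self.q


@dataclass
class BackgroundPrior:
    """Beta(p_j, q_j) background prior for every block in a panel."""

    entries: dict[str, PriorEntry] = field(default_factory=dict)

    def __getitem__(self, block_id: str) -> PriorEntry:
        return self.entries[block_id]

    def __contains__(self, block_id: str) -> bool:
        return block_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def fit_block_prior(
    ratios: Sequence[float],
    *,
    clip: float = 1e-4,
    variance_floor: float = 1e-8,
    fallback_concentration: float = 100.0,
    epsilon: float = 0.5,
) -> tuple[float, float, str]:
    """Fit Beta(p, q) to a set of methylation ratios by the method of moments.

    Ratios exactly 0 or 1 are clipped into [clip, 1-clip] first. When the
    sample variance is at or below ``variance_floor`` (or implies a
    non-positive concentration) the pseudocount fallback
    ``p = m*c0 + eps, q = (1-m)*c0 + eps`` is used instead.

    Returns ``(p, q, fit_method)``.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 ratios to fit a block prior, got {arr.size}"
        )
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    arr = np.clip(arr, clip, 1.0 - clip)
    m = float(arr.mean())
    v = float(arr.var(ddof=1))
    if v > variance_floor:
        c = m * (1.0 - m) / v - 1.0
        if c > 0.0:
            return m * c, (1.0 - m) * c, MOMENTS
    return (
        m * fallback_concentration + epsilon,
        (1.0 - m) * fallback_concentration + epsilon,
        PSEUDOCOUNT,
    )


def fit_panel_prior(
    healthy: Sequence[BlockCounts],
    blocks: Sequence[BlockDef] | Sequence[str],
    min_depth: int = 10,
    *,
    clip: float = 1e-4,
    variance_floor: float = 1e-8,
    fallback_concentration: float = 100.0,
    epsilon: float = 0.5,
) -> BackgroundPrior:
    """Fit the background prior for every panel block from healthy plasma.

    Per block, the per-sample ratios M/N from samples with N >= ``min_depth``
    are fitted with :func:`fit_block_prior`. Blocks with fewer than two
    usable samples receive a pseudocount prior centred on the panel-wide
    pooled mean so the prior stays total over the panel.
    """
    if len(healthy) < 2:
        raise InsufficientDataError(
            f"need >= 2 healthy samples to fit a prior, got {len(healthy)}"
        )
    block_ids = [b.block_id if isinstance(b, BlockDef) else str(b) for b in blocks]

    total_m = sum(m for s in healthy for (_, m) in s.counts.values())
    total_n = sum(n for s in healthy for (n, _) in s.counts.values())
    pooled_mean = total_m / total_n if total_n > 0 else 0.5
    pooled_mean = float(np.clip(pooled_mean, clip, 1.0 - clip))

    entries: dict[str, PriorEntry] = {}
    any_moment_capable = False
    for block_id in block_ids:
        ratios = [
            m / n
            for s in healthy
            for (n, m) in [s.get(block_id)]
            if n >= min_depth
        ]
        if len(ratios) >= 2:
            any_moment_capable = True
            p, q, method = fit_block_prior(
                ratios,
                clip=clip,
                variance_floor=variance_floor,
                fallback_concentration=fallback_concentration,
                epsilon=epsilon,
            )
            entries[block_id] = PriorEntry(p, q, len(ratios), method)
        else:
            entries[block_id] = PriorEntry(
                pooled_mean * fallback_concentration + epsilon,
                (1.0 - pooled_mean) * fallback_concentration + epsilon,
                len(ratios),
                PSEUDOCOUNT,
            )
    if not entries or not any_moment_capable:
        raise UndefinedResultError("no block has enough covered healthy samples")
    return BackgroundPrior(entries)


def write_prior(prior: BackgroundPrior, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#block_id\tp\tq\tn_samples_used\tfit_method\n")
        for block_id, e in prior.entries.items():
            handle.write(
                f"{block_id}\t{e.p:.10g}\t{e.q:.10g}\t{e.n_samples_used}\t{e.fit_method}\n"
            )


def read_prior(path: str | Path) -> BackgroundPrior:
    entries: dict[str, PriorEntry] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        block_id, p_s, q_s, n_s, method = fields
        try:
            p, q, n_used = float(p_s), float(q_s), int(n_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad numeric field ({exc})") from exc
        if p <= 0 or q <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive beta shape")
        entries[block_id] = PriorEntry(p, q, n_used, method)
    return BackgroundPrior(entries)
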