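"""Differentially methylated block (DMB) discovery and patient panel selection.

Two layers of marker selection feed the deconvolution model:

* **Cohort discovery** — a paired tumor vs adjacent-normal comparison
  across patients (Wilcoxon signed-rank per block, Benjamini-Hochberg
  across blocks, plus a floor on the mean paired difference) yielding a
  cohort-level DMB set.

* **Patient-specific selection** — for one patient, the blocks whose tumor
  level stands clear of both the healthy-plasma background prior and the
  patient's own adjacent-normal tissue. These blocks carry the
  identifiable ctDNA signal and define the per-patient panel scored in
  plasma.

Default direction is hypermethylation (tumor above background), the
informative direction for a background-hypomethylated panel; hypo blocks
can be enabled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .background_prior import BackgroundPrior
from .errors import InsufficientDataError, UndefinedResultError, UnscoreablePatientError, ValidationError
from .panel_io import TissueMethylome, _data_lines


@dataclass(frozen=True)
class DmbCandidate:
    block_id: str
    mean_tumor: float
    mean_normal: float
    effect_size: float  # mean paired (tumor - normal) difference
    p_value: float
    q_value: float
    direction: str  # hyper | hypo


@dataclass
class PanelBlock:
    block_id: str
    beta_t: float
    beta_n: float


@dataclass
class PatientPanel:
    """The selected DMBs for one patient, ranked by tumor-over-prior margin."""

    patient_id: str
    blocks: list[PanelBlock] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.blocks)

    def block_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks]


def discover_cohort_dmbs(
    tumors: list[TissueMethylome],
    normals: list[TissueMethylome],
    effect_min: float = 0.1,
    q_max: float = 0.05,
    direction: str = "hyper",
) -> list[DmbCandidate]:
    """Paired tumor vs adjacent-normal DMB discovery across a cohort.

    ``tumors[k]`` and ``normals[k]`` must come from the same patient. Per
    block, a two-tailed Wilcoxon signed-rank test on the paired differences
    is combined with a Benjamini-Hochberg correction across blocks; blocks
    with ``|mean difference| >= effect_min`` and ``q <= q_max`` are
    returned ranked by absolute effect size (ties broken by block id).

    ``direction`` restricts the output to ``hyper``, ``hypo`` or ``both``.
    """
    if len(tumors) != len(normals):
        raise ValidationError(
            f"unmatched cohort: {len(tumors)} tumors vs {len(normals)} normals"
        )
    if len(tumors) < 3:
        raise InsufficientDataError("need >= 3 tumor/normal pairs")
    if direction not in ("hyper", "hypo", "both"):
        raise ValidationError(f"unknown direction {direction!r}")

    block_ids = sorted(
        set().union(*(set(t.levels) for t in tumors)).intersection(
            *(set(n.levels) for n in normals)
        )
    )
    tested: list[tuple[str, float, float, float, float]] = []
    pvals: list[float] = []
    for block_id in block_ids:
        diffs, t_levels, n_levels = [], [], []
        for t, n in zip(tumors, normals):
            lt, ln = t.level(block_id), n.level(block_id)
            if lt is None or ln is None:
                continue
            diffs.append(lt - ln)
            t_levels.append(lt)
            n_levels.append(ln)
        if len(diffs) < 3:
            continue
        diffs = np.asarray(diffs)
        if np.allclose(diffs, 0.0):
            p = 1.0
        else:
            # zero differences dropped (wilcox convention); exact where possible
            p = float(
                stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided").pvalue
            )
        tested.append(
            (block_id, float(np.mean(t_levels)), float(np.mean(n_levels)), float(np.mean(diffs)), p)
        )
        pvals.append(p)

    if not tested:
        return []
    qvals = stats.false_discovery_control(pvals, method="bh")
    candidates = []
    for (block_id, mt, mn, eff, p), q in zip(tested, qvals):
        if abs(eff) < effect_min or q > q_max:
            continue
        d = "hyper" if eff > 0 else "hypo"
        if direction != "both" and d != direction:
            continue
        candidates.append(DmbCandidate(block_id, mt, mn, eff, p, float(q), d))
    candidates.sort(key=lambda c: (-abs(c.effect_size), c.block_id))
    return candidates


def select_patient_dmbs(
    tumor: TissueMethylome,
    normal: TissueMethylome,
    prior: BackgroundPrior,
    cohort_dmbs: set[str] | None = None,
    delta_prior: float = 0.2,
    delta_normal: float = 0.1,
    concentration_min: float = 10.0,
    m_max: int = 5000,
    patient_id: str | None = None,
) -> PatientPanel:
    """Select a patient's informative hypermethylated blocks.

    A block is kept when (i) its tumor level exceeds the background prior
    mean by ``delta_prior``, (ii) its tumor level exceeds the patient's
    adjacent-normal level by ``delta_normal``, and (iii) the prior is
    concentrated enough (p + q >= ``concentration_min``) to constrain the
    background. Blocks are ranked by tumor-over-prior margin and truncated
    at ``m_max``. Raises when nothing survives: such a patient cannot be
    scored and must be reported, not silently dropped.
    """
    candidates = set(tumor.levels) & set(normal.levels) & set(prior.entries)
    if cohort_dmbs is not None:
        candidates &= set(cohort_dmbs)
    if not candidates:
        raise UnscoreablePatientError("no candidate block covered by tissue and prior")

    kept: list[tuple[float, str, float, float]] = []
    for block_id in candidates:
        bt = tumor.level(block_id)
        bn = normal.level(block_id)
        if bt is None or bn is None:
            continue
        entry = prior[block_id]
        margin = bt - entry.mean
        if margin < delta_prior:
            continue
        if bt - bn < delta_normal:
            continue
        if entry.concentration < concentration_min:
            continue
        kept.append((margin, block_id, bt, bn))
    if not kept:
        raise UnscoreablePatientError(
            "no block passes patient-specific selection thresholds"
        )
    kept.sort(key=lambda t: (-t[0], t[1]))
    pid = patient_id or tumor.sample_id
    return PatientPanel(
        pid, [PanelBlock(bid, bt, bn) for _, bid, bt, bn in kept[:m_max]]
    )


def hypermethylation_ratio(
    tissue: TissueMethylome, prior: BackgroundPrior, margin: float = 0.2
) -> float:
    """Fraction of evaluable blocks hypermethylated relative to background.

    A block counts when its tissue level exceeds the prior mean by more
    than ``margin``; evaluable means covered in both tissue and prior.
    """
    n_eval = 0
    n_hyper = 0
    for block_id, entry in prior.entries.items():
        level = tissue.level(block_id)
        if level is None:
            continue
        n_eval += 1
        if level > entry.mean + margin:
            n_hyper += 1
    if n_eval == 0:
        raise UndefinedResultError("no evaluable block for hypermethylation ratio")
    return n_hyper / n_eval


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_panel(panel: PatientPanel, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#patient_id\tblock_id\tbeta_t\tbeta_n\n")
        for b in panel.blocks:
            handle.write(f"{panel.patient_id}\t{b.block_id}\t{b.beta_t:.10g}\t{b.beta_n:.10g}\n")


def read_panels(path) -> dict[str, PatientPanel]:
    panels: dict[str, PatientPanel] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ValidationError(f"{path}:{lineno}: expected 4 columns")
        pid, block_id, bt_s, bn_s = fields
        bt, bn = float(bt_s), float(bn_s)
        panels.setdefault(pid, PatientPanel(pid)).blocks.append(
            PanelBlock(block_id, bt, bn)
        )
    return panels


def write_candidates(candidates: list[DmbCandidate], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#block_id\teffect_size\tp_value\tq_value\tdirection\n")
        for c in candidates:
            handle.write(
                f"{c.block_id}\t{c.effect_size:.6g}\t{c.p_value:.6g}\t{c.q_value:.6g}\t{c.direction}\n"
            )
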