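"""Hand-pollination (crossing) experiment analysis.

Each record is one hand-pollinated flower.  A cross is *parental* when pollen
and maternal tree come from the same ecotype and *hybrid* when they differ;
negative controls (emasculated, unpollinated flowers) must never set seed and
are excluded from treatment comparisons, as are positive (open-pollinated)
controls.

Three sequential stages are scored per treatment:

adhesion
    mean number of pollen grains adhered to the stigma per flower,
germination
    mean per-flower proportion of adhered grains that germinated a pollen
    tube,
seed_set
    proportion of flowers with a developing seed.

Treatments are compared with a Mann-Whitney U test (count/proportion stages)
or a two-sided Fisher exact test (seed set), and each stage's RI is the RI4A
index on the hybrid (heterospecific, H) vs parental (conspecific, C) metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ri_core import MatingCounts, ri_mating

__all__ = [
    "STAGES",
    "CrossRecord",
    "StageSummary",
    "StageTest",
    "read_crosses",
    "records_from_frame",
    "validate_records",
    "stage_metrics",
    "compare_stage",
    "ri_stage",
    "analyze_stage",
]

STAGES = ("adhesion", "germination", "seed_set")


@dataclass(frozen=True)
class CrossRecord:
    """One hand-pollinated flower's stage outcomes.

    Optional fields are None when the stage was not scored for this flower.
    ``control_type`` is ``"none"`` for experimental crosses; controls carry no
    pollen ecotype.
    """

    flower_id: str
    maternal_ecotype: str
    pollen_ecotype: str | None
    adhered: int | None = None
    germinated: int | None = None
    seed_set: bool | None = None
    control_type: str = "none"
    inflorescence_id: str | None = None

    def __post_init__(self) -> None:
        if self.control_type not in ("none", "negative", "positive"):
            raise ValueError(f"unknown control_type {self.control_type!r}")
        if self.control_type == "none" and not self.pollen_ecotype:
            raise ValueError(f"flower {self.flower_id}: experimental cross lacks pollen_ecotype")
        if self.control_type != "none" and self.pollen_ecotype:
            raise ValueError(f"flower {self.flower_id}: controls carry no pollen_ecotype")
        if self.adhered is not None and self.adhered < 0:
            raise ValueError(f"flower {self.flower_id}: adhered count negative")
        if self.germinated is not None:
            if self.adhered is None:
                raise ValueError(f"flower {self.flower_id}: germinated scored without adhered")
            if not 0 <= self.germinated <= self.adhered:
                raise ValueError(
                    f"flower {self.flower_id}: germinated={self.germinated} "
                    f"outside [0, adhered={self.adhered}]"
                )
        if self.control_type == "negative" and self.seed_set:
            raise ValueError(f"flower {self.flower_id}: negative control set seed")

    @property
    def treatment(self) -> str | None:
        """'parental' or 'hybrid' for experimental crosses, None for controls."""
        if self.control_type != "none":
            return None
        return "parental" if self.maternal_ecotype == self.pollen_ecotype else "hybrid"


@dataclass(frozen=True)
class StageTest:
    statistic: float
    p_value: float
    method: str

    def as_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value, "method": self.method}


@dataclass(frozen=True)
class StageSummary:
    """Per-treatment metrics for one stage, with optional test and RI."""

    stage: str
    parental_metric: float
    hybrid_metric: float
    parental_se: float
    hybrid_se: float
    n_parental: int
    n_hybrid: int
    test: StageTest | None = None
    ri: float | None = None


def read_crosses(path: str | Path) -> list[CrossRecord]:
    """Read hand-cross records from CSV.

    Expected columns: flower_id, maternal_ecotype, pollen_ecotype, adhered,
    germinated, seed_set, control_type (optional: inflorescence_id).  Empty
    cells mean the stage was not scored.
    """
    df = pd.read_csv(path, dtype={"flower_id": str})
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[CrossRecord]:
    required = {"flower_id", "maternal_ecotype", "pollen_ecotype", "seed_set"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cross table lacks columns {sorted(missing)}")

    def _int(v):
        return None if pd.isna(v) else int(v)

    def _bool(v):
        return None if pd.isna(v) else bool(int(v))

    def _str(v):
        return None if (pd.isna(v) or v == "") else str(v)

    records = []
    for rec in df.to_dict("records"):
        records.append(
            CrossRecord(
                flower_id=str(rec["flower_id"]),
                maternal_ecotype=str(rec["maternal_ecotype"]),
                pollen_ecotype=_str(rec.get("pollen_ecotype")),
                adhered=_int(rec.get("adhered")),
                germinated=_int(rec.get("germinated")),
                seed_set=_bool(rec.get("seed_set")),
                control_type=_str(rec.get("control_type")) or "none",
                inflorescence_id=_str(rec.get("inflorescence_id")),
            )
        )
    return records


def records_to_frame(records: Iterable[CrossRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "flower_id": r.flower_id,
                "inflorescence_id": r.inflorescence_id or "",
                "maternal_ecotype": r.maternal_ecotype,
                "pollen_ecotype": r.pollen_ecotype or "",
                "adhered": r.adhered,
                "germinated": r.germinated,
                "seed_set": None if r.seed_set is None else int(r.seed_set),
                "control_type": r.control_type,
            }
        )
    return pd.DataFrame(rows)


def validate_records(records: Sequence[CrossRecord]) -> None:
    """Dataset-level sanity checks (per-record invariants run at construction)."""
    if not records:
        raise ValueError("no cross records")
    seen = set()
    for r in records:
        if r.flower_id in seen:
            raise ValueError(f"duplicate flower_id {r.flower_id}")
        seen.add(r.flower_id)


def _stage_values(records: Sequence[CrossRecord], treatment: str, stage: str) -> np.ndarray:
    vals = []
    for r in records:
        if r.treatment != treatment:
            continue
        if stage == "adhesion":
            if r.adhered is not None:
                vals.append(float(r.adhered))
        elif stage == "germination":
            if r.germinated is not None and r.adhered:
                vals.append(r.germinated / r.adhered)
        elif stage == "seed_set":
            if r.seed_set is not None:
                vals.append(float(r.seed_set))
        else:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return np.asarray(vals, dtype=float)


def stage_metrics(records: Sequence[CrossRecord], stage: str) -> StageSummary:
    """Per-treatment metric and standard error for one stage.

    adhesion: mean adhered grains; germination: mean per-flower germinated
    proportion; seed_set: fraction of flowers setting seed (binomial SE).
    """
    out = {}
    for treatment in ("parental", "hybrid"):
        vals = _stage_values(records, treatment, stage)
        if vals.size == 0:
            raise ValueError(f"stage {stage!r} unmeasured in treatment {treatment!r}")
        mean = float(vals.mean())
        if stage == "seed_set":
            se = math.sqrt(mean * (1.0 - mean) / vals.size)
        else:
            se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
        out[treatment] = (mean, se, vals.size)
    return StageSummary(
        stage=stage,
        parental_metric=out["parental"][0],
        hybrid_metric=out["hybrid"][0],
        parental_se=out["parental"][1],
        hybrid_se=out["hybrid"][1],
        n_parental=out["parental"][2],
        n_hybrid=out["hybrid"][2],
    )


def compare_stage(records: Sequence[CrossRecord], stage: str) -> StageTest:
    """Treatment comparison for one stage.

    adhesion/germination: two-sample Mann-Whitney U on per-flower values
    (midranks, tie-corrected normal approximation); seed_set: two-sided
    Fisher exact test on the 2x2 treatment-by-outcome table.
    """
    parental = _stage_values(records, "parental", stage)
    hybrid = _stage_values(records, "hybrid", stage)
    if parental.size < 2 or hybrid.size < 2:
        raise ValueError(f"stage {stage!r}: need at least 2 observations per treatment")
    if stage == "seed_set":
        table = [
            [int(hybrid.sum()), int(hybrid.size - hybrid.sum())],
            [int(parental.sum()), int(parental.size - parental.sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return StageTest(float(odds), float(p), "fisher_exact")
    res = stats.mannwhitneyu(parental, hybrid, alternative="two-sided", method="asymptotic")
    return StageTest(float(res.statistic), float(res.pvalue), "mann_whitney_u")


def ri_stage(summary: StageSummary) -> StageSummary:
    """Fill in the stage RI4A with hybrid success as H, parental as C."""
    ri = ri_mating(MatingCounts(H=summary.hybrid_metric, C=summary.parental_metric))
    return replace(summary, ri=ri)


def analyze_stage(records: Sequence[CrossRecord], stage: str) -> StageSummary:
    """Metrics + treatment test + RI for one stage in a single call."""
    summary = stage_metrics(records, stage)
    test = compare_stage(records, stage)
    return ri_stage(replace(summary, test=test))
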