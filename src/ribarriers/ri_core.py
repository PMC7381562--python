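"""Sobel-Chen RI4 family of reproductive-isolation indices and barrier cascades.

All indices score the reduction in heterospecific gene flow caused by a single
barrier: 1 means complete isolation, 0 random mating, and (for the mating and
temporal forms) negative values mean disassortative gene flow, i.e. the barrier
*enhances* heterospecific mating.

Four estimators are provided:

``ri_cooccurrence``
    RI4C = 1 - S/(S+U), for barriers expressed as shared vs unshared
    quantities (habitat pixels, pollinator-community overlap). Range [0, 1].
``ri_temporal``
    RI4S2, an abundance-weighted flowering-time overlap over a temporal
    series. Range [-1, 1].
``ri_mating``
    RI4A = 1 - 2H/(H+C) on heterospecific vs conspecific mating success
    (counts, means, or rates in identical units). Range [-1, 1].
``ri_4e``
    RI4E, a total-isolation form that conditions gene-flow probabilities on
    habitat co-occurrence.

Per-barrier strengths are combined with the sequential multiplicative cascade
(``cascade_total``): earlier-acting barriers remove gene flow first, so barrier
k can only block what barriers 1..k-1 let through. This yields the standard
absolute/relative contribution decomposition AC_k = RI_k * prod_{j<k}(1-RI_j).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "BARRIER_ORDER",
    "BarrierStrength",
    "CooccurrenceCounts",
    "MatingCounts",
    "FloweringSeries",
    "BarrierCascade",
    "CascadeResult",
    "RI4EInputs",
    "ri_cooccurrence",
    "ri_mating",
    "ri_temporal",
    "ri_to_mating_ratio",
    "cascade_total",
    "ri_4e",
    "ri_4e_from_barriers",
    "read_barrier_table",
    "write_barrier_table",
    "barrier_for",
    "write_cascade_report",
]

STAGES = ("prepollination", "postpollination_prezygotic", "postzygotic")

#: Canonical life-cycle order of the barriers handled by this package.
BARRIER_ORDER = (
    "ecogeography",
    "phenology",
    "pollinator_assemblage",
    "pollen_adhesion",
    "pollen_germination",
    "seed_development",
)

_BARRIER_STAGE = {
    "ecogeography": "prepollination",
    "phenology": "prepollination",
    "pollinator_assemblage": "prepollination",
    "pollen_adhesion": "postpollination_prezygotic",
    "pollen_germination": "postpollination_prezygotic",
    "seed_development": "postzygotic",
}

_METHODS = ("RI4C", "RI4S2", "RI4A")


class UndefinedInputError(ValueError):
    """Raised when an RI index is evaluated on degenerate inputs (0/0)."""


@dataclass(frozen=True)
class BarrierStrength:
    """One barrier's isolation strength in one direction.

    ``focal`` names the ecotype from whose perspective the estimate is made
    (e.g. isolation experienced by brown-sand maternal trees).  ``available``
    is False for barriers that were not measured in this direction; such
    barriers are skipped, never imputed as zero.
    """

    barrier_name: str
    stage: str
    focal: str
    value: float
    method: str
    available: bool = True

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        if self.available:
            v = self.value
            if not math.isfinite(v):
                raise ValueError("barrier value must be finite")
            if self.method == "RI4C":
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"RI4C value {v} outside [0, 1]")
            elif not -1.0 <= v <= 1.0:
                raise ValueError(f"{self.method} value {v} outside [-1, 1]")


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Shared (S) and unshared (U) co-occurrence quantities for RI4C."""

    S: float
    U: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.S) and math.isfinite(self.U)):
            raise ValueError("S and U must be finite")
        if self.S < 0 or self.U < 0:
            raise ValueError("S and U must be non-negative")
        if self.S + self.U == 0:
            raise UndefinedInputError("S + U must be positive")


@dataclass(frozen=True)
class MatingCounts:
    """Heterospecific (H) and conspecific (C) mating quantities for RI4A.

    H and C may be raw counts, per-treatment means, or success rates, but must
    share units.
    """

    H: float
    C: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.H) and math.isfinite(self.C)):
            raise ValueError("H and C must be finite")
        if self.H < 0 or self.C < 0:
            raise ValueError("H and C must be non-negative")
        if self.H + self.C == 0:
            raise UndefinedInputError("H + C must be positive")


@dataclass(frozen=True)
class FloweringSeries:
    """Per-period flowering counts for the focal (A) and other (B) ecotype.

    ``A[i]`` / ``B[i]`` count distinct trees in flower during period i;
    ``A_total`` / ``B_total`` are the census sizes of the monitored
    populations.
    """

    periods: tuple
    A: tuple
    B: tuple
    A_total: int
    B_total: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(self.periods))
        object.__setattr__(self, "A", tuple(float(a) for a in self.A))
        object.__setattr__(self, "B", tuple(float(b) for b in self.B))
        if not (len(self.periods) == len(self.A) == len(self.B)):
            raise ValueError("periods, A and B must have equal length")
        if self.A_total <= 0 or self.B_total <= 0:
            raise ValueError("census totals must be positive")
        for a in self.A:
            if not 0 <= a <= self.A_total:
                raise ValueError(f"A_i={a} outside [0, A_total={self.A_total}]")
        for b in self.B:
            if not 0 <= b <= self.B_total:
                raise ValueError(f"B_i={b} outside [0, B_total={self.B_total}]")

    def swapped(self) -> "FloweringSeries":
        """The same series viewed from the other ecotype's perspective."""
        return FloweringSeries(self.periods, self.B, self.A, self.B_total, self.A_total)


@dataclass(frozen=True)
class BarrierCascade:
    """An ordered sequence of barrier strengths for one focal ecotype.

    Order is fixed by life-cycle stage (ecogeography first, seed development
    last); ``include_ecogeography=False`` drops the ecogeographic barrier to
    model isolation at a contact zone (sympatry).
    """

    barriers: tuple
    include_ecogeography: bool = True
    baseline_gene_flow: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "barriers", tuple(self.barriers))
        if not 0.0 < self.baseline_gene_flow < 1.0:
            raise ValueError("baseline_gene_flow must lie in (0, 1)")
        names = [b.barrier_name for b in self.barriers]
        if len(set(names)) != len(names):
            raise ValueError("each barrier may appear at most once")
        known = [n for n in names if n in BARRIER_ORDER]
        if known != sorted(known, key=BARRIER_ORDER.index):
            raise ValueError(f"barriers out of life-cycle order: {names}")

    def active_barriers(self) -> tuple:
        """Available barriers, with ecogeography dropped in sympatry mode."""
        out = []
        for b in self.barriers:
            if not b.available:
                continue
            if b.barrier_name == "ecogeography" and not self.include_ecogeography:
                continue
            out.append(b)
        return tuple(out)


@dataclass(frozen=True)
class CascadeResult:
    """Total RI plus per-barrier absolute (AC) and relative (RC) contributions."""

    total: float
    barrier_names: tuple
    absolute_contribution: tuple
    relative_contribution: tuple

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barrier_name": self.barrier_names,
                "absolute_contribution": self.absolute_contribution,
                "relative_contribution": self.relative_contribution,
            }
        )


@dataclass(frozen=True)
class RI4EInputs:
    """Habitat-share fractions and conditional gene-flow probabilities for RI4E."""

    S_total: float
    U_total: float
    p_H_given_S: float
    p_H_given_U: float
    p_C_given_S: float
    p_C_given_U: float

    def __post_init__(self) -> None:
        if abs(self.S_total + self.U_total - 1.0) > 1e-9:
            raise ValueError("S_total + U_total must equal 1")
        for name in ("S_total", "U_total", "p_H_given_S", "p_H_given_U", "p_C_given_S", "p_C_given_U"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# index formulas
# ---------------------------------------------------------------------------

def ri_cooccurrence(counts: CooccurrenceCounts) -> float:
    """RI4C = 1 - S/(S+U): isolation from shared vs unshared co-occurrence.

    Returns 0 for complete overlap (U = 0) and 1 for disjoint ranges (S = 0).
    """
    return 1.0 - counts.S / (counts.S + counts.U)


def ri_mating(counts: MatingCounts) -> float:
    """RI4A = 1 - 2H/(H+C): isolation from mating-success asymmetry.

    1 = no heterospecific success, 0 = random mating, -1 = completely
    disassortative mating.
    """
    return 1.0 - 2.0 * counts.H / (counts.H + counts.C)


def ri_temporal(series: FloweringSeries) -> float:
    """RI4S2: abundance-weighted temporal isolation over a flowering series.

    For each period i the heterospecific and conspecific pollen-transfer
    weights are

        H_i = (A_i/A_total) * (B_i/(A_i+B_i)) * (B_total/(A_total+B_total))
        C_i = (A_i/A_total) * (A_i/(A_i+B_i)) * (A_total/(A_total+B_total))

    and the index is 1 - 2*sum(H_i) / (sum(H_i) + sum(C_i)).  Periods in which
    neither population flowers (A_i + B_i = 0) offer no mating opportunity and
    contribute zero to both sums.
    """
    A = np.asarray(series.A, dtype=float)
    B = np.asarray(series.B, dtype=float)
    At, Bt = float(series.A_total), float(series.B_total)
    tot = A + B
    active = tot > 0
    H = np.zeros_like(A)
    C = np.zeros_like(A)
    w_b = Bt / (At + Bt)
    w_a = At / (At + Bt)
    H[active] = (A[active] / At) * (B[active] / tot[active]) * w_b
    C[active] = (A[active] / At) * (A[active] / tot[active]) * w_a
    sH, sC = H.sum(), C.sum()
    if sH + sC == 0:
        raise UndefinedInputError("no overlap mass: all H_i and C_i are zero")
    return 1.0 - 2.0 * sH / (sH + sC)


def ri_to_mating_ratio(ri: float) -> float:
    """Invert RI4A: the heterospecific:conspecific success ratio r with
    ``ri_mating(H=r, C=1) == ri``.

    r = (1 - ri) / (1 + ri); defined for ri in (-1, 1].
    """
    if not -1.0 < ri <= 1.0:
        if ri == -1.0:
            raise UndefinedInputError("ri = -1 corresponds to an infinite mating ratio")
        raise ValueError(f"ri={ri} outside (-1, 1]")
    return (1.0 - ri) / (1.0 + ri)


def cascade_total(cascade: BarrierCascade) -> CascadeResult:
    """Combine sequential barrier strengths into total RI and contributions.

    total = 1 - prod_k(1 - RI_k) over the available barriers in life-cycle
    order; the absolute contribution of barrier k is the gene flow it removes
    given that earlier barriers act first, AC_k = RI_k * prod_{j<k}(1 - RI_j),
    so the AC_k sum telescopes to the total.  Negative strengths
    (disassortative barriers) propagate unchanged via factors above 1.
    """
    active = cascade.active_barriers()
    if not active:
        raise ValueError("cascade has no available barriers")
    names, acs = [], []
    passthrough = 1.0
    for b in active:
        names.append(b.barrier_name)
        acs.append(b.value * passthrough)
        passthrough *= 1.0 - b.value
    total = 1.0 - passthrough
    if total != 0:
        rcs = [ac / total for ac in acs]
    else:
        rcs = [math.nan] * len(acs)
    return CascadeResult(total, tuple(names), tuple(acs), tuple(rcs))


def ri_4e(inputs: RI4EInputs) -> float:
    """RI4E: total isolation conditioned on habitat co-occurrence.

    RI4E = 1 - 2*(S*P(H|S) + U*P(H|U)) /
               (S*P(H|S) + U*P(H|U) + S*P(C|S) + U*P(C|U))
    """
    h = inputs.S_total * inputs.p_H_given_S + inputs.U_total * inputs.p_H_given_U
    c = inputs.S_total * inputs.p_C_given_S + inputs.U_total * inputs.p_C_given_U
    if h + c == 0:
        raise UndefinedInputError("all conditional gene-flow terms are zero")
    return 1.0 - 2.0 * h / (h + c)


def ri_4e_from_barriers(cascade: BarrierCascade) -> float:
    """Evaluate RI4E from a barrier cascade under a default probability mapping.

    The ecogeographic RI4C value fixes the habitat split (S_total = 1 - RI_eco);
    heterospecific gene flow is impossible in unshared habitat (P(H|U) = 0);
    conspecific gene flow happens at the baseline rate everywhere; and within
    shared habitat the heterospecific rate is the baseline discounted by the
    compounded mating-ratio of every later-acting available barrier.
    """
    active = cascade.active_barriers()
    eco = next((b for b in active if b.barrier_name == "ecogeography"), None)
    if cascade.include_ecogeography:
        if eco is None:
            raise ValueError("cascade lacks an available ecogeographic barrier")
        if eco.method != "RI4C":
            raise ValueError("ecogeographic barrier must use method RI4C")
        s_total = 1.0 - eco.value
        u_total = eco.value
    else:
        s_total, u_total = 1.0, 0.0
    ratio = 1.0
    for b in active:
        if b is eco:
            continue
        ratio *= ri_to_mating_ratio(b.value)
    g = cascade.baseline_gene_flow
    if s_total == 0.0:
        # no shared habitat: heterospecific gene flow is impossible
        return 1.0
    return ri_4e(
        RI4EInputs(
            S_total=s_total,
            U_total=u_total,
            p_H_given_S=g * ratio,
            p_H_given_U=0.0,
            p_C_given_S=g,
            p_C_given_U=g,
        )
    )


# ---------------------------------------------------------------------------
# barrier-table / report I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["barrier_name", "stage", "focal", "method", "value", "available"]


def write_barrier_table(barriers: Iterable[BarrierStrength], path: str | Path) -> None:
    """Write barrier strengths as CSV (one row per barrier and direction)."""
    rows = []
    for b in barriers:
        rows.append(
            {
                "barrier_name": b.barrier_name,
                "stage": b.stage,
                "focal": b.focal,
                "method": b.method,
                "value": b.value if b.available else "",
                "available": int(b.available),
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def read_barrier_table(path: str | Path) -> list[BarrierStrength]:
    """Read a barrier-table CSV written by :func:`write_barrier_table`."""
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"barrier table {path} lacks columns {sorted(missing)}")
    out = []
    for rec in df.to_dict("records"):
        available = bool(int(rec["available"]))
        value = float(rec["value"]) if available else math.nan
        out.append(
            BarrierStrength(
                barrier_name=str(rec["barrier_name"]),
                stage=str(rec["stage"]),
                focal=str(rec["focal"]),
                value=value,
                method=str(rec["method"]),
                available=available,
            )
        )
    return out


def barrier_for(name: str, focal: str, value: float, method: str, available: bool = True) -> BarrierStrength:
    """Convenience constructor resolving the canonical stage for a known barrier."""
    if name not in _BARRIER_STAGE:
        raise ValueError(f"unknown barrier {name!r}; expected one of {BARRIER_ORDER}")
    return BarrierStrength(name, _BARRIER_STAGE[name], focal, value, method, available)


def write_cascade_report(
    result: CascadeResult,
    path: str | Path,
    *,
    sympatry_total: float | None = None,
    ri_4e_total: float | None = None,
    round_to: int | None = None,
) -> None:
    """Write a cascade result as JSON (totals plus per-barrier contributions)."""
    rnd = (lambda x: round(x, round_to)) if round_to is not None else (lambda x: x)
    payload = {
        "total": rnd(result.total),
        "barriers": [
            {
                "barrier_name": n,
                "absolute_contribution": rnd(ac),
                "relative_contribution": rnd(rc) if math.isfinite(rc) else None,
            }
            for n, ac, rc in zip(
                result.barrier_names, result.absolute_contribution, result.relative_contribution
            )
        ],
    }
    if sympatry_total is not None:
        payload["sympatry_total"] = rnd(sympatry_total)
    if ri_4e_total is not None:
        payload["ri_4e_total"] = rnd(ri_4e_total)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
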