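"""Molecular-clock dating of duplication events and stage assignment.

A duplication's age is T = Ks / (2λ), with λ the neutral substitution rate
per silent site per year (6.5×10⁻⁹ for the rice genome).  Dated events are
binned into three evolutionary stages of grass-genome history — 70–50 My
(origin of grasses to the rice/maize split), 50–20 My (rice/maize split to
the Zizaniinae/Oryzinae separation) and 20–9 My (to the branching-off of
Oryza) — with a nearest-bin fallback plus flag for dates outside all bins,
and an optional per-pair override for narrative assignments that disagree
with strict binning.

Reported dates and Ka/Ks ratios are TRUNCATED (not rounded) to the table's
printed precision; full-precision values are preserved alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from optfam.kaks import classify_selection

#: Neutral substitution rate per silent site per year for rice.
LAMBDA_RICE = 6.5e-9

#: Stage bins in million years, newest bound last, as (upper, lower).
DEFAULT_STAGE_BINS: tuple[tuple[float, float], ...] = (
    (70.0, 50.0),
    (50.0, 20.0),
    (20.0, 9.0),
)


def pair_key(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


@dataclass
class StageConfig:
    lam: float = LAMBDA_RICE
    bins: tuple[tuple[float, float], ...] = DEFAULT_STAGE_BINS
    overrides: Mapping[frozenset[str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("λ must be positive")
        prev_lower = math.inf
        for upper, lower in self.bins:
            if upper <= lower or upper > prev_lower:
                raise ValueError("stage boundaries must be strictly decreasing")
            prev_lower = lower


@dataclass
class DatedEvent:
    id_a: str
    id_b: str
    ks: float
    date_my: float
    stage: int
    out_of_range: bool


def truncate(value: float, decimals: int) -> float:
    """Floor at the given number of decimals (with a tiny guard against
    representation error just below an integer grid point)."""
    scale = 10 ** decimals
    return math.floor(value * scale * (1.0 + 1e-12) + 1e-9) / scale


def date_event(ks: float, lam: float = LAMBDA_RICE) -> float:
    """Duplication age T = Ks/(2λ) in million years (full precision)."""
    if lam <= 0:
        raise ValueError("λ must be positive")
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    return ks / (2.0 * lam) / 1e6


def assign_stage(
    date_my: float, config: StageConfig | None = None
) -> tuple[int, bool]:
    """Stage bin containing a date; nearest bin with a flag when outside.

    Bins are half-open ``(lower, upper]`` except the oldest, which is
    closed at its upper bound; stages are numbered 1 (oldest) onward.
    """
    config = config or StageConfig()
    if date_my < 0:
        raise ValueError("negative date")
    for i, (upper, lower) in enumerate(config.bins, 1):
        if lower < date_my <= upper:
            return i, False
    if date_my > config.bins[0][0]:
        return 1, True
    if date_my <= config.bins[-1][1]:
        return len(config.bins), True
    # between non-contiguous bins: nearest boundary wins
    best, best_gap = 1, math.inf
    for i, (upper, lower) in enumerate(config.bins, 1):
        gap = min(abs(date_my - upper), abs(date_my - lower))
        if gap < best_gap:
            best, best_gap = i, gap
    return best, True


def ancestral_count(
    members: Sequence[str], events: Iterable[tuple[str, str]]
) -> int:
    """Number of ancestral genes implied by a set of duplication events.

    Events are edges of a graph over the family members; each connected
    component of duplicates descends from a single ancestral gene, so the
    count is total members minus duplication-derived genes.  Invariant
    under event order and repeated events.
    """
    members = list(members)
    g = nx.Graph()
    for a, b in events:
        for gene in (a, b):
            if gene not in members:
                raise KeyError(f"event gene {gene} not a family member")
        g.add_edge(a, b)
    derived = g.number_of_nodes() - nx.number_connected_components(g)
    return len(members) - derived


def build_event_report(
    kaks: Mapping[tuple[str, str], tuple[float, float]],
    mechanisms: Mapping[frozenset[str], str],
    config: StageConfig | None = None,
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Assemble the per-pair duplication report.

    ``kaks`` maps ordered pairs to (Ka, Ks); ``mechanisms`` maps unordered
    pairs to tandem/segmental/unclassified.  One row per pair with the
    ratio and date truncated to the report's printed precision (4 and 2
    decimals), the selection call as Yes/No (purifying or not), and the
    stage assignment.  Rows are ordered by date descending.
    """
    config = config or StageConfig()
    rows = []
    for (a, b), (ka, ks) in kaks.items():
        key = pair_key(a, b)
        if key not in mechanisms:
            raise KeyError(f"no mechanism for pair {a}/{b}")
        ratio = ka / ks if ks > 0 else None
        date = date_event(ks, config.lam)
        if key in config.overrides:
            stage, flagged = config.overrides[key], False
            strict_stage, _ = assign_stage(date, config)
            overridden = stage != strict_stage
        else:
            stage, flagged = assign_stage(date, config)
            overridden = False
        sel = classify_selection(ratio, epsilon)
        rows.append({
            "pair": f"{a}/{b}",
            "Ka": ka,
            "Ks": ks,
            "Ka/Ks": truncate(ratio, 4) if ratio is not None else float("nan"),
            "ratio_full": ratio,
            "date_my": truncate(date, 2),
            "date_my_full": date,
            "mechanism": mechanisms[key],
            "selection": sel,
            "purifying": "Yes" if sel == "purifying" else "No",
            "stage": stage,
            "out_of_range": flagged,
            "stage_overridden": overridden,
        })
    df = pd.DataFrame(rows, columns=[
        "pair", "Ka", "Ks", "Ka/Ks", "ratio_full", "date_my", "date_my_full",
        "mechanism", "selection", "purifying", "stage", "out_of_range",
        "stage_overridden",
    ])
    if not df.empty:
        df = df.sort_values("date_my_full", ascending=False).reset_index(drop=True)
    return df
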